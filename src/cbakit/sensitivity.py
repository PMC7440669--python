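"""Co-factor stoichiometry landscapes on the terminal aldehyde-reductase step.

The terminal butyraldehyde -> butanol reaction is rewritten with artificial
NADH (X) and ATP (Y) coefficients,

    btal + X nadh + (X + Y) h + Y adp + Y pi -> btoh + X nad + Y atp + Y h2o,

so that positive X/Y mean the step releases a co-factor surplus, negative
values an extra demand, and zero a co-factor-free step.  The native reaction
is recovered at (X, Y) = (1, 0).  Sweeping a grid of (X, Y) and re-optimising
with pFBA maps how product yield and biomass respond to the pathway's
co-factor balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd

from .cba import carbon_yield
from .core_model import BIOMASS_ID
from .solvers import InfeasibleModelError, optimize_pfba

logger = logging.getLogger(__name__)

TERMINAL_REACTION = "ALCD4"
NATIVE_X = 1.0
NATIVE_Y = 0.0


@dataclass
class LandscapeGrid:
    """Long-format (X, Y) grid of carbon yields and biomass rates."""

    table: pd.DataFrame  # columns: X, Y, yield, biomass, status
    variant: str = ""
    condition: str = ""

    def pivot(self, value: str = "yield") -> pd.DataFrame:
        return self.table.pivot(index="Y", columns="X", values=value)

    def at(self, x: float, y: float) -> pd.Series:
        sel = self.table[(self.table["X"] == x) & (self.table["Y"] == y)]
        if sel.empty:
            raise KeyError(f"no grid cell at X={x}, Y={y}")
        return sel.iloc[0]

    @property
    def max_yield(self) -> float:
        return float(self.table["yield"].max())


def modify_terminal_stoichiometry(
    network: cobra.Model,
    x_nadh: float,
    y_atp: float,
    terminal_reaction: str = TERMINAL_REACTION,
) -> cobra.Model:
    """Return a copy whose terminal reductase carries coefficients (X, Y)."""
    if not network.reactions.has_id(terminal_reaction):
        raise ValueError(f"terminal reaction {terminal_reaction!r} not in model")
    model = network.copy()
    rxn = model.reactions.get_by_id(terminal_reaction)
    get = model.metabolites.get_by_id
    stoich = {
        get("btal_c"): -1.0,
        get("btoh_c"): 1.0,
        get("nadh_c"): -x_nadh,
        get("nad_c"): x_nadh,
        get("h_c"): -(x_nadh + y_atp),
        get("adp_c"): -y_atp,
        get("pi_c"): -y_atp,
        get("atp_c"): y_atp,
        get("h2o_c"): y_atp,
    }
    rxn.subtract_metabolites(dict(rxn.metabolites))
    rxn.add_metabolites({m: c for m, c in stoich.items() if c != 0.0})
    rxn.bounds = (0.0, 1000.0)
    return model


def build_landscape(
    network: cobra.Model,
    target_metabolite: str = "btoh_e",
    x_range: tuple[float, float] = (-10.0, 10.0),
    y_range: tuple[float, float] = (-10.0, 10.0),
    step: float = 1.0,
    condition: str = "",
    terminal_reaction: str = TERMINAL_REACTION,
) -> LandscapeGrid:
    """pFBA yield/biomass surface over the (X, Y) co-factor grid.

    Infeasible cells are recorded with zero yield and status ``infeasible``.
    """
    xs = np.arange(x_range[0], x_range[1] + step / 2, step)
    ys = np.arange(y_range[0], y_range[1] + step / 2, step)
    rows = []
    for y in ys:
        for x in xs:
            model = modify_terminal_stoichiometry(network, float(x), float(y),
                                                  terminal_reaction)
            try:
                sol = optimize_pfba(model)
                rows.append({
                    "X": float(x), "Y": float(y),
                    "yield": carbon_yield(model, sol, target_metabolite),
                    "biomass": sol.fluxes.get(BIOMASS_ID, 0.0),
                    "status": "optimal",
                })
            except InfeasibleModelError:
                rows.append({"X": float(x), "Y": float(y), "yield": 0.0,
                             "biomass": 0.0, "status": "infeasible"})
    table = pd.DataFrame(rows)
    return LandscapeGrid(table, variant=network.name or network.id, condition=condition)
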