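"""Programmatic fixtures: a toy co-factor network and a synthetic flux table.

The toy network (11 metabolites, 9 reactions) has hand-set, mass-balanced
fluxes with analytically known category totals, plus a planted
phosphofructokinase/fructose-bisphosphatase futile cycle that dissipates a
known amount of ATP.  The synthetic flux table emulates the shape of a
published 13C-MFA compendium: central-carbon reactions as rows (including
isozyme families), wild-type replicates and knockout strains as columns,
designated plastic and rigid rows, and a glucose-uptake row for
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd
from cobra import Metabolite, Reaction

from .cba import CategoryRules, CofactorSpec
from .curation import CycleCandidate
from .mfa import GLUCOSE_ROW, FluxDataset
from .solvers import FluxDistribution

TOY_COFACTORS = (
    CofactorSpec("ATP", ("atp_c",)),
    CofactorSpec("NAD(P)H", ("nadh_c",)),
)

TOY_RULES = CategoryRules(
    biomass=("BIOM",),
    target=("TGT", "TGT_sink"),
    waste={"ATP": ("ATPM",), "NAD(P)H": ("NADOX",)},
    ppp_production=(),
)

TOY_CANDIDATES = (
    CycleCandidate(cap="FBP", partners=("PFK",), cofactor="ATP"),
)

#: hand-set steady-state fluxes (engineered state, with the planted cycle).
TOY_FLUXES = {
    "SRC": 10.0, "CAT": 10.0, "TGT": 8.0, "TGT_sink": 8.0, "BIOM": 2.0,
    "ATPM": 8.0, "PFK": 8.0, "FBP": 8.0, "NADOX": 10.0,
}

#: reference state: no cycle, maintenance absorbs the surplus.
TOY_WT_FLUXES = {
    "SRC": 10.0, "CAT": 10.0, "TGT": 8.0, "TGT_sink": 8.0, "BIOM": 2.0,
    "ATPM": 16.0, "PFK": 0.0, "FBP": 0.0, "NADOX": 10.0,
}

#: analytically derived CBA category nets for TOY_FLUXES.
TOY_EXPECTED = {
    "ATP": {"production": 20.0, "biomass": -4.0, "target": 0.0,
            "waste": -8.0, "maintenance": -8.0},
    "NAD(P)H": {"production": 20.0, "biomass": -2.0, "target": -8.0,
                "waste": -10.0, "maintenance": 0.0},
}


@dataclass
class ToyFixture:
    model: cobra.Model
    fluxes: FluxDistribution
    wt_fluxes: FluxDistribution
    rules: CategoryRules
    cofactors: tuple[CofactorSpec, ...]
    candidates: tuple[CycleCandidate, ...]
    expected: dict
    flux_table: FluxDataset


def build_toy_model() -> cobra.Model:
    """Small network with known co-factor stoichiometry.

    SRC   : -> s            (substrate source)
    CAT   : s + 2 adp + 2 pi + 2 nad -> p + 2 atp + 2 nadh   (catabolism)
    TGT   : p + nadh -> t + nad                              (target synthesis)
    TGT_sink : t ->
    BIOM  : p + 2 atp + nadh -> 2 adp + 2 pi + nad           (biomass proxy)
    ATPM  : atp -> adp + pi                                  (maintenance)
    PFK   : f6 + atp -> fdp + adp                            (cycle, forward)
    FBP   : fdp -> f6 + pi                                   (cycle, back)
    NADOX : nadh -> nad                                      (respiration proxy)
    """
    model = cobra.Model("toy_cofactor_net")
    mets = {mid: Metabolite(mid, compartment="c") for mid in (
        "s_c", "p_c", "t_c", "f6_c", "fdp_c",
        "atp_c", "adp_c", "pi_c", "nad_c", "nadh_c",
    )}
    model.add_metabolites(list(mets.values()))
    m = mets

    def add(rid, stoich, bounds=(0.0, 1000.0)):
        rxn = Reaction(rid)
        rxn.bounds = bounds
        model.add_reactions([rxn])
        rxn.add_metabolites(stoich)
        return rxn

    add("SRC", {m["s_c"]: 1})
    add("CAT", {m["s_c"]: -1, m["adp_c"]: -2, m["pi_c"]: -2, m["nad_c"]: -2,
                m["p_c"]: 1, m["atp_c"]: 2, m["nadh_c"]: 2})
    add("TGT", {m["p_c"]: -1, m["nadh_c"]: -1, m["t_c"]: 1, m["nad_c"]: 1})
    add("TGT_sink", {m["t_c"]: -1})
    add("BIOM", {m["p_c"]: -1, m["atp_c"]: -2, m["nadh_c"]: -1,
                 m["adp_c"]: 2, m["pi_c"]: 2, m["nad_c"]: 1})
    add("ATPM", {m["atp_c"]: -1, m["adp_c"]: 1, m["pi_c"]: 1})
    add("PFK", {m["f6_c"]: -1, m["atp_c"]: -1, m["fdp_c"]: 1, m["adp_c"]: 1})
    add("FBP", {m["fdp_c"]: -1, m["f6_c"]: 1, m["pi_c"]: 1})
    add("NADOX", {m["nadh_c"]: -1, m["nad_c"]: 1})
    model.objective = "TGT_sink"
    return model


def _as_distribution(model, fluxes, label) -> FluxDistribution:
    series = pd.Series({r.id: fluxes.get(r.id, 0.0) for r in model.reactions})
    return FluxDistribution(
        fluxes=series, objective_id="TGT_sink",
        objective_value=series["TGT_sink"], status="hand-set",
        method="fixture", variant=label,
    )


# ---------------------------------------------------------------------------
# synthetic reaction x strain flux table
# ---------------------------------------------------------------------------

#: final (formatted) reaction set, mirroring the 15-reaction reference shape.
MEASURED_REACTIONS = (
    "PGI", "PFK", "FBA", "TPI", "GAPD", "PGK", "ENO", "PYK", "PDH",
    "G6PDH2r", "GND", "PPC", "PPCK", "ME1", "ME2",
)

ISOZYME_MAP = {"pfkA": "PFK", "pfkB": "PFK", "maeA": "ME1", "maeB": "ME2"}

#: baseline flux per 10 glucose, and half-range across strains: plastic
#: glycolytic reactions move widely, anaplerotic/malic-enzyme reactions are
#: rigid with ranges near 1.3.
_PROFILE = {
    "PGI": (8.0, 2.5), "PFK": (9.0, 4.0), "FBA": (9.0, 3.0), "TPI": (9.0, 3.0),
    "GAPD": (17.0, 4.5), "PGK": (17.0, 4.5), "ENO": (15.0, 3.5),
    "PYK": (5.0, 2.0), "PDH": (9.0, 3.0), "G6PDH2r": (2.0, 1.5),
    "GND": (2.0, 1.5), "PPC": (2.5, 1.0), "PPCK": (0.65, 0.65),
    "ME1": (0.65, 0.65), "ME2": (0.65, 0.65),
}

KNOCKOUT_COLUMNS = ("d_pgi", "d_zwf", "d_gnd", "d_ppc", "d_pck", "d_pyk")


def synthetic_flux_table(seed: int = 0, n_wt_replicates: int = 2,
                         uptake: float = 9.5) -> FluxDataset:
    """Seeded reaction x strain table in the 13C-MFA compendium shape."""
    rng = np.random.default_rng(seed)
    strains = [f"WT_{i + 1}" for i in range(n_wt_replicates)] + list(KNOCKOUT_COLUMNS)
    rows = {}
    raw_ids = []
    for rid in MEASURED_REACTIONS:
        members = [k for k, v in ISOZYME_MAP.items() if v == rid] or [rid]
        raw_ids.extend(members)
    for raw in raw_ids:
        rid = ISOZYME_MAP.get(raw, raw)
        base, half = _PROFILE[rid]
        offsets = rng.uniform(-half, half, size=len(strains))
        # wild-type replicates sit near the baseline
        offsets[:n_wt_replicates] = rng.uniform(-0.1 * half, 0.1 * half,
                                                size=n_wt_replicates)
        rows[raw] = base + offsets
    # a measured reaction absent from the core model: dropped by formatting
    rows["EDD"] = rng.uniform(0.0, 0.5, size=len(strains))
    uptakes = uptake * (1.0 + rng.uniform(-0.05, 0.05, size=len(strains)))
    rows[GLUCOSE_ROW] = uptakes
    data = pd.DataFrame(rows, index=strains).T
    return FluxDataset(
        data=data, glucose_row=GLUCOSE_ROW,
        wt_columns=tuple(f"WT_{i + 1}" for i in range(n_wt_replicates)),
        isozyme_map=dict(ISOZYME_MAP),
    )


def generate_toy_fixture(seed: int = 0) -> ToyFixture:
    """Toy network, hand-set solutions, rules and a synthetic flux table."""
    model = build_toy_model()
    return ToyFixture(
        model=model,
        fluxes=_as_distribution(model, TOY_FLUXES, "toy-engineered"),
        wt_fluxes=_as_distribution(model, TOY_WT_FLUXES, "toy-wt"),
        rules=TOY_RULES,
        cofactors=TOY_COFACTORS,
        candidates=TOY_CANDIDATES,
        expected=TOY_EXPECTED,
        flux_table=synthetic_flux_table(seed),
    )
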