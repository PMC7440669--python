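"""Analytic pathway-yield chain from degree-of-reductance bookkeeping.

For a route from glucose to a CHO product the chain is:

* maximum (energetic) yield ``Y_E = gamma_S / gamma_P`` per C-mol, with the
  degree of reductance ``gamma = 4C + H - 2O``; ``Y_Ea`` is the same yield on
  a mass basis;
* pathway yield ``Y_P``: the stoichiometric yield discounted for NADPH demand
  (supplied by oxidative PPP at 2 NADPH per C-mol glucose) and, when the
  route is net ATP-negative, for respiratory ATP at 4.82 ATP per C-mol;
* glycerol-adjusted yield ``Y_PG``: surplus NADH is drained into a glycerol
  sink that itself consumes 1/3 ATP and 1/3 NADH per C-mol;
* biomass-adjusted yield ``Y_PGX``: remaining ATP surplus is diverted to
  biomass formation (degree of reductance kappa = 4.2), whose excess
  electrons are again drained as glycerol;
* efficiency ``eta = Y_PGX / Y_E``.

Coefficients a (NADPH demand), b (product), c (ATP), d (NADH) and e (CO2)
are normalised per C-mol glucose and include the glycolytic premise of 2 net
ATP and 4 NADH per glucose catabolised to two acetyl-CoA.

The biomass stage depends on an energetics parameter ``epsilon`` (C-mol of
glucose respired per C-mol of biomass formed) and the biomass ATP coefficient
``alpha``, neither of which has a canonical printed value; they must be
supplied explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import cobra

from .core_model import PathwayDefinition

#: respiratory ATP per C-mol glucose fully oxidised.
RESPIRATION_ATP = 4.82
#: degree of reductance of biomass (CH1.83O0.56N0.17 basis).
BIOMASS_KAPPA = 4.2
#: glycerol sink cost per C-mol glycerol.
GLYCEROL_ATP = 1.0 / 3.0
GLYCEROL_NADH = 1.0 / 3.0

GLUCOSE = {"C": 6, "H": 12, "O": 6}
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: glycolytic premise: glucose -> 2 acetyl-CoA + 2 CO2 + 2 ATP + 4 NADH.
GLYCOLYSIS_ATP = 2.0
GLYCOLYSIS_NADH = 4.0
GLYCOLYSIS_CO2 = 2.0


def parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if sym:
            out[sym] = out.get(sym, 0) + (int(num) if num else 1)
    if not out:
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def degree_of_reductance(formula: str | dict) -> float:
    """Available electrons per molecule: 4C + H - 2O (CHO compounds)."""
    el = parse_formula(formula) if isinstance(formula, str) else formula
    unknown = set(el) - {"C", "H", "O"}
    if unknown:
        raise ValueError(f"only CHO formulas supported, got extra elements {unknown}")
    return 4.0 * el.get("C", 0) + el.get("H", 0) - 2.0 * el.get("O", 0)


def molecular_weight(formula: str | dict) -> float:
    el = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(_ATOMIC_MASS[s] * n for s, n in el.items())


@dataclass(frozen=True)
class PathwayCoefficients:
    """Net route coefficients per C-mol glucose (glycolytic premise included)."""

    a: float  # NADPH demand (>= 0)
    b: float  # product, C-mol per C-mol glucose
    c: float  # ATP release (negative = demand)
    d: float  # NADH release (negative = demand)
    e: float  # CO2 release
    product_formula: str

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("product coefficient b must be positive")
        if self.a < 0:
            raise ValueError("NADPH demand a must be non-negative")

    @property
    def stoichiometric_yield(self) -> float:
        """Product per glucose in mol/mol at b C-mol per C-mol."""
        carbons = parse_formula(self.product_formula)["C"]
        return self.b * 6.0 / carbons


@dataclass(frozen=True)
class DugarParameters:
    """Biomass-stage energetics; epsilon and alpha have no printed canonical
    value and must be chosen explicitly."""

    epsilon: float
    alpha: float
    kappa: float = BIOMASS_KAPPA
    respiration_atp: float = RESPIRATION_ATP

    @property
    def x(self) -> float:
        """NADH released per (1+epsilon) C-mol glucose converted to biomass."""
        return (4.0 * (1.0 + self.epsilon) - self.kappa) / 2.0


@dataclass(frozen=True)
class YieldChain:
    pathway: str
    Y_E: float
    Y_Ea: float
    Y_P: float
    Y_PG: float
    Y_PGX: float | None = None
    eta: float | None = None


def pathway_coefficients(
    pathway: PathwayDefinition,
    product_formula: str,
    network: cobra.Model,
) -> PathwayCoefficients:
    """Derive (a, b, c, d, e) for a route built into a network.

    The NADH/NADPH split, ATP and CO2 release are summed over the pathway's
    actual reaction stoichiometry and combined with the glycolytic premise.
    """
    formula = parse_formula(product_formula)
    carbons = formula["C"]
    b = carbons / 6.0
    nadph = nadh = atp = co2 = 0.0
    get = network.metabolites.get_by_id
    mets = {m: get(m) for m in ("nadh_c", "nadph_c", "atp_c", "co2_c", "hco3_c")
            if network.metabolites.has_id(m)}
    for rid in pathway.reaction_ids:
        rxn = network.reactions.get_by_id(rid)
        nadh += rxn.metabolites.get(mets.get("nadh_c"), 0.0)
        nadph += rxn.metabolites.get(mets.get("nadph_c"), 0.0)
        atp += rxn.metabolites.get(mets.get("atp_c"), 0.0)
        co2 += rxn.metabolites.get(mets.get("co2_c"), 0.0)
        co2 += rxn.metabolites.get(mets.get("hco3_c"), 0.0)
    a = max(0.0, -nadph) / 6.0
    c = (GLYCOLYSIS_ATP + atp) / 6.0
    d = (GLYCOLYSIS_NADH + nadh) / 6.0
    e = (GLYCOLYSIS_CO2 + co2) / 6.0
    return PathwayCoefficients(a=a, b=b, c=c, d=d, e=e, product_formula=product_formula)


def max_yield(product_formula: str) -> tuple[float, float]:
    """Energetic maximum yield (mol/mol, mass/mass) for a CHO product."""
    gamma_p = degree_of_reductance(product_formula)
    if gamma_p <= 0:
        raise ValueError("product has zero degree of reductance")
    carbons = parse_formula(product_formula)["C"]
    gamma_s = degree_of_reductance(GLUCOSE)
    y_cmol = (gamma_s / 6.0) / (gamma_p / carbons)
    y_mol = y_cmol * 6.0 / carbons
    y_mass = y_mol * molecular_weight(product_formula) / molecular_weight(GLUCOSE)
    return y_mol, y_mass


def pathway_yield(coeffs: PathwayCoefficients,
                  respiration_atp: float = RESPIRATION_ATP) -> float:
    """Stoichiometric yield discounted for NADPH and net-negative ATP."""
    denom = 1.0 + coeffs.a / 2.0
    if coeffs.c < 0:
        denom += -coeffs.c / respiration_atp
    if denom <= 0:
        raise ValueError("non-positive denominator in pathway yield")
    return coeffs.stoichiometric_yield / denom


def glycerol_adjusted_yield(coeffs: PathwayCoefficients,
                            respiration_atp: float = RESPIRATION_ATP) -> float:
    """Pathway yield after draining surplus NADH into the glycerol sink.

    Each C-mol of glycerol consumes 1/3 NADH and 1/3 ATP; any ATP deficit
    that the sink creates is covered by respiring additional glucose.
    """
    surplus = max(0.0, coeffs.d)
    glycerol = surplus / GLYCEROL_NADH  # C-mol glycerol per C-mol pathway glucose
    atp_after = coeffs.c - GLYCEROL_ATP * glycerol
    denom = 1.0 + coeffs.a / 2.0 + glycerol
    if atp_after < 0:
        denom += -atp_after / respiration_atp
    if denom <= 0:
        raise ValueError("non-positive denominator in glycerol-adjusted yield")
    return coeffs.stoichiometric_yield / denom


def biomass_adjusted_yield(
    coeffs: PathwayCoefficients,
    params: DugarParameters,
    y_e: float | None = None,
) -> tuple[float, float]:
    """Divert remaining ATP surplus into biomass; returns (Y_PGX, eta).

    Biomass formation consumes ``alpha/(1+epsilon)`` ATP and releases
    ``x/(1+epsilon)`` NADH per C-mol of glucose routed to it; that NADH is
    drained by additional glycerol.  Solving the coupled ATP/NADH balance
    gives the glucose spent on biomass (v5) and glycerol (v4).
    """
    surplus_nadh = max(0.0, coeffs.d)
    glycerol0 = surplus_nadh / GLYCEROL_NADH
    atp_surplus = coeffs.c - GLYCEROL_ATP * glycerol0
    y_pg = glycerol_adjusted_yield(coeffs, params.respiration_atp)
    if y_e is None:
        y_e, _ = max_yield(coeffs.product_formula)
    if atp_surplus <= 0:
        return y_pg, y_pg / y_e

    eps, alpha, x = params.epsilon, params.alpha, params.x
    # v5: C-mol glucose into the biomass route; v4: total C-mol glycerol.
    # ATP:  c - (1/3) v4 - alpha/(1+eps) v5 = 0
    # NADH: d + x/(1+eps) v5 - (1/3) v4 = 0
    denom = alpha + x
    if denom <= 0:
        raise ValueError("alpha + x must be positive for a bounded biomass diversion")
    v5 = (coeffs.c - coeffs.d) * (1.0 + eps) / denom
    v5 = max(0.0, v5)
    v4 = 3.0 * (max(0.0, coeffs.d) + x / (1.0 + eps) * v5)
    v4 = max(0.0, v4)
    total = 1.0 + coeffs.a / 2.0 + v4 + v5
    y_pgx = coeffs.stoichiometric_yield / total
    y_pgx = min(y_pgx, y_pg)
    return y_pgx, y_pgx / y_e


def yield_chain(
    pathway: PathwayDefinition,
    product_formula: str,
    network: cobra.Model,
    params: DugarParameters | None = None,
) -> YieldChain:
    """Full yield chain for one pathway (biomass stage only with params)."""
    coeffs = pathway_coefficients(pathway, product_formula, network)
    y_e, y_ea = max_yield(product_formula)
    y_p = pathway_yield(coeffs)
    y_pg = glycerol_adjusted_yield(coeffs)
    y_pgx = eta = None
    if params is not None:
        y_pgx, eta = biomass_adjusted_yield(coeffs, params, y_e)
    return YieldChain(pathway.name, y_e, y_ea, min(y_p, y_e), min(y_pg, y_p), y_pgx, eta)
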