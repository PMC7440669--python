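"""Closed-form yield chain: reductance arithmetic and adjustment stages."""

import numpy as np
import pytest

from cbakit.cli import PRODUCT_FORMULAS
from cbakit.dugar import (
    DugarParameters,
    GLYCEROL_ATP,
    GLYCEROL_NADH,
    PathwayCoefficients,
    RESPIRATION_ATP,
    biomass_adjusted_yield,
    degree_of_reductance,
    glycerol_adjusted_yield,
    max_yield,
    pathway_coefficients,
    pathway_yield,
    yield_chain,
)

BUTANOL_ROUTES = ("BuOH-0", "BuOH-1", "tpcBuOH", "BuOH-2", "fasBuOH")


@pytest.mark.parametrize("formula,ye,yea", [
    ("C4H10O", 1.000, 0.411),   # butanol
    ("C4H6O2", 1.333, 0.637),   # crotonic acid
    ("C4H8O2", 1.200, 0.587),   # butyric acid
    ("C4H8O", 1.091, 0.437),    # butyraldehyde
])
def test_energetic_maximum_yields(formula, ye, yea):
    y_mol, y_mass = max_yield(formula)
    assert y_mol == pytest.approx(ye, abs=5e-4)
    assert y_mass == pytest.approx(yea, abs=5e-4)


def test_glucose_identity():
    y_mol, y_mass = max_yield("C6H12O6")
    assert y_mol == pytest.approx(1.0)
    assert y_mass == pytest.approx(1.0)


def test_reductance_convention():
    assert degree_of_reductance("C6H12O6") == 24
    assert degree_of_reductance("C4H10O") == 24
    with pytest.raises(ValueError):
        degree_of_reductance("C4H9NO2")  # nitrogen not supported
    with pytest.raises(ValueError):
        max_yield("CO2")  # zero reductance


@pytest.mark.parametrize("variant,a,c,d", [
    ("BuOH-0", 0.0, 2 / 6, 0.0),
    ("BuOH-1", 0.0, 1 / 6, 0.0),
    ("tpcBuOH", 1 / 6, 1 / 6, 1 / 6),
    ("BuOH-2", 1 / 6, 0.0, 1 / 6),
    ("fasBuOH", 2 / 6, 0.0, 2 / 6),
    ("CROT", 0.0, 2 / 6, 3 / 6),
    ("BUTYR", 0.0, 2 / 6, 2 / 6),
    ("BUTAL", 0.0, 2 / 6, 1 / 6),
])
def test_route_coefficients(catalog, pathways, variant, a, c, d):
    coeffs = pathway_coefficients(
        pathways[variant], PRODUCT_FORMULAS[variant], catalog[variant]
    )
    assert coeffs.a == pytest.approx(a)
    assert coeffs.c == pytest.approx(c)
    assert coeffs.d == pytest.approx(d)
    assert coeffs.b == pytest.approx(4 / 6)


@pytest.mark.parametrize("variant,yp", [
    ("BuOH-0", 1.000), ("BuOH-1", 1.000),
    ("tpcBuOH", 0.923), ("BuOH-2", 0.923), ("fasBuOH", 0.857),
    ("CROT", 1.000), ("BUTYR", 1.000), ("BUTAL", 1.000),
])
def test_pathway_yields(catalog, pathways, variant, yp):
    coeffs = pathway_coefficients(
        pathways[variant], PRODUCT_FORMULAS[variant], catalog[variant]
    )
    assert pathway_yield(coeffs) == pytest.approx(yp, abs=5e-4)


@pytest.mark.parametrize("variant,ypg", [
    ("BuOH-0", 1.000), ("BuOH-1", 1.000),
    ("CROT", 0.395), ("BUTYR", 0.500), ("BUTAL", 0.667),
])
def test_glycerol_adjustment_without_nadph_demand(catalog, pathways, variant, ypg):
    coeffs = pathway_coefficients(
        pathways[variant], PRODUCT_FORMULAS[variant], catalog[variant]
    )
    assert glycerol_adjusted_yield(coeffs) == pytest.approx(ypg, abs=5e-4)


def test_chain_is_monotone_for_all_routes(catalog, pathways):
    params = DugarParameters(epsilon=0.2, alpha=3.49)
    for name, pdef in pathways.items():
        chain = yield_chain(pdef, PRODUCT_FORMULAS[name], catalog[name], params)
        assert chain.Y_PGX <= chain.Y_PG + 1e-9, name
        assert chain.Y_PG <= chain.Y_P + 1e-9, name
        assert chain.Y_P <= chain.Y_E + 1e-9, name
        assert 0.0 <= chain.eta <= 1.0, name


def test_efficiency_ranking(catalog, pathways):
    params = DugarParameters(epsilon=0.2, alpha=3.49)
    etas = {
        name: yield_chain(pdef, PRODUCT_FORMULAS[name], catalog[name], params).eta
        for name, pdef in pathways.items()
    }
    butanol_etas = {k: etas[k] for k in BUTANOL_ROUTES}
    assert max(butanol_etas, key=butanol_etas.get) == "BuOH-1"
    assert etas["BuOH-1"] > etas["BuOH-0"]


def _direct_chain_evaluation(coeffs, eps, alpha):
    """Independent evaluation of the biomass-diversion balance, written as a
    literal 2x2 linear solve rather than the closed form used in the module."""
    x = (4.0 * (1.0 + eps) - 4.2) / 2.0
    glycerol0 = max(0.0, coeffs.d) / GLYCEROL_NADH
    surplus = coeffs.c - GLYCEROL_ATP * glycerol0
    if surplus <= 0:
        return glycerol_adjusted_yield(coeffs)
    mat = np.array([[GLYCEROL_ATP, alpha / (1.0 + eps)],
                    [GLYCEROL_NADH, -x / (1.0 + eps)]])
    rhs = np.array([coeffs.c, coeffs.d])
    v4, v5 = np.linalg.solve(mat, rhs)
    return coeffs.stoichiometric_yield / (1.0 + coeffs.a / 2.0 + v4 + v5)


def test_biomass_stage_matches_direct_solve_over_grid(catalog, pathways):
    coeffs = pathway_coefficients(pathways["BuOH-0"], "C4H10O", catalog["BuOH-0"])
    values = []
    for eps in np.linspace(0.05, 1.0, 12):
        params = DugarParameters(epsilon=float(eps), alpha=3.49)
        y_pgx, _ = biomass_adjusted_yield(coeffs, params)
        assert y_pgx == pytest.approx(
            _direct_chain_evaluation(coeffs, float(eps), 3.49), abs=1e-9
        )
        values.append(y_pgx)
    diffs = np.diff(values)
    assert (diffs <= 1e-12).all() or (diffs >= -1e-12).all()


def test_trivial_coefficients_have_no_penalty():
    coeffs = PathwayCoefficients(a=0.0, b=4 / 6, c=0.0, d=0.0, e=2 / 6,
                                 product_formula="C4H10O")
    assert pathway_yield(coeffs) == pytest.approx(coeffs.stoichiometric_yield)
    assert glycerol_adjusted_yield(coeffs) == pytest.approx(coeffs.stoichiometric_yield)
    y_pgx, eta = biomass_adjusted_yield(coeffs, DugarParameters(0.2, 3.49))
    assert y_pgx == pytest.approx(glycerol_adjusted_yield(coeffs))


def test_invalid_coefficients_error():
    with pytest.raises(ValueError):
        PathwayCoefficients(a=0.0, b=0.0, c=0.0, d=0.0, e=0.0, product_formula="C4H10O")
    with pytest.raises(ValueError):
        PathwayCoefficients(a=-0.1, b=0.5, c=0.0, d=0.0, e=0.0, product_formula="C4H10O")
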