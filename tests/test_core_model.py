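"""Wild-type reduction and engineered-variant construction."""

import pytest

from cbakit.core_model import (
    ATPM_ID,
    BIOMASS_ID,
    MediumCondition,
    ModelBuildError,
    PathwayDefinition,
    add_pathway,
    apply_medium,
    load_core_model,
    pathway_cofactor_sums,
    write_variant_sbml,
)
from cbakit.solvers import optimize_pfba

# variant -> (metabolites, reactions, objective, ATP sum, NAD(P)H sum)
VARIANT_TABLE = {
    "WT": (63, 77, BIOMASS_ID, None, None),
    "BuOH-0": (70, 85, "BTOH_sink", 0, -4),
    "BuOH-1": (72, 87, "BTOH_sink", -1, -4),
    "tpcBuOH": (71, 86, "BTOH_sink", -1, -4),
    "BuOH-2": (73, 88, "BTOH_sink", -2, -4),
    "fasBuOH": (77, 91, "BTOH_sink", -2, -4),
    "CROT": (68, 83, "CROAC_sink", 0, -1),
    "BUTYR": (69, 84, "BTAC_sink", 0, -2),
    "BUTAL": (69, 84, "BTAL_sink", 0, -3),
}


def test_wild_type_shape():
    wt = load_core_model()
    assert len(wt.reactions) == 77
    assert len(wt.metabolites) == 63
    assert wt.reactions.get_by_id(ATPM_ID).lower_bound == pytest.approx(7.6)
    assert [r.id for r in wt.reactions if r.objective_coefficient] == [BIOMASS_ID]


@pytest.mark.parametrize("variant", sorted(VARIANT_TABLE))
def test_variant_shapes_and_objectives(catalog, variant):
    n_mets, n_rxns, objective, _, _ = VARIANT_TABLE[variant]
    model = catalog[variant]
    assert len(model.metabolites) == n_mets
    assert len(model.reactions) == n_rxns
    assert [r.id for r in model.reactions if r.objective_coefficient] == [objective]


def test_catalog_has_nine_models(catalog):
    assert len(catalog) == 9


@pytest.mark.parametrize("variant", [v for v in VARIANT_TABLE if v != "WT"])
def test_declared_cofactor_sums(catalog, pathways, variant):
    _, _, _, atp, pool = VARIANT_TABLE[variant]
    s_atp, s_pool = pathway_cofactor_sums(catalog[variant], pathways[variant])
    assert s_atp == pytest.approx(atp)
    assert s_pool == pytest.approx(pool)


@pytest.mark.parametrize("variant", [v for v in VARIANT_TABLE if v != "WT"])
def test_added_reactions_are_balanced(catalog, pathways, variant):
    """Every introduced interior reaction conserves elements and charge."""
    model = catalog[variant]
    for spec in pathways[variant].reactions:
        rxn = model.reactions.get_by_id(spec.id)
        if not rxn.reactants or not rxn.products:
            continue  # sink
        assert rxn.check_mass_balance() == {}, spec.id


def test_add_pathway_leaves_base_untouched(catalog, pathways):
    wt = load_core_model()
    n_r, n_m = len(wt.reactions), len(wt.metabolites)
    add_pathway(wt, pathways["BuOH-0"])
    assert (len(wt.reactions), len(wt.metabolites)) == (n_r, n_m)


def test_add_pathway_duplicate_id_errors(catalog, pathways):
    engineered = catalog["BuOH-0"]
    with pytest.raises(ModelBuildError, match="already present"):
        add_pathway(engineered, pathways["BuOH-0"])


def test_add_empty_pathway_is_identity(catalog):
    wt = load_core_model()
    empty = PathwayDefinition(
        name="empty", reactions=(), metabolites={}, target_metabolite="",
        sink="", atp=0.0, nadph_pool=0.0,
    )
    out = add_pathway(wt, empty)
    assert len(out.reactions) == len(wt.reactions)
    assert len(out.metabolites) == len(wt.metabolites)


def test_pathway_is_purely_additive(catalog, pathways, wt_aerobic):
    """Removing the introduced reactions recovers a WT-equivalent optimum."""
    model = apply_medium(catalog["BuOH-0"], MediumCondition.aerobic())
    model.remove_reactions(
        [model.reactions.get_by_id(r) for r in pathways["BuOH-0"].reaction_ids],
        remove_orphans=True,
    )
    model.objective = BIOMASS_ID
    stripped = optimize_pfba(model)
    reference = optimize_pfba(wt_aerobic)
    assert stripped.objective_value == pytest.approx(reference.objective_value, abs=1e-6)


def test_medium_presets(catalog):
    wt = catalog["WT"]
    aerobic = apply_medium(wt, MediumCondition.aerobic())
    assert aerobic.reactions.EX_glc__D_e.lower_bound == -10.0
    assert aerobic.reactions.EX_o2_e.lower_bound == -10.0
    anaerobic = apply_medium(wt, MediumCondition.anaerobic())
    assert anaerobic.reactions.EX_o2_e.lower_bound == 0.0
    twice = apply_medium(anaerobic, MediumCondition.anaerobic())
    for rxn in twice.exchanges:
        assert rxn.bounds == anaerobic.reactions.get_by_id(rxn.id).bounds


def test_medium_validation():
    with pytest.raises(ValueError, match="oxygen"):
        MediumCondition("aerobic", oxygen_uptake=-50.0)
    with pytest.raises(ValueError, match="zero oxygen"):
        MediumCondition("anaerobic", oxygen_uptake=-1.0)


def test_unknown_exchange_errors(catalog):
    condition = MediumCondition("custom", other_exchanges={"EX_nope_e": (0.0, 0.0)})
    with pytest.raises(ModelBuildError, match="EX_nope_e"):
        apply_medium(catalog["WT"], condition)


def test_sbml_round_trip(tmp_path, catalog):
    model = catalog["BuOH-0"]
    path = tmp_path / "buoh0.xml"
    write_variant_sbml(model, path)
    again = load_core_model(path)
    assert len(again.reactions) == len(model.reactions)
    for rxn in model.reactions:
        twin = again.reactions.get_by_id(rxn.id)
        assert {m.id: c for m, c in twin.metabolites.items()} == \
               {m.id: c for m, c in rxn.metabolites.items()}
        assert twin.bounds == rxn.bounds


def test_sbml_without_objective_errors(tmp_path, catalog):
    model = catalog["WT"].copy()
    model.objective = {}
    path = tmp_path / "noobj.xml"
    write_variant_sbml(model, path)
    with pytest.raises(ModelBuildError, match="no objective"):
        load_core_model(path)


def test_malformed_sbml_errors(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml><model><listOfSpecies></sbml>")
    with pytest.raises(ModelBuildError):
        load_core_model(path)
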