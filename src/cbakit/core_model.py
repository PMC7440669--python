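"""Wild-type core model and engineered pathway variants.

The wild type used throughout is a reduced *Escherichia coli* core network
(77 reactions, 63 metabolites): the textbook core model stripped of the nine
alternative-substrate uptake systems (fructose, glutamine, glutamate,
2-oxoglutarate, malate, fumarate, acetaldehyde, pyruvate and D-lactate
exchange/transport pairs), with the non-growth-associated maintenance demand
(ATPM) reset to the classic chemostat estimate of 7.6 mmol gDW-1 hr-1.
Engineered variants are built by layering declarative pathway definitions
(see ``data/pathways.yml``) on top of this wild type; each definition carries
the declared net ATP and NAD(P)H coefficients of the introduced route, which
are validated against the actual reaction stoichiometry at build time.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import cobra.io
import yaml
from cobra import Metabolite, Reaction

logger = logging.getLogger(__name__)

#: reactions removed from the bundled textbook core model to obtain the
#: 77-reaction / 63-metabolite wild type (nine exchange/transport pairs for
#: alternative substrates).
CORE_DELETIONS = (
    "EX_fru_e", "FRUpts2",
    "EX_gln__L_e", "GLNabc",
    "EX_glu__L_e", "GLUt2r",
    "EX_akg_e", "AKGt2r",
    "EX_mal__L_e", "MALt2_2",
    "EX_fum_e", "FUMt2_2",
    "EX_acald_e", "ACALDt",
    "EX_pyr_e", "PYRt2",
    "EX_lac__D_e", "D_LACt2",
)

BIOMASS_ID = "Biomass_Ecoli_core"
GLUCOSE_EXCHANGE = "EX_glc__D_e"
OXYGEN_EXCHANGE = "EX_o2_e"
ATPM_ID = "ATPM"

#: non-growth-associated ATP maintenance (mmol gDW-1 hr-1).
DEFAULT_NGAM = 7.6

VARIANT_ORDER = (
    "BuOH-0", "BuOH-1", "tpcBuOH", "BuOH-2", "fasBuOH", "CROT", "BUTYR", "BUTAL",
)


class ModelBuildError(ValueError):
    """Raised when a network or pathway cannot be constructed as specified."""


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction of a pathway definition (BiGG-style equation string)."""

    id: str
    equation: str
    name: str = ""
    lower_bound: float | None = None
    upper_bound: float | None = None


@dataclass(frozen=True)
class PathwayDefinition:
    """Declarative description of an engineered production route.

    ``atp`` and ``nadph_pool`` are the declared net sums of the ATP and
    pooled NADH+NADPH stoichiometric coefficients over all introduced
    reactions; :func:`add_pathway` checks them against the actual equations.
    """

    name: str
    reactions: tuple[ReactionSpec, ...]
    metabolites: dict[str, dict]
    target_metabolite: str
    sink: str
    atp: float
    nadph_pool: float
    description: str = ""

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(spec.id for spec in self.reactions)


@dataclass(frozen=True)
class MediumCondition:
    """Exchange-bound preset for minimal glucose medium.

    Uptake bounds are given as negative lower bounds on the exchange
    reactions, in mmol gDW-1 hr-1.
    """

    name: str
    glucose_uptake: float = -10.0
    oxygen_uptake: float = -10.0
    other_exchanges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name == "aerobic" and abs(self.oxygen_uptake) > 10.0:
            raise ValueError("aerobic preset allows at most 10 mmol gDW-1 hr-1 oxygen uptake")
        if self.name == "anaerobic" and self.oxygen_uptake != 0.0:
            raise ValueError("anaerobic preset requires zero oxygen uptake")

    @classmethod
    def aerobic(cls, glucose_uptake: float = -10.0) -> "MediumCondition":
        return cls("aerobic", glucose_uptake=glucose_uptake, oxygen_uptake=-10.0)

    @classmethod
    def anaerobic(cls, glucose_uptake: float = -10.0) -> "MediumCondition":
        return cls("anaerobic", glucose_uptake=glucose_uptake, oxygen_uptake=0.0)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("cbakit") / "data" / name)


def load_pathway_catalog(path: str | Path | None = None) -> dict[str, PathwayDefinition]:
    """Read the pathway-definition file into :class:`PathwayDefinition` objects."""
    raw = yaml.safe_load(Path(path or _data_path("pathways.yml")).read_text())
    reactions = raw["reactions"]
    metabolites = raw["metabolites"]
    catalog: dict[str, PathwayDefinition] = {}
    for name, spec in raw["pathways"].items():
        specs = []
        for rid in spec["reactions"]:
            entry = reactions[rid]
            specs.append(ReactionSpec(id=rid, equation=entry["equation"], name=entry.get("name", "")))
        needed = {
            tok for s in specs for tok in s.equation.replace("-->", " ").replace("<=>", " ").split()
            if tok in metabolites
        }
        catalog[name] = PathwayDefinition(
            name=name,
            reactions=tuple(specs),
            metabolites={k: metabolites[k] for k in sorted(needed)},
            target_metabolite=spec["target_metabolite"],
            sink=spec["sink"],
            atp=float(spec["atp"]),
            nadph_pool=float(spec["nadph_pool"]),
            description=spec.get("description", ""),
        )
    return catalog


def load_core_model(source: str | Path | None = None, ngam: float = DEFAULT_NGAM) -> cobra.Model:
    """Load the wild-type core network.

    Parameters
    ----------
    source
        Path to an SBML file.  When omitted, the bundled textbook core model
        is loaded and reduced to the 77-reaction wild type.
    ngam
        Lower bound placed on the ATP maintenance reaction.
    """
    if source is None:
        model = cobra.io.load_model("textbook")
        to_drop = [model.reactions.get_by_id(rid) for rid in CORE_DELETIONS]
        model.remove_reactions(to_drop, remove_orphans=True)
        model.id = "e_coli_core_wt"
        model.name = "WT"
        model.reactions.get_by_id(ATPM_ID).bounds = (ngam, 1000.0)
        model.objective = BIOMASS_ID
    else:
        try:
            model = cobra.io.read_sbml_model(str(source))
        except Exception as exc:  # cobra wraps libsbml errors
            raise ModelBuildError(f"could not parse SBML from {source}: {exc}") from exc
        for rxn in model.reactions:
            if rxn.lower_bound is None or rxn.upper_bound is None:
                raise ModelBuildError(f"reaction {rxn.id} is missing flux bounds")
    if not _objective_reactions(model):
        raise ModelBuildError("no objective set in model")
    return model


def _objective_reactions(model: cobra.Model) -> list[str]:
    return [
        rxn.id for rxn in model.reactions
        if rxn.objective_coefficient not in (0, 0.0)
    ]


def add_pathway(base: cobra.Model, pathway: PathwayDefinition) -> cobra.Model:
    """Return a copy of ``base`` with the pathway's reactions added.

    The base model is left untouched.  Duplicate reaction ids raise a
    :class:`ModelBuildError`, as does a declared-coefficient mismatch.
    """
    model = base.copy()
    for rid in pathway.reaction_ids:
        if model.reactions.has_id(rid):
            raise ModelBuildError(f"reaction id {rid!r} already present in {base.id}")
    new_mets = []
    for mid, meta in pathway.metabolites.items():
        if not model.metabolites.has_id(mid):
            new_mets.append(Metabolite(
                mid, name=meta.get("name", mid), formula=meta.get("formula"),
                charge=meta.get("charge"), compartment=meta.get("compartment", "c"),
            ))
    model.add_metabolites(new_mets)
    for spec in pathway.reactions:
        rxn = Reaction(spec.id, name=spec.name)
        model.add_reactions([rxn])
        try:
            rxn.build_reaction_from_string(spec.equation, verbose=False)
        except Exception as exc:
            raise ModelBuildError(f"bad equation for {spec.id}: {exc}") from exc
        if spec.lower_bound is not None:
            rxn.lower_bound = spec.lower_bound
        if spec.upper_bound is not None:
            rxn.upper_bound = spec.upper_bound
    _check_dangling(model, pathway)
    _check_declared_coefficients(model, pathway)
    model.id = f"e_coli_core_{pathway.name}"
    model.name = pathway.name
    return model


def _check_dangling(model: cobra.Model, pathway: PathwayDefinition) -> None:
    """A pathway metabolite other than the drained target must be both
    produced and consumed somewhere, otherwise the route is broken."""
    if not pathway.reactions:
        return
    sink = model.reactions.get_by_id(pathway.sink)
    drained = set(sink.reactants)
    for mid in pathway.metabolites:
        met = model.metabolites.get_by_id(mid)
        if met in drained:
            continue
        degrees = len(met.reactions)
        if degrees < 2:
            raise ModelBuildError(
                f"metabolite {mid!r} of pathway {pathway.name!r} is a dead end"
            )


def pathway_cofactor_sums(model: cobra.Model, pathway: PathwayDefinition) -> tuple[float, float]:
    """Net (ATP, NADH+NADPH) stoichiometric sums over the introduced reactions."""
    atp = model.metabolites.get_by_id("atp_c")
    pool = [model.metabolites.get_by_id(m) for m in ("nadh_c", "nadph_c")]
    s_atp = s_pool = 0.0
    for rid in pathway.reaction_ids:
        rxn = model.reactions.get_by_id(rid)
        s_atp += rxn.metabolites.get(atp, 0.0)
        s_pool += sum(rxn.metabolites.get(m, 0.0) for m in pool)
    return s_atp, s_pool


def _check_declared_coefficients(model: cobra.Model, pathway: PathwayDefinition) -> None:
    s_atp, s_pool = pathway_cofactor_sums(model, pathway)
    if abs(s_atp - pathway.atp) > 1e-9 or abs(s_pool - pathway.nadph_pool) > 1e-9:
        raise ModelBuildError(
            f"pathway {pathway.name!r}: declared coefficients (ATP {pathway.atp}, "
            f"NAD(P)H {pathway.nadph_pool}) do not match stoichiometry "
            f"({s_atp:g}, {s_pool:g})"
        )


def build_catalog(
    source: str | Path | None = None,
    pathway_file: str | Path | None = None,
    ngam: float = DEFAULT_NGAM,
) -> dict[str, cobra.Model]:
    """Build all nine variants: the wild type plus eight engineered models.

    The wild type keeps biomass as its objective; each engineered model is
    objective-set to its sink reaction.
    """
    wild_type = load_core_model(source, ngam=ngam)
    catalog = {"WT": wild_type}
    for name, pdef in load_pathway_catalog(pathway_file).items():
        model = add_pathway(wild_type, pdef)
        model.objective = pdef.sink
        catalog[name] = model
    return catalog


def apply_medium(network: cobra.Model, condition: MediumCondition) -> cobra.Model:
    """Return a copy of the network with exchange bounds set for the condition."""
    model = network.copy()
    updates = {
        GLUCOSE_EXCHANGE: (condition.glucose_uptake, 1000.0),
        OXYGEN_EXCHANGE: (condition.oxygen_uptake, 1000.0),
    }
    updates.update(condition.other_exchanges)
    for rid, bounds in updates.items():
        if not model.reactions.has_id(rid):
            raise ModelBuildError(f"unknown exchange reaction {rid!r}")
        model.reactions.get_by_id(rid).bounds = bounds
    return model


def write_variant_sbml(model: cobra.Model, path: str | Path) -> None:
    """Serialise a variant to SBML Level 3 with flux-bounds."""
    cobra.io.write_sbml_model(model, str(path))
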