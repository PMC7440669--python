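"""Co-factor balance assessment (CBA).

For a steady-state flux distribution the co-factor flux score (CFS) of a
reaction is the summed stoichiometric coefficient of the co-factor's member
metabolites multiplied by the reaction flux: positive scores are co-factor
production, negative scores consumption.  Scores are partitioned into five
categories — production, biomass, target, waste and maintenance — and, since
every co-factor pool is balanced at steady state, the category nets close to
zero exactly.

Two co-factors are tracked by default: ATP, and an interchangeable NAD(P)H
pool (NADH + NADPH).  A split accounting (NADH and NADPH as separate
co-factors) is available for questions such as the share of NADPH supplied
by the oxidative pentose-phosphate pathway.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import cobra
import pandas as pd
import yaml

from .solvers import FluxDistribution

logger = logging.getLogger(__name__)


class Category(str, Enum):
    PRODUCTION = "production"
    BIOMASS = "biomass"
    TARGET = "target"
    WASTE = "waste"
    MAINTENANCE = "maintenance"


@dataclass(frozen=True)
class CofactorSpec:
    """A named co-factor with its member metabolite ids."""

    name: str
    members: tuple[str, ...]


DEFAULT_COFACTORS = (
    CofactorSpec("ATP", ("atp_c",)),
    CofactorSpec("NAD(P)H", ("nadh_c", "nadph_c")),
)

SPLIT_COFACTORS = (
    CofactorSpec("ATP", ("atp_c",)),
    CofactorSpec("NADH", ("nadh_c",)),
    CofactorSpec("NADPH", ("nadph_c",)),
)


@dataclass
class CategoryRules:
    """Id-based category membership.

    ``waste`` maps a co-factor name to the reaction ids whose scores belong
    to the waste category for that co-factor (both signs: e.g. ATP made on
    the acetate branch and ATP burnt by the maintenance reactions).
    """

    biomass: tuple[str, ...]
    target: tuple[str, ...]
    waste: dict[str, tuple[str, ...]]
    ppp_production: tuple[str, ...] = ("G6PDH2r", "GND")

    def validate(self) -> None:
        overlap = set(self.biomass) & set(self.target)
        if overlap:
            raise ValueError(f"reactions in both biomass and target: {sorted(overlap)}")

    def with_target(self, target_ids) -> "CategoryRules":
        return CategoryRules(
            biomass=self.biomass, target=tuple(target_ids),
            waste=self.waste, ppp_production=self.ppp_production,
        )


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("cbakit") / "data" / name)


def load_category_rules(path: str | Path | None = None,
                        target_ids=()) -> CategoryRules:
    raw = yaml.safe_load(Path(path or _data_path("categories.yml")).read_text())
    rules = CategoryRules(
        biomass=tuple(raw["biomass"]),
        target=tuple(target_ids),
        waste={k: tuple(v) for k, v in raw["waste"].items()},
        ppp_production=tuple(raw.get("ppp_production", ("G6PDH2r", "GND"))),
    )
    rules.validate()
    return rules


def load_cofactor_specs(path: str | Path | None = None, split: bool = False):
    raw = yaml.safe_load(Path(path or _data_path("categories.yml")).read_text())
    key = "split_cofactors" if split else "cofactors"
    specs = [CofactorSpec(n, tuple(m)) for n, m in raw[key].items()]
    if split and "ATP" not in {s.name for s in specs}:
        specs.insert(0, CofactorSpec("ATP", ("atp_c",)))
    return tuple(specs)


def cofactor_flux_score(reaction: cobra.Reaction, flux: float,
                        cofactor: CofactorSpec) -> float:
    """Summed member coefficient times flux; positive means production."""
    coeff = sum(
        c for met, c in reaction.metabolites.items() if met.id in cofactor.members
    )
    return coeff * flux


def classify_reaction(reaction_id: str, cofactor: CofactorSpec, score: float,
                      rules: CategoryRules) -> Category:
    """Deterministic category for one reaction's score under one co-factor."""
    if reaction_id in rules.target:
        return Category.TARGET
    if reaction_id in rules.biomass:
        return Category.BIOMASS
    waste_key = cofactor.name if cofactor.name in rules.waste else _pool_key(cofactor, rules)
    if waste_key and reaction_id in rules.waste[waste_key]:
        return Category.WASTE
    return Category.PRODUCTION if score > 0 else Category.MAINTENANCE


def _pool_key(cofactor: CofactorSpec, rules: CategoryRules) -> str | None:
    # split NADH / NADPH specs reuse the pooled NAD(P)H waste list
    if set(cofactor.members) <= {"nadh_c", "nadph_c"} and "NAD(P)H" in rules.waste:
        return "NAD(P)H"
    return None


@dataclass
class CofactorProfile:
    """Per-co-factor category totals of one flux distribution."""

    scores: pd.DataFrame  # columns: cofactor, reaction, score, category
    variant: str = ""
    condition: str = ""

    def category_totals(self, cofactor: str) -> pd.Series:
        sub = self.scores[self.scores["cofactor"] == cofactor]
        totals = sub.groupby("category")["score"].sum()
        return totals.reindex([c.value for c in Category], fill_value=0.0)

    def total_production(self, cofactor: str) -> float:
        """Sum of positive scores outside the target category."""
        sub = self.scores[
            (self.scores["cofactor"] == cofactor)
            & (self.scores["score"] > 0)
            & (self.scores["category"] != Category.TARGET.value)
        ]
        return float(sub["score"].sum())

    def total_positive(self, cofactor: str) -> float:
        sub = self.scores[(self.scores["cofactor"] == cofactor) & (self.scores["score"] > 0)]
        return float(sub["score"].sum())

    def closure(self, cofactor: str) -> float:
        """Signed sum of all scores; zero for a mass-balanced distribution."""
        return float(self.scores.loc[self.scores["cofactor"] == cofactor, "score"].sum())

    def fractions(self, cofactor: str) -> pd.Series:
        """Category nets as fractions of total production."""
        prod = self.total_production(cofactor)
        totals = self.category_totals(cofactor)
        if prod <= 0:
            return totals * float("nan")
        return totals / prod

    def waste_fraction(self, cofactor: str = "ATP",
                       reactions: tuple[str, ...] = ("ATPM", "ADK1")) -> float:
        """Fraction of total production consumed by the named reactions."""
        sub = self.scores[
            (self.scores["cofactor"] == cofactor)
            & (self.scores["reaction"].isin(reactions))
            & (self.scores["score"] < 0)
        ]
        consumed = -float(sub["score"].sum())
        prod = self.total_positive(cofactor)
        return consumed / prod if prod else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cof in self.scores["cofactor"].unique():
            totals = self.category_totals(cof)
            prod = self.total_production(cof)
            for cat, net in totals.items():
                rows.append({
                    "cofactor": cof, "category": cat, "net_flux": net,
                    "fraction": net / prod if prod else float("nan"),
                })
        return pd.DataFrame(rows)


def assemble_profile(
    network: cobra.Model,
    fluxes: FluxDistribution,
    rules: CategoryRules,
    cofactors=DEFAULT_COFACTORS,
    zero_tolerance: float = 1e-12,
) -> CofactorProfile:
    """Score and classify every co-factor-carrying reaction of a solution."""
    known = {r.id for r in network.reactions}
    for name, ids in list(rules.waste.items()):
        unknown = [i for i in ids if i not in known]
        if unknown:
            logger.warning("waste rule ids absent from %s: %s", network.id, unknown)
    rows = []
    for cof in cofactors:
        members = [network.metabolites.get_by_id(m) for m in cof.members
                   if network.metabolites.has_id(m)]
        touching = {r for m in members for r in m.reactions}
        for rxn in touching:
            score = cofactor_flux_score(rxn, fluxes[rxn.id], cof)
            if abs(score) <= zero_tolerance:
                continue
            cat = classify_reaction(rxn.id, cof, score, rules)
            rows.append({
                "cofactor": cof.name, "reaction": rxn.id,
                "score": score, "category": cat.value,
            })
    frame = pd.DataFrame(rows, columns=["cofactor", "reaction", "score", "category"])
    return CofactorProfile(frame, variant=fluxes.variant, condition=fluxes.condition)


def ppp_share(network: cobra.Model, fluxes: FluxDistribution,
              rules: CategoryRules | None = None,
              cofactor: CofactorSpec = DEFAULT_COFACTORS[1]) -> float:
    """Share of total NAD(P)H production contributed by the oxidative PPP.

    The PPP dehydrogenases keep their waste classification; their positive
    scores still count toward the production total.
    """
    rules = rules or load_category_rules()
    profile = assemble_profile(network, fluxes, rules, cofactors=(cofactor,))
    total = profile.total_positive(cofactor.name)
    sub = profile.scores[
        (profile.scores["reaction"].isin(rules.ppp_production))
        & (profile.scores["score"] > 0)
    ]
    return float(sub["score"].sum()) / total if total else float("nan")


def carbon_yield(
    network: cobra.Model,
    fluxes: FluxDistribution,
    target_metabolite: str,
    glucose_exchange: str = "EX_glc__D_e",
) -> float:
    """Product carbon efflux as a percentage of glucose carbon influx."""
    uptake = -fluxes[glucose_exchange]
    if abs(uptake) < 1e-12:
        raise ValueError("glucose uptake flux is zero; carbon yield undefined")
    met = network.metabolites.get_by_id(target_metabolite)
    carbons = met.elements.get("C", 0)
    sinks = [r for r in met.reactions if not r.products and met in r.reactants]
    if not sinks:
        raise ValueError(f"no sink reaction drains {target_metabolite!r}")
    efflux = sum(fluxes[r.id] for r in sinks)
    return 100.0 * carbons * efflux / (6.0 * uptake)
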