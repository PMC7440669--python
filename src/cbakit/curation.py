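"""Iterative futile-cycle detection and capping against a wild-type reference.

Engineered models burn their co-factor surplus through high-flux cycle pairs
(phosphofructokinase/fructose-bisphosphatase, PEP carboxylase/carboxykinase,
pyruvate kinase/PEP synthase, the two transhydrogenases, the malic enzymes,
the glutamine cycle, succinate dehydrogenase/fumarate reductase, and reversal
of ATP synthase).  Curation first caps the maintenance reaction (ATPM) at the
wild-type value, then repeatedly re-optimises, compares candidate fluxes with
the wild-type flux envelope and caps the designated cycle member to the
wild-type flux (zero when the wild type leaves it inactive), until no cycle
remains.

Because the ATP-spilling optimum is often degenerate, a solution vector alone
can hide an escape route in an alternate vertex; after the solution scan
comes up empty the candidate set is probed by flux variability at the fixed
optimum, which is vertex-independent.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import yaml

from .core_model import ATPM_ID, DEFAULT_NGAM
from .solvers import FluxDistribution, InfeasibleModelError, flux_variability, optimize_pfba

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CycleCandidate:
    """A cycle family: the reaction that gets capped plus its loop partners."""

    cap: str
    partners: tuple[str, ...]
    cofactor: str


@dataclass
class FutileCycleReport:
    members: tuple[str, ...]
    cofactor: str
    cycle_flux: float
    capped_reaction: str
    iteration: int = -1


@dataclass
class CapRecord:
    iteration: int
    reaction: str
    old_bounds: tuple[float, float]
    new_bounds: tuple[float, float]
    wt_flux: float
    source: str  # 'solution' | 'probe' | 'atpm'
    rolled_back: bool = False


@dataclass
class CurationLog:
    caps: list[CapRecord] = field(default_factory=list)
    status: str = "running"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([vars(c) for c in self.caps])


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("cbakit") / "data" / name)


def load_curation_config(path: str | Path | None = None) -> dict:
    raw = yaml.safe_load(Path(path or _data_path("curation.yml")).read_text())
    raw["candidates"] = tuple(
        CycleCandidate(c["cap"], tuple(c.get("partners", ())), c["cofactor"])
        for c in raw["candidates"]
    )
    return raw


def cap_atpm(network: cobra.Model, limit: float = DEFAULT_NGAM) -> cobra.Model:
    """Return a copy with the maintenance reaction capped at ``limit``."""
    if not network.reactions.has_id(ATPM_ID):
        raise ValueError("model has no ATPM reaction")
    model = network.copy()
    rxn = model.reactions.get_by_id(ATPM_ID)
    rxn.bounds = (min(rxn.lower_bound, limit), limit)
    return model


def _envelope_violation(flux: float, wt_flux: float, threshold: float) -> float:
    """How far a flux sits outside the wild type's directional envelope."""
    lo = min(0.0, wt_flux) - threshold
    hi = max(0.0, wt_flux) + threshold
    return max(flux - hi, lo - flux, 0.0)


def detect_futile_cycles(
    engineered: FluxDistribution,
    wild_type: FluxDistribution,
    candidates: tuple[CycleCandidate, ...] | None = None,
    threshold: float | None = None,
) -> list[FutileCycleReport]:
    """Candidate cycle members whose flux escapes the wild-type envelope.

    Reports are ordered by dissipated flux (largest first), ties broken by
    reaction id.
    """
    config = load_curation_config()
    candidates = candidates if candidates is not None else config["candidates"]
    threshold = config["threshold"] if threshold is None else threshold
    orphaned = set(wild_type.fluxes.index) - set(engineered.fluxes.index)
    if orphaned:
        raise ValueError(
            f"engineered distribution misses reference reactions: {sorted(orphaned)[:5]}"
        )
    known = set(engineered.fluxes.index) & set(wild_type.fluxes.index)
    reports = []
    for cand in candidates:
        if cand.cap not in known:
            if cand.cap in missing:
                logger.debug("candidate %s absent from one distribution", cand.cap)
            continue
        violation = _envelope_violation(
            engineered[cand.cap], wild_type.fluxes.get(cand.cap, 0.0), threshold
        )
        if violation > 0:
            reports.append(FutileCycleReport(
                members=(cand.cap, *[p for p in cand.partners if p in known]),
                cofactor=cand.cofactor,
                cycle_flux=violation,
                capped_reaction=cand.cap,
            ))
    reports.sort(key=lambda r: (-r.cycle_flux, r.capped_reaction))
    return reports


def _objective_id(model) -> str:
    ids = [r.id for r in model.reactions if r.objective_coefficient]
    return ids[0] if len(ids) == 1 else ""


def _probe_candidates(model, wt_fluxes, candidates, threshold):
    """Vertex-independent escape detection: maximise/minimise each candidate
    at the fixed optimum and test the wild-type envelope."""
    ids = [c.cap for c in candidates if model.reactions.has_id(c.cap)]
    if not ids:
        return []
    ranges = flux_variability(model, fraction_of_optimum=1.0, reactions=ids)
    hits = []
    for cand in candidates:
        if cand.cap not in ranges.ranges.index:
            continue
        wt = wt_fluxes.get(cand.cap, 0.0)
        v = max(
            _envelope_violation(ranges.ranges.loc[cand.cap, "maximum"], wt, threshold),
            _envelope_violation(ranges.ranges.loc[cand.cap, "minimum"], wt, threshold),
        )
        if v > 0:
            hits.append(FutileCycleReport(
                members=(cand.cap, *cand.partners), cofactor=cand.cofactor,
                cycle_flux=v, capped_reaction=cand.cap,
            ))
    hits.sort(key=lambda r: (-r.cycle_flux, r.capped_reaction))
    return hits


def curate_model(
    network: cobra.Model,
    wt_reference: FluxDistribution,
    objective: str | None = None,
    max_iterations: int = 30,
    threshold: float | None = None,
    atpm_limit: float | None = None,
    candidates: tuple[CycleCandidate, ...] | None = None,
    probe: bool = True,
) -> tuple[cobra.Model, CurationLog, FluxDistribution]:
    """Run the iterative detect-and-cap loop until no futile cycle remains.

    Returns the curated model, the audit log and the final pFBA solution.
    """
    config = load_curation_config()
    candidates = candidates if candidates is not None else config["candidates"]
    threshold = config["threshold"] if threshold is None else threshold
    atpm_limit = config["atpm_cap"] if atpm_limit is None else atpm_limit

    model = network.copy()
    if objective is not None:
        model.objective = objective
    log = CurationLog()

    atpm = model.reactions.get_by_id(ATPM_ID)
    old = atpm.bounds
    model = cap_atpm(model, atpm_limit)
    log.caps.append(CapRecord(0, ATPM_ID, old, model.reactions.get_by_id(ATPM_ID).bounds,
                              wt_reference.fluxes.get(ATPM_ID, atpm_limit), "atpm"))

    # Curating the reference condition itself (same objective as the
    # reference solution) needs no solution-space probing: the probe exists
    # to catch surplus-dissipating alternate vertices of production optima.
    is_reference = _objective_id(model) == wt_reference.objective_id
    solution = optimize_pfba(model)
    for iteration in range(1, max_iterations + 1):
        found = detect_futile_cycles(solution, wt_reference, candidates, threshold)
        source = "solution"
        if not found and probe and not is_reference:
            found = _probe_candidates(model, wt_reference.fluxes, candidates, threshold)
            source = "probe"
        if not found:
            log.status = "converged"
            break
        report = found[0]
        report.iteration = iteration
        rxn = model.reactions.get_by_id(report.capped_reaction)
        wt_flux = float(wt_reference.fluxes.get(report.capped_reaction, 0.0))
        old_bounds = rxn.bounds
        rxn.upper_bound = max(0.0, wt_flux)
        rxn.lower_bound = max(rxn.lower_bound, min(0.0, wt_flux))
        record = CapRecord(iteration, rxn.id, old_bounds, rxn.bounds, wt_flux, source)
        try:
            solution = optimize_pfba(model)
        except InfeasibleModelError:
            rxn.bounds = old_bounds
            record.rolled_back = True
            log.caps.append(record)
            logger.warning("cap on %s made the model infeasible; rolled back", rxn.id)
            solution = optimize_pfba(model)
            continue
        log.caps.append(record)
        logger.info("iteration %d: capped %s to %s (cycle %s, %s)",
                    iteration, rxn.id, rxn.bounds, report.members, source)
    else:
        log.status = "max-iterations"
    return model, log, solution
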