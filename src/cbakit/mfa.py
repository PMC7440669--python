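"""Flux-measurement (13C-MFA shaped) datasets as bound constraints.

A :class:`FluxDataset` is a reaction-by-strain table of central-carbon fluxes:
rows are measured reactions (possibly isozyme families such as pfkA/pfkB that
map onto a single model reaction), columns are a wild type (possibly
replicated) plus single-knockout strains.  Formatting collapses isozyme
families and wild-type replicates, restricts rows to model reactions and
rescales every strain to the model's glucose uptake.  The per-reaction
min/max across strains then becomes a :class:`~cbakit.solvers.FluxRangeSet`
that can be applied as hard bounds, or compared against FVA and MOMA ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import cobra
import numpy as np
import pandas as pd

from .solvers import FluxDistribution, FluxRangeSet, InfeasibleModelError, moma_knockout

logger = logging.getLogger(__name__)

GLUCOSE_ROW = "GLC_uptake"
MODEL_UPTAKE = 10.0


@dataclass
class FluxDataset:
    """Reaction x strain flux table plus formatting metadata."""

    data: pd.DataFrame
    glucose_row: str = GLUCOSE_ROW
    wt_columns: tuple[str, ...] = ("WT",)
    isozyme_map: dict[str, str] = field(default_factory=dict)
    sign_map: dict[str, float] = field(default_factory=dict)
    formatted: bool = False

    def copy(self) -> "FluxDataset":
        return replace(self, data=self.data.copy(),
                       isozyme_map=dict(self.isozyme_map),
                       sign_map=dict(self.sign_map))


def format_flux_dataset(raw: FluxDataset, network: cobra.Model,
                        model_uptake: float = MODEL_UPTAKE) -> FluxDataset:
    """Collapse isozymes and replicates, restrict to model reactions and
    normalise all strains to the model glucose uptake.

    Idempotent: formatting an already-formatted dataset returns it unchanged.
    """
    if raw.formatted:
        return raw
    if raw.glucose_row not in raw.data.index:
        raise ValueError(f"dataset lacks glucose-uptake row {raw.glucose_row!r}")
    df = raw.data.copy()

    # (i) isozyme families -> single model reaction (mean over members)
    if raw.isozyme_map:
        grouped = df.rename(index=raw.isozyme_map)
        df = grouped.groupby(level=0).mean()

    # (ii) wild-type replicate columns -> one WT column
    replicates = [c for c in raw.wt_columns if c in df.columns]
    if not replicates:
        raise ValueError("no wild-type column found")
    wt = df[replicates].mean(axis=1)
    df = df.drop(columns=replicates)
    df.insert(0, "WT", wt)

    # (iii) normalise to the model's glucose uptake
    uptake = df.loc[raw.glucose_row]
    if (uptake.abs() < 1e-12).any():
        raise ValueError("zero glucose uptake in at least one strain")
    df = df * (model_uptake / uptake)

    # (iv) sign convention and restriction to model reactions
    keep = [r for r in df.index if r == raw.glucose_row or network.reactions.has_id(r)]
    dropped = sorted(set(df.index) - set(keep))
    if dropped:
        logger.info("dropping %d rows absent from the model: %s", len(dropped), dropped)
    df = df.loc[keep]
    for rid, sign in raw.sign_map.items():
        if rid in df.index:
            df.loc[rid] *= sign
    return FluxDataset(df, glucose_row=raw.glucose_row, wt_columns=("WT",),
                       formatted=True)


def extract_ranges(dataset: FluxDataset) -> FluxRangeSet:
    """Per-reaction [min, max] across all strain columns."""
    df = dataset.data.drop(index=[dataset.glucose_row], errors="ignore")
    frame = pd.DataFrame({
        "minimum": df.min(axis=1),
        "maximum": df.max(axis=1),
    })
    return FluxRangeSet(frame, provenance="MFA")


def apply_ranges(network: cobra.Model, ranges: FluxRangeSet) -> cobra.Model:
    """Return a copy with measured [min, max] installed as hard bounds."""
    model = network.copy()
    for rid, row in ranges.ranges.iterrows():
        if not model.reactions.has_id(rid):
            raise ValueError(f"range refers to unknown reaction {rid!r}")
        model.reactions.get_by_id(rid).bounds = (float(row["minimum"]), float(row["maximum"]))
    if np.isnan(model.slim_optimize(error_value=float("nan"))):
        binding = _infeasibility_report(network, ranges)
        raise InfeasibleModelError(
            f"model infeasible after applying ranges; suspect constraints: {binding}"
        )
    return model


def _infeasibility_report(network: cobra.Model, ranges: FluxRangeSet) -> list[str]:
    """Greedy scan for the constraints that break feasibility."""
    model = network.copy()
    binding = []
    for rid, row in ranges.ranges.iterrows():
        if not model.reactions.has_id(rid):
            continue
        old = model.reactions.get_by_id(rid).bounds
        model.reactions.get_by_id(rid).bounds = (float(row["minimum"]), float(row["maximum"]))
        if np.isnan(model.slim_optimize(error_value=float("nan"))):
            binding.append(rid)
            model.reactions.get_by_id(rid).bounds = old
    return binding


def moma_range_scan(
    network: cobra.Model,
    reference: FluxDistribution,
    knockouts: list[str],
    measured_reactions: list[str] | None = None,
) -> FluxRangeSet:
    """[min, max] per measured reaction over the MOMA solutions of all
    knockouts plus the reference itself."""
    measured = measured_reactions or [r for r in reference.fluxes.index]
    vectors = [reference.fluxes]
    for ko in knockouts:
        try:
            sol = moma_knockout(network, reference, ko)
        except InfeasibleModelError:
            logger.warning("knockout %s infeasible; skipped in MOMA scan", ko)
            continue
        vectors.append(sol.fluxes)
    stack = pd.concat(vectors, axis=1)
    stack = stack.loc[[r for r in measured if r in stack.index]]
    frame = pd.DataFrame({
        "minimum": stack.min(axis=1),
        "maximum": stack.max(axis=1),
    })
    return FluxRangeSet(frame, provenance="MOMA-scan")


def compare_ranges(a: FluxRangeSet, b: FluxRangeSet,
                   labels: tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Width, winner and overlap per shared reaction."""
    shared = a.ranges.index.intersection(b.ranges.index)
    if shared.empty:
        raise ValueError("range sets share no reaction ids")
    la, lb = labels
    rows = []
    for rid in shared:
        amin, amax = a.ranges.loc[rid]
        bmin, bmax = b.ranges.loc[rid]
        wa, wb = amax - amin, bmax - bmin
        if np.isclose(wa, wb):
            wider = "equal"
        else:
            wider = la if wa > wb else lb
        lo, hi = max(amin, bmin), min(amax, bmax)
        rows.append({
            "reaction": rid, f"width_{la}": wa, f"width_{lb}": wb,
            "wider": wider,
            "overlap_min": lo if lo <= hi else np.nan,
            "overlap_max": hi if lo <= hi else np.nan,
        })
    return pd.DataFrame(rows).set_index("reaction")
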