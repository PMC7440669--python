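"""Tab-separated report writers and readers.

Everything is written as plain TSV so results diff cleanly between runs.
Every table carries a comment header recording the tool version, solver
settings and (when given) the configuration hash, for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .solvers import SOLVER_TOLERANCES, FluxDistribution, FluxRangeSet


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header(kind: str, meta: dict | None = None) -> str:
    meta = dict(meta or {})
    meta.setdefault("tolerances", SOLVER_TOLERANCES)
    parts = [f"# cbakit {kind}"]
    for key, value in meta.items():
        parts.append(f"# {key}: {value}")
    return "\n".join(parts) + "\n"


def write_fluxes(dist: FluxDistribution, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    meta = {"method": dist.method, "variant": dist.variant,
            "objective": f"{dist.objective_id}={dist.objective_value:.6f}",
            "status": dist.status, **(meta or {})}
    with open(path, "w") as fh:
        fh.write(_header("flux distribution", meta))
        dist.to_frame().to_csv(fh, sep="\t")
    return path


def read_fluxes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_ranges(ranges: FluxRangeSet, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    meta = {"provenance": ranges.provenance,
            "fraction_of_optimum": ranges.fraction_of_optimum, **(meta or {})}
    with open(path, "w") as fh:
        fh.write(_header("flux ranges", meta))
        ranges.ranges.to_csv(fh, sep="\t")
    return path


def read_ranges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_table(frame: pd.DataFrame, path: str | Path, kind: str,
                meta: dict | None = None, index: bool = True) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(kind, meta))
        frame.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
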