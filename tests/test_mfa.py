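"""Measured-flux dataset formatting, range extraction and application."""

import numpy as np
import pandas as pd
import pytest

from cbakit.fixtures import MEASURED_REACTIONS, synthetic_flux_table
from cbakit.mfa import (
    FluxDataset,
    apply_ranges,
    compare_ranges,
    extract_ranges,
    format_flux_dataset,
    moma_range_scan,
)
from cbakit.solvers import FluxRangeSet, optimize_pfba


def _tiny_dataset():
    data = pd.DataFrame(
        {
            "WT_1": [10.0, 5.0, 1.0, 4.0],
            "WT_2": [10.0, 5.0, 1.0, 4.0],
            "d_x": [10.0, 2.0, 6.0, 4.0],
        },
        index=["GLC_uptake", "pfkA", "pfkB", "GAPD"],
    )
    return FluxDataset(data, wt_columns=("WT_1", "WT_2"),
                       isozyme_map={"pfkA": "PFK", "pfkB": "PFK"})


def test_isozyme_families_are_averaged(catalog):
    formatted = format_flux_dataset(_tiny_dataset(), catalog["WT"])
    # pfkA=5, pfkB=1 average to a single PFK row of 3
    assert formatted.data.loc["PFK", "WT"] == pytest.approx(3.0)
    assert formatted.data.loc["PFK", "d_x"] == pytest.approx(4.0)
    assert "pfkA" not in formatted.data.index


def test_formatting_is_idempotent(catalog, toy):
    once = format_flux_dataset(toy.flux_table, catalog["WT"])
    twice = format_flux_dataset(once, catalog["WT"])
    pd.testing.assert_frame_equal(once.data, twice.data)


def test_reference_shape_keeps_fifteen_reactions(catalog, toy):
    formatted = format_flux_dataset(toy.flux_table, catalog["WT"])
    reactions = [r for r in formatted.data.index if r != formatted.glucose_row]
    assert sorted(reactions) == sorted(MEASURED_REACTIONS)
    assert len(reactions) == 15


def test_normalisation_scales_uptake_to_model(catalog, toy):
    formatted = format_flux_dataset(toy.flux_table, catalog["WT"])
    assert np.allclose(formatted.data.loc[formatted.glucose_row], 10.0)


def test_missing_uptake_row_errors(catalog):
    ds = _tiny_dataset()
    ds.data = ds.data.drop(index=["GLC_uptake"])
    with pytest.raises(ValueError, match="glucose-uptake"):
        format_flux_dataset(ds, catalog["WT"])


def test_extract_min_max():
    frame = pd.DataFrame({"a": [3.0, 2.0], "b": [5.0, 2.0], "c": [4.0, 2.0]},
                         index=["PLASTIC", "RIGID"])
    ranges = extract_ranges(FluxDataset(frame, glucose_row="none"))
    assert tuple(ranges.ranges.loc["PLASTIC"]) == (3.0, 5.0)
    assert tuple(ranges.ranges.loc["RIGID"]) == (2.0, 2.0)


def test_fixture_has_rigid_and_plastic_rows(catalog, toy):
    formatted = format_flux_dataset(toy.flux_table, catalog["WT"])
    widths = extract_ranges(formatted).widths
    rigid = widths[["ME1", "ME2", "PPCK"]].max()
    plastic = widths[["PFK", "GAPD", "PGK"]].min()
    assert rigid < plastic


def test_apply_ranges_identity_and_fixed(wt_aerobic):
    empty = FluxRangeSet(pd.DataFrame(columns=["minimum", "maximum"]), "MFA")
    same = apply_ranges(wt_aerobic, empty)
    assert all(
        same.reactions.get_by_id(r.id).bounds == r.bounds for r in wt_aerobic.reactions
    )
    fixed = FluxRangeSet(
        pd.DataFrame({"minimum": [5.0], "maximum": [5.0]}, index=["PGI"]), "MFA"
    )
    pinned = apply_ranges(wt_aerobic, fixed)
    sol = optimize_pfba(pinned)
    assert sol.fluxes["PGI"] == pytest.approx(5.0, abs=1e-6)


def test_apply_ranges_reports_infeasibility(wt_aerobic):
    impossible = FluxRangeSet(
        pd.DataFrame({"minimum": [900.0], "maximum": [1000.0]}, index=["PGI"]), "MFA"
    )
    with pytest.raises(Exception, match="PGI"):
        apply_ranges(wt_aerobic, impossible)


def test_unknown_range_id_errors(wt_aerobic):
    bogus = FluxRangeSet(
        pd.DataFrame({"minimum": [0.0], "maximum": [1.0]}, index=["NOPE"]), "MFA"
    )
    with pytest.raises(ValueError, match="NOPE"):
        apply_ranges(wt_aerobic, bogus)


def test_moma_scan_contains_reference_flux(wt_aerobic, wt_aerobic_solution):
    kos = ["PGI", "GND", "PPC"]
    ranges = moma_range_scan(wt_aerobic, wt_aerobic_solution, kos,
                             measured_reactions=kos)
    for rid in kos:
        ref = wt_aerobic_solution.fluxes[rid]
        assert ranges.ranges.loc[rid, "minimum"] <= ref + 1e-6
        assert ranges.ranges.loc[rid, "maximum"] >= ref - 1e-6


def test_moma_scan_empty_knockouts_degenerate(wt_aerobic, wt_aerobic_solution):
    ranges = moma_range_scan(wt_aerobic, wt_aerobic_solution, [],
                             measured_reactions=["PGI", "PFK"])
    assert (ranges.widths.abs() < 1e-9).all()


def test_compare_ranges():
    a = FluxRangeSet(pd.DataFrame({"minimum": [0.0], "maximum": [10.0]}, index=["R"]), "FVA")
    b = FluxRangeSet(pd.DataFrame({"minimum": [2.0], "maximum": [3.0]}, index=["R"]), "MFA")
    table = compare_ranges(a, b, labels=("fva", "mfa"))
    assert table.loc["R", "wider"] == "fva"
    assert table.loc["R", "overlap_min"] == 2.0
    assert table.loc["R", "overlap_max"] == 3.0
    same = compare_ranges(a, a, labels=("x", "y"))
    assert (same["wider"] == "equal").all()


def test_compare_disjoint_errors():
    a = FluxRangeSet(pd.DataFrame({"minimum": [0.0], "maximum": [1.0]}, index=["A"]), "FVA")
    b = FluxRangeSet(pd.DataFrame({"minimum": [0.0], "maximum": [1.0]}, index=["B"]), "MFA")
    with pytest.raises(ValueError, match="share no"):
        compare_ranges(a, b)


def test_round_trip_ranges_through_own_extraction(catalog, toy):
    formatted = format_flux_dataset(toy.flux_table, catalog["WT"])
    first = extract_ranges(formatted)
    second = extract_ranges(format_flux_dataset(formatted, catalog["WT"]))
    pd.testing.assert_frame_equal(first.ranges, second.ranges)


def test_synthetic_table_is_seed_deterministic():
    a = synthetic_flux_table(seed=42)
    b = synthetic_flux_table(seed=42)
    pd.testing.assert_frame_equal(a.data, b.data)
    c = synthetic_flux_table(seed=43)
    assert not a.data.equals(c.data)
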