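"""Tests for event merging, recurrent-region detection and filtering."""

import math

import numpy as np
import pandas as pd
import pytest

from updtrio.events import EVENT_COLUMNS, llr_p_value
from updtrio.postprocess import (
    collapse_events,
    filter_events,
    identify_recurrent_regions,
    mark_recurrent_regions,
    read_regions_bed,
    write_regions_bed,
)


def make_events(rows):
    """rows: (sample, chrom, start, end, state[, extras dict])"""
    out = []
    for row in rows:
        sample, chrom, start, end, state, *rest = row
        rec = {
            "sample_id": sample,
            "chromosome": chrom,
            "start": start,
            "end": end,
            "state": state,
            "n_snps": 10,
            "n_mendelian_errors": 2,
            "log_likelihood_ratio": 5.0,
            "p_value": llr_p_value(5.0),
            "depth_ratio_proband": 1.0,
            "depth_ratio_father": 1.0,
            "depth_ratio_mother": 1.0,
        }
        if rest:
            rec.update(rest[0])
        out.append(rec)
    return pd.DataFrame(out, columns=EVENT_COLUMNS)


class TestCollapseEvents:
    def test_same_type_same_chrom_merge_to_span(self):
        ev = make_events(
            [
                ("s", "chr1", 100, 200, "father_isodisomy"),
                ("s", "chr1", 300, 400, "father_isodisomy"),
            ]
        )
        merged = collapse_events(ev)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row["start"], row["end"]) == (100, 400)
        assert row["n_snps"] == 20 and row["n_mendelian_errors"] == 4
        assert row["log_likelihood_ratio"] == pytest.approx(10.0)
        assert row["p_value"] == pytest.approx(llr_p_value(10.0))
        assert math.isnan(row["depth_ratio_proband"])  # no trio supplied

    def test_different_types_never_merge(self):
        ev = make_events(
            [
                ("s", "chr1", 100, 200, "father_isodisomy"),
                ("s", "chr1", 300, 400, "mother_heterodisomy"),
            ]
        )
        merged = collapse_events(ev)
        assert len(merged) == 2
        pd.testing.assert_frame_equal(
            merged.sort_values("start").reset_index(drop=True),
            ev.sort_values("start").reset_index(drop=True),
        )

    def test_single_event_unchanged_and_idempotent(self):
        ev = make_events([("s", "chr2", 5, 9, "mother_isodisomy")])
        once = collapse_events(ev)
        pd.testing.assert_frame_equal(once, ev)
        twice = collapse_events(once)
        pd.testing.assert_frame_equal(twice, once)

    def test_idempotent_after_merging(self):
        ev = make_events(
            [
                ("s", "chr1", 100, 200, "father_isodisomy"),
                ("s", "chr1", 300, 400, "father_isodisomy"),
                ("s", "chr2", 10, 20, "father_isodisomy"),
            ]
        )
        once = collapse_events(ev)
        twice = collapse_events(once)
        pd.testing.assert_frame_equal(twice, once)

    def test_multi_sample_table_rejected(self):
        ev = make_events(
            [
                ("a", "chr1", 1, 2, "father_isodisomy"),
                ("b", "chr1", 3, 4, "father_isodisomy"),
            ]
        )
        with pytest.raises(ValueError):
            collapse_events(ev)


def brute_force_recurrent(events, min_samples):
    """Per-base distinct-sample counting (oracle for small coordinates)."""
    regions = []
    for chrom in events["chromosome"].unique():
        grp = events[events["chromosome"] == chrom]
        hi = int(grp["end"].max())
        counts = []
        for pos in range(1, hi + 2):
            n = grp.loc[
                (grp["start"] <= pos) & (grp["end"] >= pos), "sample_id"
            ].nunique()
            counts.append(n >= min_samples)
        start = None
        for pos, ok in enumerate(counts, start=1):
            if ok and start is None:
                start = pos
            elif not ok and start is not None:
                regions.append((chrom, start, pos - 1))
                start = None
        if start is not None:
            regions.append((chrom, start, hi + 1))
    return regions


class TestIdentifyRecurrentRegions:
    def test_full_overlap_across_three_samples(self):
        ev = make_events(
            [(s, "chr1", 1000, 2000, "father_isodisomy") for s in "abc"]
        )
        regions = identify_recurrent_regions(ev, min_samples=3)
        assert len(regions) == 1
        row = regions.iloc[0]
        assert (row["start"], row["end"], row["n_samples"]) == (1000, 2000, 3)

    def test_disjoint_events_give_no_region(self):
        ev = make_events(
            [
                ("a", "chr1", 1, 10, "father_isodisomy"),
                ("b", "chr1", 20, 30, "father_isodisomy"),
            ]
        )
        assert identify_recurrent_regions(ev, min_samples=2).empty

    def test_staggered_overlap_region(self):
        ev = make_events(
            [
                ("a", "chr1", 1, 10, "father_isodisomy"),
                ("b", "chr1", 5, 15, "father_isodisomy"),
                ("c", "chr1", 8, 20, "father_isodisomy"),
            ]
        )
        regions = identify_recurrent_regions(ev, min_samples=3)
        assert len(regions) == 1
        row = regions.iloc[0]
        assert (row["start"], row["end"], row["n_samples"]) == (8, 10, 3)

    def test_duplicate_events_of_one_sample_count_once(self):
        ev = make_events(
            [
                ("a", "chr1", 1, 10, "father_isodisomy"),
                ("a", "chr1", 5, 15, "mother_isodisomy"),
                ("b", "chr1", 8, 12, "father_isodisomy"),
            ]
        )
        regions = identify_recurrent_regions(ev, min_samples=2)
        assert len(regions) == 1
        assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (8, 12)

    def test_matches_per_base_brute_force_on_random_toys(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 12))
            rows = []
            for i in range(n):
                s = int(rng.integers(1, 80))
                e = s + int(rng.integers(0, 40))
                rows.append(
                    (f"s{rng.integers(0, 6)}", "chr1", s, e,
                     "father_isodisomy")
                )
            ev = make_events(rows)
            for k in (2, 3):
                got = [
                    (r.chromosome, r.start, r.end)
                    for r in identify_recurrent_regions(
                        ev, min_samples=k
                    ).itertuples(index=False)
                ]
                assert got == brute_force_recurrent(ev, k)

    def test_raising_threshold_never_enlarges_regions(self, rng):
        rows = []
        for i in range(12):
            s = int(rng.integers(1, 60))
            rows.append((f"s{i % 5}", "chr1", s, s + int(rng.integers(5, 30)),
                         "father_isodisomy"))
        ev = make_events(rows)
        covered_prev = None
        for k in (2, 3, 4):
            regions = identify_recurrent_regions(ev, min_samples=k)
            covered = set()
            for r in regions.itertuples(index=False):
                covered.update(range(r.start, r.end + 1))
            if covered_prev is not None:
                assert covered <= covered_prev
            covered_prev = covered

    def test_default_threshold_is_two_for_small_cohorts(self):
        ev = make_events(
            [(s, "chr1", 1, 10, "father_isodisomy") for s in "ab"]
        )
        assert len(identify_recurrent_regions(ev)) == 1


class TestMarkRecurrentRegions:
    regions = pd.DataFrame(
        [{"chromosome": "chr1", "start": 100, "end": 200, "n_samples": 3}]
    )

    @pytest.mark.parametrize(
        "chrom,start,end,flag",
        [
            ("chr1", 120, 180, True),  # fully inside
            ("chr2", 120, 180, False),  # other chromosome
            ("chr1", 50, 100, True),  # shares exactly one base
            ("chr1", 200, 250, True),  # shares exactly one base
            ("chr1", 201, 250, False),  # adjacent, no shared base
        ],
    )
    def test_inclusive_overlap_convention(self, chrom, start, end, flag):
        ev = make_events([("s", chrom, start, end, "father_isodisomy")])
        marked = mark_recurrent_regions(ev, self.regions)
        assert bool(marked["recurrent"].iloc[0]) is flag
        # the rest of the table is unchanged
        pd.testing.assert_frame_equal(marked[EVENT_COLUMNS], ev)


class TestFilterEvents:
    def test_depth_deviation_drops_likely_cnvs(self):
        ev = make_events(
            [
                ("s", "chr1", 1, 10, "father_isodisomy"),
                ("s", "chr1", 20, 30, "father_isodisomy",
                 {"depth_ratio_proband": 1.6}),
                ("s", "chr1", 40, 50, "father_isodisomy",
                 {"depth_ratio_mother": float("nan")}),
            ]
        )
        kept = filter_events(ev, depth_bounds=(0.75, 1.25))
        assert list(kept["start"]) == [1]

    def test_min_snps_and_min_size(self):
        ev = make_events(
            [
                ("s", "chr1", 1, 5, "father_isodisomy", {"n_snps": 3}),
                ("s", "chr1", 10, 200, "father_isodisomy", {"n_snps": 50}),
            ]
        )
        kept = filter_events(ev, depth_bounds=None, min_snps=10, min_size=100)
        assert list(kept["start"]) == [10]

    def test_drop_recurrent_requires_marking(self):
        ev = make_events([("s", "chr1", 1, 5, "father_isodisomy")])
        with pytest.raises(ValueError):
            filter_events(ev, drop_recurrent=True)
        marked = mark_recurrent_regions(
            ev, TestMarkRecurrentRegions.regions
        )
        assert len(filter_events(marked, drop_recurrent=True)) == 1


def test_regions_bed_round_trip(tmp_path):
    regions = pd.DataFrame(
        [
            {"chromosome": "chr1", "start": 100, "end": 200, "n_samples": 4},
            {"chromosome": "chr2", "start": 1, "end": 9, "n_samples": 2},
        ]
    )
    path = tmp_path / "r.bed"
    write_regions_bed(regions, path)
    assert path.read_text().splitlines()[0] == "chr1\t99\t200\t4"
    back = read_regions_bed(path)
    pd.testing.assert_frame_equal(back, regions)
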