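"""Overlap counting and closest-distance tests, checked against a
brute-force all-pairs oracle (property-based) and the bedtools binary."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regionenrich import (
    ConfigurationError,
    EmptyTestError,
    IntervalSet,
    TestConfig,
    count_overlaps,
    mean_closest_distance,
    run_enrichment_test,
    write_bed,
)
from regionenrich.enrichment import closest_distances
from regionenrich.synthetic import make_intersect_fixture

from conftest import make_set

# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _qualifies(iv, tv, orientation, ov_fraction):
    if iv.chrom != tv.chrom:
        return False
    if orientation == "concordant" and iv.strand != tv.strand:
        return False
    if orientation == "discordant" and iv.strand == tv.strand:
        return False
    shared = min(iv.end, tv.end) - max(iv.start, tv.start)
    need = 1 if ov_fraction is None else max(1, math.ceil(ov_fraction * iv.length))
    return shared >= need


def brute_force_count(input_set, target, orientation="strandless", ov_fraction=None):
    return sum(
        1
        for iv in input_set
        if any(_qualifies(iv, tv, orientation, ov_fraction) for tv in target)
    )


def brute_force_distance(iv, target):
    best = math.inf
    for tv in target:
        if tv.chrom != iv.chrom:
            continue
        if min(iv.end, tv.end) > max(iv.start, tv.start):
            return 0.0
        best = min(best, max(tv.start - iv.end, iv.start - tv.end, 0))
    return best


@st.composite
def interval_sets(draw, max_n=50, stranded=True):
    n = draw(st.integers(1, max_n))
    recs = []
    for _ in range(n):
        chrom = draw(st.sampled_from(["chr1", "chr2"]))
        start = draw(st.integers(0, 500))
        length = draw(st.integers(1, 120))
        strand = draw(st.sampled_from(["+", "-"])) if stranded else "."
        recs.append((chrom, start, start + length, strand))
    return make_set(recs)


class TestCountOverlaps:
    def test_region_overlapping_three_targets_counts_once(self):
        inp = make_set([("chr1", 0, 300)])
        tgt = make_set([("chr1", 10, 20), ("chr1", 50, 60), ("chr1", 200, 400)])
        assert count_overlaps(inp, tgt, TestConfig()) == 1

    def test_disjoint_chromosomes_count_zero(self):
        inp = make_set([("chr1", 0, 100)])
        tgt = make_set([("chr9", 0, 100)])
        with pytest.warns(UserWarning, match="share no chromosome"):
            results = run_enrichment_test(
                inp, tgt, background=make_set([("chr1", 0, 100), ("chr1", 500, 600)]),
                config=TestConfig(n_randomizations=2),
            )
        assert results[0].real == 0

    def test_ov_fraction_gates_on_input_length(self):
        inp = make_set([("chr1", 0, 100)])
        tgt = make_set([("chr1", 90, 200)])
        assert count_overlaps(inp, tgt, TestConfig()) == 1  # 10 nt >= 1
        assert count_overlaps(inp, tgt, TestConfig(ov_fraction=0.5)) == 0  # 10 < 50
        assert count_overlaps(inp, tgt, TestConfig(ov_fraction=0.1)) == 1  # 10 >= 10

    def test_orientation_modes_on_stranded_data(self):
        inp = make_set([("chr1", 0, 100, "+"), ("chr1", 200, 300, "-")])
        tgt = make_set([("chr1", 50, 150, "+"), ("chr1", 250, 350, "+")])
        assert count_overlaps(inp, tgt, TestConfig(orientation="concordant")) == 1
        assert count_overlaps(inp, tgt, TestConfig(orientation="discordant")) == 1
        assert count_overlaps(inp, tgt, TestConfig(orientation="strandless")) == 2

    def test_orientation_requires_known_strands(self):
        inp = make_set([("chr1", 0, 100)])
        tgt = make_set([("chr1", 50, 150, "+")])
        with pytest.raises(ConfigurationError, match="strand"):
            count_overlaps(inp, tgt, TestConfig(orientation="concordant"))

    def test_exclusions_remove_input_regions_before_counting(self):
        inp = make_set([("chr1", 0, 100), ("chr1", 500, 600)])
        tgt = make_set([("chr1", 50, 550)])
        cfg = TestConfig(exclusions=make_set([("chr1", 0, 200)]))
        assert count_overlaps(inp, tgt, cfg) == 1

    def test_engineered_fixture_count(self):
        inp, _, tgt = make_intersect_fixture(
            n_input=60, n_background=200, n_target=300, n_overlap=17, seed=5
        )
        assert count_overlaps(inp, tgt, TestConfig()) == 17

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        inp=interval_sets(),
        tgt=interval_sets(),
        orientation=st.sampled_from(["strandless", "concordant", "discordant"]),
        ov_fraction=st.sampled_from([None, 0.1, 0.5, 1.0]),
    )
    def test_matches_brute_force_oracle(self, inp, tgt, orientation, ov_fraction):
        cfg = TestConfig(orientation=orientation, ov_fraction=ov_fraction)
        assert count_overlaps(inp, tgt, cfg) == brute_force_count(
            inp, tgt, orientation, ov_fraction
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(inp=interval_sets(), tgt=interval_sets())
    def test_count_bounds_and_strand_partition(self, inp, tgt):
        strandless = count_overlaps(inp, tgt, TestConfig())
        assert strandless <= len(inp)
        conc = count_overlaps(inp, tgt, TestConfig(orientation="concordant"))
        disc = count_overlaps(inp, tgt, TestConfig(orientation="discordant"))
        assert max(conc, disc) <= strandless

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(inp=interval_sets(max_n=20), tgt=interval_sets(max_n=20))
    def test_monotone_in_ov_fraction(self, inp, tgt):
        counts = [
            count_overlaps(inp, tgt, TestConfig(ov_fraction=f)) for f in (0.01, 0.25, 0.5, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClosestDistance:
    def test_overlap_counts_as_zero(self):
        inp = make_set([("chr1", 0, 100)])
        tgt = make_set([("chr1", 90, 200)])
        assert mean_closest_distance(inp, tgt, TestConfig(mode="closest")) == 0.0

    def test_nearest_edge_gap(self):
        inp = make_set([("chr1", 0, 100)])
        tgt = make_set([("chr1", 150, 160), ("chr1", 500, 600)])
        assert mean_closest_distance(inp, tgt, TestConfig(mode="closest")) == 50.0

    def test_touching_intervals_are_zero_apart(self):
        inp = make_set([("chr1", 0, 100)])
        tgt = make_set([("chr1", 100, 200)])
        assert mean_closest_distance(inp, tgt, TestConfig(mode="closest")) == 0.0

    def test_exclude_ov_skips_overlapping_targets(self):
        inp = make_set([("chr1", 0, 100)])
        tgt = make_set([("chr1", 50, 150), ("chr1", 300, 400)])
        cfg = TestConfig(mode="closest", exclude_ov=True)
        assert mean_closest_distance(inp, tgt, cfg) == 200.0

    def test_upstream_downstream_resolved_by_input_strand(self):
        # plus-strand input: upstream = lower coordinates
        inp_plus = make_set([("chr1", 1000, 1100, "+")])
        inp_minus = make_set([("chr1", 1000, 1100, "-")])
        tgt = make_set([("chr1", 800, 900, "+"), ("chr1", 1400, 1500, "+")])
        up = TestConfig(mode="closest", exclude_upstream=True)
        down = TestConfig(mode="closest", exclude_downstream=True)
        assert mean_closest_distance(inp_plus, tgt, up) == 300.0  # only downstream kept
        assert mean_closest_distance(inp_plus, tgt, down) == 100.0
        assert mean_closest_distance(inp_minus, tgt, up) == 100.0  # mirrored
        assert mean_closest_distance(inp_minus, tgt, down) == 300.0

    def test_regions_without_candidates_dropped_with_warning(self):
        inp = make_set([("chr1", 0, 100), ("chr5", 0, 100)])
        tgt = make_set([("chr1", 200, 300)])
        with pytest.warns(UserWarning, match="no candidate"):
            assert mean_closest_distance(inp, tgt, TestConfig(mode="closest")) == 100.0

    def test_all_dropped_is_empty_test_error(self):
        inp = make_set([("chr5", 0, 100)])
        tgt = make_set([("chr1", 200, 300)])
        with pytest.raises(EmptyTestError), warnings_ignored():
            mean_closest_distance(inp, tgt, TestConfig(mode="closest"))

    def test_invariant_to_target_duplication_and_order(self):
        inp = make_set([("chr1", 0, 100), ("chr1", 1000, 1100)])
        tgt = make_set([("chr1", 300, 400), ("chr1", 600, 700)])
        dup = tgt.concat(tgt)
        cfg = TestConfig(mode="closest")
        assert mean_closest_distance(inp, tgt, cfg) == mean_closest_distance(inp, dup, cfg)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(inp=interval_sets(max_n=25, stranded=False), tgt=interval_sets(max_n=25, stranded=False))
    def test_matches_brute_force_distances(self, inp, tgt):
        expected = [brute_force_distance(iv, tgt) for iv in inp]
        expected = [d for d in expected if math.isfinite(d)]
        if not expected:
            with pytest.raises(EmptyTestError), warnings_ignored():
                closest_distances(inp, tgt, TestConfig(mode="closest"))
            return
        with warnings_ignored():
            got = closest_distances(inp, tgt, TestConfig(mode="closest"))
        assert sorted(got.tolist()) == sorted(expected)


import contextlib
import warnings as _warnings


@contextlib.contextmanager
def warnings_ignored():
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        yield


# ---------------------------------------------------------------------------
# Independent binary oracle
# ---------------------------------------------------------------------------


@pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not on PATH")
def test_agrees_with_bedtools_on_random_sets(tmp_path, rng):
    recs_a = [("chr1", int(s), int(s) + int(l)) for s, l in
              zip(rng.integers(0, 50_000, 80), rng.integers(50, 500, 80))]
    recs_b = [("chr1", int(s), int(s) + int(l)) for s, l in
              zip(rng.integers(0, 50_000, 120), rng.integers(50, 500, 120))]
    inp, tgt = make_set(recs_a, "a.bed"), make_set(recs_b, "b.bed")
    a, b = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(inp, a)
    write_bed(tgt, b)
    # overlap count: input regions with >= 1 hit, counted once
    out = subprocess.run(
        ["bedtools", "intersect", "-a", str(a), "-b", str(b), "-u"],
        capture_output=True, text=True, check=True,
    )
    expected_count = len([ln for ln in out.stdout.splitlines() if ln])
    assert count_overlaps(inp, tgt, TestConfig()) == expected_count
    # closest distance per region
    out = subprocess.run(
        ["bedtools", "closest", "-a", str(a), "-b", str(b), "-d", "-t", "first"],
        capture_output=True, text=True, check=True,
    )
    # bedtools reports gap+1 for non-overlapping pairs (bookended = 1);
    # this package reports the nearest-edge gap (bookended = 0)
    expected = sorted(
        max(float(ln.split("\t")[-1]) - 1.0, 0.0) for ln in out.stdout.splitlines() if ln
    )
    got = sorted(closest_distances(inp, tgt, TestConfig(mode="closest")).tolist())
    assert got == expected


# ---------------------------------------------------------------------------
# Full randomization run
# ---------------------------------------------------------------------------


class TestRunEnrichment:
    def test_null_calibrated_when_input_is_background_like(self):
        """Input drawn from the background itself: |Z| < 2 nearly always."""
        inp, bg, tgt = make_intersect_fixture(
            n_input=200, n_background=800, n_target=1000, n_overlap=50,
            n_bg_extra_overlap=150, seed=9,  # same 25% overlap rate on both sides
        )
        hits = 0
        for s in range(10):
            r = run_enrichment_test(
                inp, tgt, background=bg, config=TestConfig(seed=s, n_randomizations=50)
            )[0]
            hits += abs(r.z) < 2
        assert hits >= 9

    def test_multiple_targets_one_row_each(self):
        inp, bg, tgt = make_intersect_fixture(
            n_input=50, n_background=200, n_target=300, n_overlap=10, seed=2
        )
        results = run_enrichment_test(
            inp, [tgt, tgt], background=bg, config=TestConfig(n_randomizations=10)
        )
        assert [r.target_label for r in results] == ["Target.bed", "Target.bed"]

    def test_at_gc_and_length_rows(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + seq + "\n")
        from pyfaidx import Fasta

        recs = [("chr1", i * 200, i * 200 + 50) for i in range(20)]
        inp = make_set(recs[:5], "in.bed")
        bg = make_set(recs, "bg.bed")
        tgt = make_set([("chr1", 0, 20000)], "t.bed")
        results = run_enrichment_test(
            inp, tgt, background=bg,
            config=TestConfig(n_randomizations=10, run_at_gc=True, run_length=True),
            genome=Fasta(str(fasta)),
        )
        labels = [(r.test_type, r.target_label) for r in results]
        assert labels == [
            ("strandless", "t.bed"),
            ("AT_GC", "AT"),
            ("AT_GC", "GC"),
            ("length", "length"),
        ]
        at_row = results[1]
        assert 0 <= at_row.real <= 1 and 0 <= at_row.random_mean <= 1

    def test_seeded_runs_reproducible(self):
        inp, bg, tgt = make_intersect_fixture(
            n_input=50, n_background=200, n_target=300, n_overlap=10, seed=2
        )
        r1 = run_enrichment_test(inp, tgt, background=bg, config=TestConfig(seed=42, n_randomizations=20))[0]
        r2 = run_enrichment_test(inp, tgt, background=bg, config=TestConfig(seed=42, n_randomizations=20))[0]
        assert r1.z == r2.z and np.array_equal(r1.null_values, r2.null_values)
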