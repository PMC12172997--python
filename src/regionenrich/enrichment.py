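"""The two primary test modes — intersect (overlap counting) and closest
(mean nearest-feature distance) — plus the optional AT/GC sequence-content
and length randomization tests.

Each test compares the input set's statistic against the same statistic
recomputed on randomized null sets (sampled from a user background or a
generated matched background) and reports a Z-score row per (target, type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._interval_ops import ChromIndex, build_index
from .errors import ConfigurationError, EmptyTestError
from .intervals import (
    STRAND_UNKNOWN,
    GenomicInterval,
    IntervalSet,
    at_gc_content,
    warn_if_disjoint_chromosomes,
)
from .randomization import (
    NullSample,
    ZResult,
    child_seeds,
    filter_excluded,
    generate_matched_background,
    sample_background,
    z_score,
)

ORIENTATIONS = ("strandless", "concordant", "discordant")


@dataclass
class TestConfig:
    """Options of one enrichment run (mirrors the command-line surface).

    ``ov_fraction`` is the minimum overlap fraction of the *input* region
    for a target hit to qualify (intersect only; default any >= 1 nt).
    ``exclude_ov`` drops overlapping targets from the closest-distance
    candidates; ``exclude_upstream``/``exclude_downstream`` restrict
    candidates relative to the input feature's strand.
    """

    mode: str = "intersect"
    orientation: str = "strandless"
    n_randomizations: int = 100
    ov_fraction: float | None = None
    exclude_ov: bool = False
    exclude_upstream: bool = False
    exclude_downstream: bool = False
    run_at_gc: bool = False
    run_length: bool = False
    exclusions: IntervalSet | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("intersect", "closest"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if self.n_randomizations < 2:
            raise ConfigurationError("need >= 2 randomizations")
        if self.ov_fraction is not None and not (0.0 < self.ov_fraction <= 1.0):
            raise ConfigurationError("ov_fraction must be in (0, 1]")
        if self.exclude_upstream and self.exclude_downstream:
            raise ConfigurationError(
                "exclude_upstream and exclude_downstream are mutually exclusive"
            )


def _orientation_indices(
    target: IntervalSet, orientation: str, input_set: IntervalSet
) -> dict[str, dict[str, ChromIndex]]:
    """Target indices keyed by the *input* strand they apply to.

    strandless: one index under key ``"."`` used for every input region.
    concordant/discordant: separate indices of +- targets; requires known
    strands on both sides.
    """
    if orientation == "strandless":
        return {".": build_index(target)}
    if not input_set.has_strands or not target.has_strands:
        raise ConfigurationError(
            f"orientation {orientation!r} requires known strands on both input and target"
        )
    plus = build_index(target, mask=target.strands == "+")
    minus = build_index(target, mask=target.strands == "-")
    if orientation == "concordant":
        return {"+": plus, "-": minus}
    return {"+": minus, "-": plus}


def count_overlaps(input_set: IntervalSet, target: IntervalSet, config: TestConfig) -> int:
    """Number of input regions with >= 1 qualifying target overlap.

    A region overlapping multiple targets is counted only once.  With
    ``ov_fraction`` set, qualifying means a single target sharing
    >= ceil(ov_fraction * input length) nt.  Regions intersecting
    ``config.exclusions`` are removed before counting.
    """
    if len(input_set) == 0 or len(target) == 0:
        raise EmptyTestError("count_overlaps requires nonempty input and target sets")
    query = filter_excluded(input_set, config.exclusions)
    indices = _orientation_indices(target, config.orientation, query)
    count = 0
    for i in range(len(query)):
        key = "." if config.orientation == "strandless" else str(query.strands[i])
        index = indices.get(key, {})
        chrom = str(query.chroms[i])
        if chrom not in index:
            continue
        cidx = index[chrom]
        qs, qe = int(query.starts[i]), int(query.ends[i])
        if config.ov_fraction is None:
            hit = bool(
                cidx.any_overlap(
                    np.array([qs], dtype=np.int64), np.array([qe], dtype=np.int64)
                )[0]
            )
        else:
            need = int(np.ceil(config.ov_fraction * (qe - qs)))
            hit = cidx.max_single_overlap(qs, qe) >= max(need, 1)
        count += int(hit)
    return count


def closest_distances(
    input_set: IntervalSet, target: IntervalSet, config: TestConfig
) -> np.ndarray:
    """Per-input-region distance (nt) to the nearest qualifying target.

    Overlap counts as distance 0 unless ``exclude_ov``.  Touching intervals
    ([0,100) then [100,200)) are 0 nt apart.  Upstream/downstream exclusion
    is resolved relative to the input feature's strand; for unknown-strand
    input, upstream = lower coordinates.  Regions with no candidate on
    their chromosome are dropped with a warning; an all-dropped result is
    an error.
    """
    if len(input_set) == 0 or len(target) == 0:
        raise EmptyTestError("closest test requires nonempty input and target sets")
    query = filter_excluded(input_set, config.exclusions)
    indices = _orientation_indices(target, config.orientation, query)
    dists: list[float] = []
    n_dropped = 0
    for i in range(len(query)):
        key = "." if config.orientation == "strandless" else str(query.strands[i])
        index = indices.get(key, {})
        chrom = str(query.chroms[i])
        if chrom not in index:
            n_dropped += 1
            continue
        cidx = index[chrom]
        qs = np.array([int(query.starts[i])], dtype=np.int64)
        qe = np.array([int(query.ends[i])], dtype=np.int64)
        if not config.exclude_ov and bool(cidx.any_overlap(qs, qe)[0]):
            dists.append(0.0)
            continue
        gap_left = float(cidx.gap_left(qs)[0])
        gap_right = float(cidx.gap_right(qe)[0])
        # upstream = 5' of the input feature: lower coords on +/unknown, higher on -
        minus = str(query.strands[i]) == "-"
        if config.exclude_upstream:
            gap = gap_right if not minus else gap_left
        elif config.exclude_downstream:
            gap = gap_left if not minus else gap_right
        else:
            gap = min(gap_left, gap_right)
        if not np.isfinite(gap):
            n_dropped += 1
            continue
        dists.append(gap)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} input region(s) had no candidate target and were "
            "excluded from the mean distance",
            stacklevel=2,
        )
    if not dists:
        raise EmptyTestError("no input region has a qualifying target feature")
    return np.asarray(dists, dtype=float)


def mean_closest_distance(
    input_set: IntervalSet, target: IntervalSet, config: TestConfig
) -> float:
    """Arithmetic mean of per-region nearest-target distances (nt)."""
    return float(np.mean(closest_distances(input_set, target, config)))


def _mean_at_gc(regions: IntervalSet, genome) -> tuple[float, float]:
    ats, gcs = [], []
    for iv in regions:
        at, gc = at_gc_content(iv, genome)
        ats.append(at)
        gcs.append(gc)
    return float(np.mean(ats)), float(np.mean(gcs))


def draw_null_sets(
    input_set: IntervalSet,
    background: IntervalSet | None,
    config: TestConfig,
    chrom_sizes: dict[str, int] | None = None,
    generate_bg: bool = False,
) -> list[IntervalSet]:
    """Draw the null interval sets once; reused across targets and tests.

    With a user background: each randomization samples |input| records
    without replacement.  With ``generate_bg``: each randomization generates
    a fresh matched set of size |input| (chromosome frequency + length
    distribution replicated).  A master seed fans out to per-randomization
    children, so results do not depend on how draws are parallelised.
    """
    n = len(input_set)
    seeds = child_seeds(config.seed, config.n_randomizations)
    null_sets: list[IntervalSet] = []
    if generate_bg:
        if chrom_sizes is None:
            raise ConfigurationError("matched-background generation requires chromosome sizes")
        strands = "random" if config.orientation != "strandless" else "unknown"
        for ss in seeds:
            null_sets.append(
                generate_matched_background(
                    input_set,
                    chrom_sizes,
                    n,
                    exclusions=config.exclusions,
                    rng=np.random.default_rng(ss),
                    strands=strands,
                )
            )
    else:
        if background is None:
            raise ConfigurationError("supply a background or enable generate_bg")
        bg = filter_excluded(background, config.exclusions)
        for ss in seeds:
            null_sets.append(sample_background(bg, n, np.random.default_rng(ss)))
    return null_sets


def run_enrichment_test(
    input_set: IntervalSet,
    targets: Sequence[IntervalSet] | IntervalSet,
    background: IntervalSet | None = None,
    config: TestConfig | None = None,
    genome=None,
    chrom_sizes: dict[str, int] | None = None,
    generate_bg: bool = False,
) -> list[ZResult]:
    """Full randomization test: one ZResult row per (target, test type).

    For each target the observed statistic (overlap count or mean nearest
    distance) is compared against the null sets; the optional AT/GC and
    length tests compare the input's mean AT, mean GC and mean length
    against the null sets' means, independent of any target.
    """
    config = config or TestConfig()
    if isinstance(targets, IntervalSet):
        targets = [targets]
    if config.run_at_gc and genome is None:
        raise ConfigurationError("AT/GC test requires a genome FASTA")
    query = filter_excluded(input_set, config.exclusions)
    if len(query) == 0:
        raise EmptyTestError("no input regions left after exclusions")
    null_sets = draw_null_sets(query, background, config, chrom_sizes, generate_bg)

    stat = count_overlaps if config.mode == "intersect" else mean_closest_distance
    kind = "overlap_count" if config.mode == "intersect" else "mean_distance"
    results: list[ZResult] = []
    for target in targets:
        warn_if_disjoint_chromosomes(query, target)
        real = float(stat(query, target, config))
        null = NullSample(
            np.array([stat(ns, target, config) for ns in null_sets], dtype=float), kind
        )
        results.append(
            z_score(real, null, test_type=config.orientation, target_label=target.source_label)
        )
    if config.run_at_gc:
        real_at, real_gc = _mean_at_gc(query, genome)
        null_at_gc = [_mean_at_gc(ns, genome) for ns in null_sets]
        results.append(
            z_score(
                real_at,
                NullSample(np.array([v[0] for v in null_at_gc]), "mean_at"),
                test_type="AT_GC",
                target_label="AT",
            )
        )
        results.append(
            z_score(
                real_gc,
                NullSample(np.array([v[1] for v in null_at_gc]), "mean_gc"),
                test_type="AT_GC",
                target_label="GC",
            )
        )
    if config.run_length:
        results.append(
            z_score(
                float(np.mean(query.lengths)),
                NullSample(
                    np.array([float(np.mean(ns.lengths)) for ns in null_sets]), "mean_length"
                ),
                test_type="length",
                target_label="length",
            )
        )
    return results
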