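"""Ranked-interval enrichment analysis.

Regions carrying a per-region score ``Si`` (BED column 5) are sorted and a
GSEA-style random walk asks whether target-overlapping regions concentrate
at one end of the ranking: the walk rises ``1/Nh`` at each hit and falls
``1/Nm`` at each miss, and the enrichment score (ES) is the maximum
absolute excursion.  Significance comes from permutations that shuffle the
scores and recompute the walk.  The closest-mode variant ranks nearest-
target distances instead and compares the real normalized cumulative
distance curve ``S_real(i)`` against the mean of score-shuffled curves with
a Kolmogorov–Smirnov statistic.

Optionally the ranking itself can be re-weighted by overlap fraction or
proximity:  ``Wi = Di * alpha + (1 - Ri) * (1 - alpha)`` combines the
overlap fraction (or 1 - scaled distance) ``Di`` with the scaled rank
``Ri``, and the scaled score is adjusted to
``Si' = Si * ((1 - w) + w * (1 - Wi))`` for ascending sorts
(``Si * ((1 - w) + w * Wi)`` for descending); ``w = 0`` leaves the pure
score ranking untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._interval_ops import build_index
from .enrichment import TestConfig, closest_distances
from .errors import ConfigurationError, DegenerateRankingError, ValidationError
from .intervals import IntervalSet


@dataclass
class RankingConfig:
    """Options of one ranked test.

    ``alpha`` balances overlap/proximity against rank inside the weight
    ``Wi``; ``w`` is the weighting strength (0 = unweighted, the default);
    ``n_permutations`` is the permutation count T.
    """

    direction: str = "ascending"
    alpha: float = 0.5
    w: float = 0.0
    n_permutations: int = 100
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("ascending", "descending"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must be in [0, 1]")
        if not (0.0 <= self.w <= 1.0):
            raise ConfigurationError("w must be in [0, 1]")
        if self.n_permutations < 1:
            raise ConfigurationError("need >= 1 permutation")
        if self.workers < 1:
            raise ConfigurationError("workers must be >= 1")


@dataclass
class ESCurve:
    """Running-sum enrichment trajectory of the ranked intersect test.

    ``order`` maps rank position -> index into the input set; ``running``
    holds the walk after each rank; ``es_signed`` is the running value at
    the (earliest) peak of |running| and ``es_final`` its absolute value.
    ``leading_ranks``/``leading_indices`` are the contiguous block driving
    the signal: ranks <= peak for positive enrichment, ranks > peak for
    negative (the peak rank itself belongs to the positive-side set).
    """

    order: np.ndarray
    running: np.ndarray
    hits_in_order: np.ndarray
    Nh: int
    Nm: int
    peak_index: int
    es_signed: float
    es_final: float
    leading_ranks: np.ndarray
    leading_indices: np.ndarray
    p_value: float | None = None
    null_es: np.ndarray | None = field(default=None, repr=False)


@dataclass
class DistanceCurve:
    """Cumulative-distance curves of the ranked closest test.

    ``s_real`` and each row of ``s_shuffle`` are normalized cumulative
    distance distributions (nondecreasing, ending at exactly 1); ``es`` is
    the maximum absolute deviation of ``s_real`` from the shuffle mean,
    signed positive when the real curve exceeds the mean at the peak.
    """

    order: np.ndarray
    distances_in_order: np.ndarray
    s_real: np.ndarray
    s_shuffle: np.ndarray
    s_shuffle_mean: np.ndarray
    es: float
    es_sign: int
    peak_index: int
    leading_ranks: np.ndarray
    leading_indices: np.ndarray
    ks_p: float


# ---------------------------------------------------------------------------
# Scaling / weighting primitives
# ---------------------------------------------------------------------------


def scale_minmax(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all 0.5."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValidationError("cannot scale an empty sequence")
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        warnings.warn("constant values under min-max scaling; returning 0.5", stacklevel=2)
        return np.full(len(v), 0.5)
    return (v - lo) / (hi - lo)


def compute_weight(Di, Ri, alpha: float):
    """``Wi = Di * alpha + (1 - Ri) * (1 - alpha)``; all arguments in [0, 1]."""
    return np.asarray(Di, dtype=float) * alpha + (1.0 - np.asarray(Ri, dtype=float)) * (
        1.0 - alpha
    )


def adjust_score(Si, Wi, w: float, direction: str):
    """Weighted score adjustment; ``w = 0`` returns ``Si`` unchanged."""
    Si = np.asarray(Si, dtype=float)
    Wi = np.asarray(Wi, dtype=float)
    if direction == "ascending":
        return Si * ((1.0 - w) + w * (1.0 - Wi))
    return Si * ((1.0 - w) + w * Wi)


def overlap_fraction(region, target: IntervalSet | dict) -> float:
    """Fraction of the region covered by the union of target intervals."""
    index = target if isinstance(target, dict) else build_index(target)
    if region.chrom not in index:
        return 0.0
    shared = index[region.chrom].union_overlap(region.start, region.end)
    return shared / region.length


# ---------------------------------------------------------------------------
# Ranking pipeline
# ---------------------------------------------------------------------------


def _require_scores(regions: IntervalSet) -> np.ndarray:
    if not regions.has_scores:
        raise ValidationError("every region must carry a score (BED column 5)")
    return regions.scores.astype(float)


def _ranked_order(scores: np.ndarray, Di: np.ndarray, config: RankingConfig) -> np.ndarray:
    """Rank positions -> original indices, after optional weighting.

    ``Ri`` is the scaled relative rank (0 = top of the direction-sorted
    list) based on the original score.  Ties are broken by input record
    order (stable sort).  With ``w = 0`` the result is exactly the pure
    score ranking: min-max scaling is monotone, so sorting the scaled
    scores reproduces it bit-for-bit.
    """
    n = len(scores)
    s_scaled = scale_minmax(scores)
    key0 = s_scaled if config.direction == "ascending" else -s_scaled
    base_order = np.argsort(key0, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[base_order] = np.arange(n, dtype=float)
    Ri = ranks / (n - 1) if n > 1 else np.zeros(n)
    Wi = compute_weight(Di, Ri, config.alpha)
    s_prime = adjust_score(s_scaled, Wi, config.w, config.direction)
    key = s_prime if config.direction == "ascending" else -s_prime
    return np.argsort(key, kind="stable")


def _walk(hits_in_order: np.ndarray) -> tuple[np.ndarray, int, float]:
    """Running sum, earliest peak index of |running|, and signed peak value."""
    nh = int(hits_in_order.sum())
    nm = len(hits_in_order) - nh
    if nh == 0 or nm == 0:
        raise DegenerateRankingError(
            "ranked intersect test needs at least one hit and one miss"
        )
    steps = np.where(hits_in_order, 1.0 / nh, -1.0 / nm)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return running, peak, float(running[peak])


def _leading(n: int, peak: int, positive: bool) -> np.ndarray:
    """Ranks <= peak for positive enrichment (peak included); ranks > peak
    for the "after the peak" sets."""
    return np.arange(0, peak + 1) if positive else np.arange(peak + 1, n)


def _null_es_one(seed: np.random.SeedSequence, scores, Di, hits, config) -> float:
    rng = np.random.default_rng(seed)
    s_perm = scores[rng.permutation(len(scores))]
    order = _ranked_order(s_perm, Di, config)
    _, _, signed = _walk(hits[order])
    return abs(signed)


def rank_intersect_test(
    regions: IntervalSet, target: IntervalSet, config: RankingConfig | None = None
) -> ESCurve:
    """Random-walk enrichment of target-overlapping regions along the score
    ranking, with an empirical permutation p-value.

    p = (# permutations with |null ES| >= |real ES|) / T, where each
    permutation shuffles the scores across regions and recomputes the full
    ranking + walk.  Permutations use per-permutation child seeds, so the
    result is identical for any ``workers`` setting.
    """
    config = config or RankingConfig()
    scores = _require_scores(regions)
    index = build_index(target)
    Di = np.array([overlap_fraction(iv, index) for iv in regions], dtype=float)
    hits = Di > 0.0

    order = _ranked_order(scores, Di, config)
    running, peak, signed = _walk(hits[order])
    es_final = abs(signed)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_permutations)
    if config.workers > 1:
        from joblib import Parallel, delayed

        null_es = Parallel(n_jobs=config.workers)(
            delayed(_null_es_one)(ss, scores, Di, hits, config) for ss in seeds
        )
    else:
        null_es = [_null_es_one(ss, scores, Di, hits, config) for ss in seeds]
    null_es = np.asarray(null_es, dtype=float)
    p_value = float(np.sum(null_es >= es_final) / config.n_permutations)

    leading_ranks = _leading(len(regions), peak, positive=signed > 0)
    return ESCurve(
        order=order,
        running=running,
        hits_in_order=hits[order],
        Nh=int(hits.sum()),
        Nm=int(len(regions) - hits.sum()),
        peak_index=peak,
        es_signed=signed,
        es_final=es_final,
        leading_ranks=leading_ranks,
        leading_indices=order[leading_ranks],
        p_value=p_value,
        null_es=null_es,
    )


def rank_closest_test(
    regions: IntervalSet, target: IntervalSet, config: RankingConfig | None = None
) -> DistanceCurve:
    """Cumulative-distance variant for proximity: compares the real
    normalized cumulative distance curve along the score ranking against
    the mean of T score-shuffled curves (Kolmogorov–Smirnov two-sample
    test between the two curves).

    Positive enrichment (real curve above the shuffle mean at the peak)
    means top-ranked regions are FAR from the target; negative means they
    are NEAR.  Leading regions are the ranks after the peak for positive
    enrichment and the ranks up to (and including) the peak for negative —
    mirroring which end of the list drives the deviation.  Optional
    weighting (``w > 0``) uses proximity ``1 - scaled distance`` as ``Di``.
    """
    config = config or RankingConfig()
    scores = _require_scores(regions)
    distances = closest_distances(regions, target, TestConfig(mode="closest"))
    if len(distances) != len(regions):
        raise DegenerateRankingError(
            "every region needs a nearest target feature on its chromosome"
        )
    total = float(distances.sum())
    if total == 0.0:
        raise DegenerateRankingError(
            "all distances are zero (every region overlaps the target); "
            "pre-filter overlapping regions to rank proximity"
        )
    proximity = 1.0 - scale_minmax(distances)
    order = _ranked_order(scores, proximity, config)
    d_ord = distances[order]
    s_real = np.cumsum(d_ord) / total

    n = len(regions)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_permutations)
    s_shuffle = np.empty((config.n_permutations, n), dtype=float)
    for k, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        s_shuffle[k] = np.cumsum(d_ord[rng.permutation(n)]) / total
    s_mean = s_shuffle.mean(axis=0)

    diff = s_real - s_mean
    peak = int(np.argmax(np.abs(diff)))
    es = float(abs(diff[peak]))
    sign = 1 if diff[peak] > 0 else (-1 if diff[peak] < 0 else 0)
    ks_p = float(stats.ks_2samp(s_real, s_mean).pvalue)

    leading_ranks = _leading(n, peak, positive=sign <= 0)
    return DistanceCurve(
        order=order,
        distances_in_order=d_ord,
        s_real=s_real,
        s_shuffle=s_shuffle,
        s_shuffle_mean=s_mean,
        es=es,
        es_sign=sign,
        peak_index=peak,
        leading_ranks=leading_ranks,
        leading_indices=order[leading_ranks],
        ks_p=ks_p,
    )
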