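"""Null-model machinery: background sampling, matched-background generation,
and conversion of an observed statistic plus a Monte-Carlo null sample into a
Z-score with a two-tailed Gaussian p-value.

The null hypothesis throughout: the input regions are an arbitrary draw from
the background universe, so their overlap/proximity statistics should look
like those of random same-size background subsets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._interval_ops import build_index, overlap_mask
from .errors import BackgroundSizeError, PlacementError
from .intervals import STRAND_UNKNOWN, IntervalSet

#: Placement retries per interval before generate_matched_background gives up.
_MAX_PLACEMENT_TRIES = 1000


@dataclass
class NullSample:
    """Per-randomization statistics forming the empirical null distribution."""

    values: np.ndarray
    statistic_kind: str  # overlap_count | mean_distance | mean_at | mean_gc | mean_length

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null sample contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ZResult:
    """One output row of the enrichment table (the published table schema).

    ``real`` is the observed statistic (a count or a mean, units depend on
    the test); ``random_mean``/``random_sd`` summarise the null sample at
    full precision (rounded only at serialisation time).
    """

    z: float
    test_type: str  # strandless | concordant | discordant | AT_GC | length
    p_value: float
    target_label: str
    real: float
    random_mean: float
    random_sd: float
    n_randomizations: int
    null_values: np.ndarray | None = field(default=None, repr=False)


def child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Fan a master seed out to ``n`` independent child seed sequences.

    One child per randomization/permutation makes results identical
    regardless of how the work is split across workers.
    """
    return np.random.SeedSequence(seed).spawn(n)


def gaussian_two_tailed_p(z: float) -> float:
    """p = 2 * Phi(-|z|) via the numerically stable complementary tail.

    Stays accurate far beyond |z| = 8 (scipy's ``norm.sf`` works in the
    log-stable regime); returns exactly 1.0 at z = 0.
    """
    if not math.isfinite(z):
        return 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def z_score(
    real: float,
    null: NullSample | Sequence[float] | np.ndarray,
    test_type: str = "strandless",
    target_label: str = "",
) -> ZResult:
    """Standardise an observed statistic against its Monte-Carlo null.

    ``z = (real - mean(null)) / sd(null)`` with the sample (n-1 denominator)
    standard deviation.  A degenerate null (sd = 0) yields z = 0, p = 1 when
    the observation equals the null mean, otherwise a signed-infinity
    sentinel with p = 0; both emit a warning.
    """
    values = null.values if isinstance(null, NullSample) else np.asarray(null, dtype=float)
    if len(values) < 2:
        raise ValueError("null sample needs >= 2 values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        if real == mean:
            warnings.warn("degenerate null (sd = 0) with real == mean; z = 0", stacklevel=2)
            z = 0.0
        else:
            warnings.warn("degenerate null (sd = 0) with real != mean; z = +/-inf", stacklevel=2)
            z = math.copysign(math.inf, real - mean)
    else:
        z = (real - mean) / sd
    return ZResult(
        z=z,
        test_type=test_type,
        p_value=gaussian_two_tailed_p(z),
        target_label=target_label,
        real=float(real),
        random_mean=mean,
        random_sd=sd,
        n_randomizations=len(values),
        null_values=values,
    )


def sample_background(
    background: IntervalSet, n: int, rng: np.random.Generator
) -> IntervalSet:
    """Draw ``n`` distinct background records without replacement.

    Each randomization is an independent draw; all record fields are
    preserved and the result is order-normalised (coordinate-sorted).
    """
    if n > len(background):
        raise BackgroundSizeError(
            f"requested {n} regions but background has only {len(background)}; "
            "supply a larger background or enable matched-background generation"
        )
    idx = rng.choice(len(background), size=n, replace=False)
    return background.subset(idx)


def generate_matched_background(
    input_set: IntervalSet,
    chrom_sizes: dict[str, int],
    n: int,
    exclusions: IntervalSet | None = None,
    rng: np.random.Generator | None = None,
    strands: str = "unknown",
) -> IntervalSet:
    """Generate ``n`` random regions replicating the input's chromosomal
    frequency and length distributions.

    Chromosomes are drawn (with replacement) from the input's empirical
    chromosome assignments, lengths resampled from its empirical length
    distribution, and start positions placed uniformly on
    ``[0, chrom_length - length]``.  No generated region intersects
    ``exclusions``.  ``strands="random"`` assigns +/- uniformly (needed for
    concordant/discordant modes on a generated background).
    """
    rng = rng if rng is not None else np.random.default_rng()
    missing = input_set.chrom_names() - set(chrom_sizes)
    if missing:
        raise KeyError(f"input chromosomes absent from chrom sizes: {sorted(missing)}")
    excl_index = build_index(exclusions) if exclusions is not None else None

    src_chroms = input_set.chroms
    src_lengths = input_set.lengths
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for i in range(n):
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            chrom = str(src_chroms[rng.integers(0, len(src_chroms))])
            length = int(src_lengths[rng.integers(0, len(src_lengths))])
            span = chrom_sizes[chrom] - length
            if span < 0:  # sampled length exceeds this chromosome: resample
                continue
            start = int(rng.integers(0, span + 1))
            end = start + length
            if excl_index is not None and chrom in excl_index:
                hit = excl_index[chrom].any_overlap(
                    np.array([start], dtype=np.int64), np.array([end], dtype=np.int64)
                )[0]
                if hit:
                    continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place region {i + 1}/{n} after {_MAX_PLACEMENT_TRIES} tries; "
                "exclusions too dense or lengths exceed chromosome sizes"
            )
    strand_col = (
        rng.choice(np.array(["+", "-"], dtype=object), size=n)
        if strands == "random"
        else np.full(n, STRAND_UNKNOWN, dtype=object)
    )
    return IntervalSet(
        chroms,
        starts,
        ends,
        names=[f"bg_{i}" for i in range(n)],
        strands=strand_col,
        source_label="generated_background",
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Optional BH adjustment across result rows (off by default in the CLI;
    the primary output mirrors raw per-row p-values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def filter_excluded(regions: IntervalSet, exclusions: IntervalSet | None) -> IntervalSet:
    """Drop regions sharing >= 1 nt with any exclusion interval."""
    if exclusions is None or len(exclusions) == 0 or len(regions) == 0:
        return regions
    mask = overlap_mask(regions, build_index(exclusions))
    return regions.subset(np.flatnonzero(~mask))
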