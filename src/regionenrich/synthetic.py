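"""Deterministic generators for the synthetic benchmark datasets.

Every statistical claim of the package is testable without downloads: the
generators engineer interval sets with known overlap counts and known
nearest-feature distance distributions on a synthetic genome, then verify
the engineered properties before returning.  All fixtures are bit-identical
regenerable from (parameters, seed).

Synthetic genome: 5 chromosomes of 10 Mb each; default region length 200 nt
(the benchmark constructions do not depend on these choices, which only
need to leave room for non-overlapping placement).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .enrichment import TestConfig, closest_distances, count_overlaps
from .errors import ValidationError
from .intervals import IntervalSet, write_bed

DEFAULT_GENOME = {f"chr{i}": 10_000_000 for i in range(1, 6)}
DEFAULT_REGION_LENGTH = 200


@dataclass
class FixtureSpec:
    """Recorded parameters of a generated fixture (JSON sidecar)."""

    kind: str
    params: dict
    genome: dict[str, int]
    seed: int


def _slots(genome: dict[str, int], width: int) -> list[tuple[str, int]]:
    out = []
    for chrom, size in genome.items():
        for s in range(0, size - width + 1, width):
            out.append((chrom, s))
    return out


def _build(
    records: list[tuple[str, int, int]],
    rng: np.random.Generator,
    label: str,
    prefix: str,
    scores: np.ndarray | None = None,
) -> IntervalSet:
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=len(records))
    return IntervalSet(
        [r[0] for r in records],
        [r[1] for r in records],
        [r[2] for r in records],
        names=[f"{prefix}_{i:05d}" for i in range(len(records))],
        scores=scores,
        strands=strands,
        source_label=label,
    )


def _trunc_normal_int(
    rng: np.random.Generator, mean: float, sd: float, size: int, low: int, high: int
) -> np.ndarray:
    """Normal draws rounded to integers and clipped to [low, high]; the
    clipping keeps coordinates integral and placements collision-free."""
    return np.clip(np.rint(rng.normal(mean, sd, size=size)).astype(np.int64), low, high)


# ---------------------------------------------------------------------------
# Intersect benchmark
# ---------------------------------------------------------------------------


def make_intersect_fixture(
    n_input: int = 500,
    n_background: int = 2000,
    n_target: int = 5000,
    n_overlap: int = 125,
    n_bg_extra_overlap: int = 0,
    seed: int = 0,
    region_length: int = DEFAULT_REGION_LENGTH,
    genome: dict[str, int] | None = None,
) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    """Engineered overlap benchmark: exactly ``n_overlap`` input regions
    overlap >= 1 target region; the background contains the input plus
    ``n_background - n_input`` extras of which ``n_bg_extra_overlap``
    overlap the target (0 by default).  All regions within each file are
    mutually non-overlapping.

    Defaults reproduce the published construction: 500 input / 2000
    background / 5000 target with 125 engineered overlaps (25% of the
    input vs 6.25% of the background).
    """
    genome = genome or DEFAULT_GENOME
    if n_overlap > min(n_input, n_target):
        raise ValidationError("n_overlap exceeds input or target size")
    n_extra = n_background - n_input
    if n_bg_extra_overlap > n_extra or n_overlap + n_bg_extra_overlap > n_target:
        raise ValidationError("background overlap request infeasible")
    L = region_length
    width = max(10 * L, 2000)
    slots = _slots(genome, width)
    need = n_target + (n_input - n_overlap) + (n_extra - n_bg_extra_overlap)
    if need > len(slots):
        raise ValidationError(
            f"synthetic genome too small: need {need} slots of {width} nt, have {len(slots)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))

    target_slots = [slots[i] for i in order[:n_target]]
    free = iter(order[n_target:])
    targets = [(c, s + 3 * L, s + 4 * L) for c, s in target_slots]

    # overlapping regions sit inside their target's slot, shifted by L/2
    hit_idx = rng.choice(n_target, size=n_overlap + n_bg_extra_overlap, replace=False)
    shift = L // 2
    inputs = [
        (c, s + shift, s + shift + L) for c, s, _ in (targets[j] for j in hit_idx[:n_overlap])
    ]
    bg_extras = [
        (c, s + shift, s + shift + L) for c, s, _ in (targets[j] for j in hit_idx[n_overlap:])
    ]
    for _ in range(n_input - n_overlap):
        c, s = slots[next(free)]
        inputs.append((c, s + 3 * L, s + 4 * L))
    for _ in range(n_extra - n_bg_extra_overlap):
        c, s = slots[next(free)]
        bg_extras.append((c, s + 3 * L, s + 4 * L))

    input_set = _build(inputs, rng, "Input.bed", "input")
    target_set = _build(targets, rng, "Target.bed", "target")
    background = input_set.concat(
        _build(bg_extras, rng, "Background.bed", "bgex"), source_label="Background.bed"
    )

    cfg = TestConfig(mode="intersect")
    assert count_overlaps(input_set, target_set, cfg) == n_overlap
    assert count_overlaps(background, target_set, cfg) == n_overlap + n_bg_extra_overlap
    return input_set, background, target_set


# ---------------------------------------------------------------------------
# Closest benchmark
# ---------------------------------------------------------------------------


def make_closest_fixture(
    n_input: int = 500,
    input_dist: tuple[float, float] = (1000.0, 200.0),
    n_extra_bg: int = 1500,
    bg_dist: tuple[float, float] = (1400.0, 600.0),
    n_target: int = 5000,
    seed: int = 0,
    region_length: int = DEFAULT_REGION_LENGTH,
    genome: dict[str, int] | None = None,
) -> tuple[IntervalSet, IntervalSet, IntervalSet]:
    """Engineered proximity benchmark: each input region sits at a
    normal-sampled gap (truncated to >= 1 nt, so nothing overlaps) from its
    own target feature, and that feature is guaranteed to be its nearest;
    background extras do the same with a wider/farther distance
    distribution.  Defaults reproduce the published construction: 500 input
    at 1000 +/- 200 nt, 1500 extras at 1400 +/- 600 nt, 5000 targets.
    """
    genome = genome or DEFAULT_GENOME
    L = region_length
    width = 10_000
    t_off = 3000  # target at [slot+3000, slot+3000+L)
    d_max = (width - 2 * L) // 2 - 1  # own target stays strictly nearest
    slots = _slots(genome, width)
    if n_target > len(slots):
        raise ValidationError("synthetic genome too small for target count")
    if n_input + n_extra_bg > n_target:
        raise ValidationError("need one distinct target per placed region")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))
    target_slots = [slots[i] for i in order[:n_target]]
    targets = [(c, s + t_off, s + t_off + L) for c, s in target_slots]

    attach = rng.choice(n_target, size=n_input + n_extra_bg, replace=False)
    d_in = _trunc_normal_int(rng, input_dist[0], input_dist[1], n_input, 1, d_max)
    d_bg = _trunc_normal_int(rng, bg_dist[0], bg_dist[1], n_extra_bg, 1, d_max)

    def _place(target_idx: np.ndarray, gaps: np.ndarray) -> list[tuple[str, int, int]]:
        out = []
        for j, d in zip(target_idx, gaps):
            c, _, te = targets[j]
            out.append((c, te + int(d), te + int(d) + L))
        return out

    inputs = _place(attach[:n_input], d_in)
    extras = _place(attach[n_input:], d_bg)

    input_set = _build(inputs, rng, "Input.bed", "input")
    target_set = _build(targets, rng, "Target.bed", "target")
    background = input_set.concat(
        _build(extras, rng, "Background.bed", "bgex"), source_label="Background.bed"
    )

    # realized nearest distances must equal the sampled gaps (checked
    # against ALL targets, not just the assigned one)
    cfg = TestConfig(mode="closest", exclude_ov=True)
    realized = closest_distances(input_set, target_set, cfg)
    assert np.array_equal(np.sort(realized), np.sort(d_in.astype(float)))
    realized_bg = closest_distances(background, target_set, cfg)
    assert np.array_equal(
        np.sort(realized_bg), np.sort(np.concatenate([d_in, d_bg]).astype(float))
    )
    return input_set, background, target_set


# ---------------------------------------------------------------------------
# Ranked benchmarks
# ---------------------------------------------------------------------------


def make_rank_intersect_fixture(
    n: int = 100,
    n_hits: int = 25,
    hit_score: tuple[float, float] = (5.0, 3.0),
    miss_score: tuple[float, float] = (6.0, 3.0),
    n_target_extra: int = 100,
    seed: int = 0,
    region_length: int = DEFAULT_REGION_LENGTH,
    genome: dict[str, int] | None = None,
) -> tuple[IntervalSet, IntervalSet]:
    """Scored ranking benchmark: exactly ``n_hits`` regions overlap >= 1
    target region and draw scores from ``N(hit_score)``; the rest overlap
    nothing and draw from ``N(miss_score)``.  Defaults reproduce the
    published construction: 100 regions, 25 hits ~ N(5, 3^2), 75 misses
    ~ N(6, 3^2) (hits enriched at the top under ascending sort).
    """
    genome = genome or DEFAULT_GENOME
    if n_hits >= n or n_hits < 1:
        raise ValidationError("need 1 <= n_hits < n")
    L = region_length
    width = max(10 * L, 2000)
    slots = _slots(genome, width)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))
    it = iter(order)

    records: list[tuple[str, int, int]] = []
    targets: list[tuple[str, int, int]] = []
    for _ in range(n_hits):
        c, s = slots[next(it)]
        targets.append((c, s + 3 * L, s + 4 * L))
        records.append((c, s + 3 * L + L // 2, s + 4 * L + L // 2))
    for _ in range(n - n_hits):
        c, s = slots[next(it)]
        records.append((c, s + 3 * L, s + 4 * L))
    for _ in range(n_target_extra):
        c, s = slots[next(it)]
        targets.append((c, s + 3 * L, s + 4 * L))

    scores = np.concatenate(
        [
            rng.normal(hit_score[0], hit_score[1], size=n_hits),
            rng.normal(miss_score[0], miss_score[1], size=n - n_hits),
        ]
    )
    input_set = _build(records, rng, "Input.bed", "input", scores=scores)
    target_set = _build(targets, rng, "Target.bed", "target")
    assert count_overlaps(input_set, target_set, TestConfig(mode="intersect")) == n_hits
    return input_set, target_set


def make_rank_closest_fixture(
    n: int = 100,
    n_near: int = 35,
    near: tuple[float, float] = (100.0, 50.0),
    far: tuple[float, float] = (150.0, 50.0),
    near_score: tuple[float, float] = (5.0, 3.0),
    far_score: tuple[float, float] = (6.0, 3.0),
    seed: int = 0,
    region_length: int = DEFAULT_REGION_LENGTH,
    genome: dict[str, int] | None = None,
) -> tuple[IntervalSet, IntervalSet]:
    """Scored proximity-ranking benchmark: ``n_near`` regions at near
    distances with lower scores, the rest farther with higher scores.
    Defaults reproduce the published construction: 35 regions at
    100 +/- 50 nt scored N(5, 3^2), 65 at 150 +/- 50 nt scored N(6, 3^2).
    """
    genome = genome or DEFAULT_GENOME
    if not (1 <= n_near < n):
        raise ValidationError("need 1 <= n_near < n")
    L = region_length
    width = 4000
    t_off = 600
    d_max = 1200  # own target stays nearest: next target >= 3600 - d away
    slots = _slots(genome, width)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))

    d_near = _trunc_normal_int(rng, near[0], near[1], n_near, 1, d_max)
    d_far = _trunc_normal_int(rng, far[0], far[1], n - n_near, 1, d_max)
    gaps = np.concatenate([d_near, d_far])

    records, targets = [], []
    for i in range(n):
        c, s = slots[order[i]]
        te = s + t_off + L
        targets.append((c, s + t_off, te))
        records.append((c, te + int(gaps[i]), te + int(gaps[i]) + L))

    scores = np.concatenate(
        [
            rng.normal(near_score[0], near_score[1], size=n_near),
            rng.normal(far_score[0], far_score[1], size=n - n_near),
        ]
    )
    input_set = _build(records, rng, "Input.bed", "input", scores=scores)
    target_set = _build(targets, rng, "Target.bed", "target")
    realized = closest_distances(input_set, target_set, TestConfig(mode="closest"))
    assert np.array_equal(np.sort(realized), np.sort(gaps.astype(float)))
    return input_set, target_set


# ---------------------------------------------------------------------------
# Sensitivity sweep
# ---------------------------------------------------------------------------

#: Default input:background overlap-percentage ratios.  The background
#: contains the input, capping its overlap percentage at 81.25%, so the
#: smallest achievable ratio is 25/81.25 ~= 0.31.
DEFAULT_RATIOS = (1 / 3, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0)


def make_ratio_sweep(
    ratios: tuple[float, ...] | list[float] = DEFAULT_RATIOS,
    seed: int = 0,
    n_input: int = 500,
    n_background: int = 2000,
    n_target: int = 5000,
    n_overlap: int = 125,
    **kwargs,
) -> list[tuple[float, tuple[IntervalSet, IntervalSet, IntervalSet]]]:
    """Fixtures spanning input:background overlap-percentage ratios.

    The input overlap fraction stays fixed (25% by default) while the
    background's extra regions are engineered so that the background
    overlap percentage equals ``input_pct / ratio``.
    """
    input_pct = n_overlap / n_input
    out = []
    seeds = np.random.SeedSequence(seed).spawn(len(ratios))
    for ratio, ss in zip(ratios, seeds):
        bg_hits = int(round(n_background * input_pct / ratio))
        extra_hits = bg_hits - n_overlap
        if extra_hits < 0 or extra_hits > n_background - n_input:
            raise ValidationError(
                f"ratio {ratio} infeasible: background needs {bg_hits} overlapping regions"
            )
        trio = make_intersect_fixture(
            n_input=n_input,
            n_background=n_background,
            n_target=n_target,
            n_overlap=n_overlap,
            n_bg_extra_overlap=extra_hits,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            **kwargs,
        )
        out.append((ratio, trio))
    return out


def write_fixture_files(
    sets: dict[str, IntervalSet], outdir: str | Path, spec: FixtureSpec
) -> None:
    """Write each set as BED plus a JSON sidecar recording spec and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, iset in sets.items():
        write_bed(iset, outdir / name)
    with open(outdir / "fixture.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
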