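"""Genomic-localization enrichment: classify regions against gene structure
(TSS, promoter, UTRs, exon, intron, intergenic) or a custom annotation BED,
and compute a per-category randomization Z-score vector (the heatmap rows).

Classification is single-label by default: each region gets the single
highest-precedence category it overlaps, so counts partition the region set
and Z-scores are comparable across categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._interval_ops import ChromIndex, build_index
from .enrichment import TestConfig, draw_null_sets
from .errors import ValidationError
from .gene_models import GeneModelSet
from .intervals import IntervalSet
from .randomization import NullSample, ZResult, z_score

DEFAULT_PRECEDENCE = ("TSS", "promoter", "5UTR", "3UTR", "exon", "intron", "intergenic")

#: Conventional annotation windows; the promoter is upstream of the TSS
#: window, strand-aware.  Both are configurable from the CLI.
DEFAULT_PROMOTER_SPAN = 2000
DEFAULT_TSS_HALFWIDTH = 200


@dataclass
class AnnotationSet:
    """Ordered categories with their interval sets and a precedence list
    used to resolve regions overlapping several categories."""

    categories: list[str]
    category_intervals: dict[str, IntervalSet]
    precedence: list[str]
    _indices: dict[str, dict[str, ChromIndex]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cat in self.precedence:
            if cat not in self.category_intervals:
                raise ValidationError(f"precedence category {cat!r} has no intervals")
        self._indices = {
            cat: build_index(ivs) for cat, ivs in self.category_intervals.items()
        }


@dataclass
class LocalizationResult:
    counts: dict[str, int]
    results: list[ZResult]


def build_annotation(
    gene_models: GeneModelSet,
    promoter_span: int = DEFAULT_PROMOTER_SPAN,
    tss_halfwidth: int = DEFAULT_TSS_HALFWIDTH,
    chrom_sizes: dict[str, int] | None = None,
) -> AnnotationSet:
    """Derive the gene-structure annotation from gene models.

    Per gene (strand-aware): TSS window ``[TSS - hw, TSS + hw)``; promoter =
    ``promoter_span`` nt upstream of the TSS excluding the TSS window.
    Windows are clipped at chromosome bounds when sizes are known.
    Intergenic is materialised as the complement of all gene-linked
    categories when ``chrom_sizes`` is given; otherwise it exists only as
    the classification fallback.
    """
    if len(gene_models) == 0:
        raise ValidationError("gene model set is empty")
    cats = gene_models.category_intervals()
    tss_blocks: list[tuple[str, int, int]] = []
    prom_blocks: list[tuple[str, int, int]] = []
    for g in gene_models.genes.values():
        limit = chrom_sizes.get(g.chrom) if chrom_sizes else None
        t0, t1 = g.tss - tss_halfwidth, g.tss + tss_halfwidth
        if g.strand == "+":
            p0, p1 = t0 - promoter_span, t0
        else:  # promoter on the higher-coordinate side
            p0, p1 = t1, t1 + promoter_span
        for blocks, (s, e) in ((tss_blocks, (t0, t1)), (prom_blocks, (p0, p1))):
            s = max(0, s)
            if limit is not None:
                e = min(e, limit)
            if e > s:
                blocks.append((g.chrom, s, e))

    def _mk(blocks: list[tuple[str, int, int]], label: str) -> IntervalSet:
        return IntervalSet(
            [b[0] for b in blocks],
            [b[1] for b in blocks],
            [b[2] for b in blocks],
            source_label=label,
        )

    category_intervals = {
        "TSS": _mk(tss_blocks, "TSS"),
        "promoter": _mk(prom_blocks, "promoter"),
        "5UTR": cats["5UTR"],
        "3UTR": cats["3UTR"],
        "exon": cats["exon"],
        "intron": cats["intron"],
    }
    # intergenic = complement of the union of every gene-linked category
    inter_blocks: list[tuple[str, int, int]] = []
    if chrom_sizes:
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
        for ivs in category_intervals.values():
            for i in range(len(ivs)):
                chrom = str(ivs.chroms[i])
                if chrom in occupied:
                    occupied[chrom].append((int(ivs.starts[i]), int(ivs.ends[i])))
        from .gene_models import _merge, _subtract

        for chrom, size in chrom_sizes.items():
            for s, e in _subtract((0, size), _merge(occupied[chrom])):
                inter_blocks.append((chrom, s, e))
    category_intervals["intergenic"] = _mk(inter_blocks, "intergenic")
    return AnnotationSet(
        categories=list(DEFAULT_PRECEDENCE),
        category_intervals=category_intervals,
        precedence=list(DEFAULT_PRECEDENCE),
    )


def annotation_from_bed(bed: IntervalSet) -> AnnotationSet:
    """Custom annotation: BED name column (column 4) names each category."""
    names = sorted({str(n) for n in bed.names})
    category_intervals: dict[str, IntervalSet] = {}
    for name in names:
        sel = np.flatnonzero(bed.names.astype(str) == name)
        category_intervals[name] = bed.subset(sel)
        category_intervals[name].source_label = name
    categories = names + ["unassigned"]
    category_intervals["unassigned"] = IntervalSet([], [], [], source_label="unassigned")
    return AnnotationSet(
        categories=categories, category_intervals=category_intervals, precedence=categories
    )


def classify_regions(
    regions: IntervalSet, annotation: AnnotationSet, multi_label: bool = False
) -> dict[str, int]:
    """Count regions per category.

    Single-label (default): each region is assigned the highest-precedence
    category it overlaps; the final precedence entry is the fallback for
    regions overlapping nothing, so counts sum to |regions|.  Multi-label:
    a region increments every category it overlaps (fallback only when it
    overlaps none).
    """
    counts = {cat: 0 for cat in annotation.precedence}
    fallback = annotation.precedence[-1]
    for i in range(len(regions)):
        qs = np.array([int(regions.starts[i])], dtype=np.int64)
        qe = np.array([int(regions.ends[i])], dtype=np.int64)
        chrom = str(regions.chroms[i])
        assigned = False
        for cat in annotation.precedence[:-1]:
            index = annotation._indices[cat]
            if chrom in index and bool(index[chrom].any_overlap(qs, qe)[0]):
                counts[cat] += 1
                assigned = True
                if not multi_label:
                    break
        if not assigned:
            counts[fallback] += 1
    return counts


def localization_test(
    input_set: IntervalSet,
    annotation: AnnotationSet,
    background: IntervalSet | None = None,
    chrom_sizes: dict[str, int] | None = None,
    generate_bg: bool = False,
    n_randomizations: int = 100,
    seed: int = 0,
) -> LocalizationResult:
    """Per-category Z-scores: real category counts vs the null distribution
    of category counts over randomized sets (intersect-mode analysis)."""
    config = TestConfig(mode="intersect", n_randomizations=n_randomizations, seed=seed)
    null_sets = draw_null_sets(input_set, background, config, chrom_sizes, generate_bg)
    real_counts = classify_regions(input_set, annotation)
    null_counts = [classify_regions(ns, annotation) for ns in null_sets]
    results = []
    for cat in annotation.precedence:
        null = NullSample(
            np.array([nc[cat] for nc in null_counts], dtype=float), "overlap_count"
        )
        results.append(
            z_score(float(real_counts[cat]), null, test_type="strandless", target_label=cat)
        )
    return LocalizationResult(counts=real_counts, results=results)
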