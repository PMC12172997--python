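"""Gene models from GTF annotation: per-gene TSS, exons, introns and UTRs.

GTF is 1-based closed; everything here is converted on read to the package's
0-based half-open convention.  The TSS is the gene start on the + strand and
``gene end - 1`` on the - strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import BedParseError
from .intervals import IntervalSet


def _merge(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open blocks."""
    if not blocks:
        return []
    blocks = sorted(blocks)
    out = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(span: tuple[int, int], blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Half-open set subtraction: span minus merged blocks."""
    out = []
    cursor = span[0]
    for s, e in blocks:
        if s > cursor:
            out.append((cursor, min(s, span[1])))
        cursor = max(cursor, e)
        if cursor >= span[1]:
            break
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return [(s, e) for s, e in out if e > s]


@dataclass
class GeneModel:
    """One gene: body extent, TSS, exon/intron/UTR blocks (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gene body minus exons; disjoint from exons by construction."""
        return _subtract((self.start, self.end), _merge(self.exons))


@dataclass
class GeneModelSet:
    genes: dict[str, GeneModel]

    def __len__(self) -> int:
        return len(self.genes)

    def category_intervals(self) -> dict[str, IntervalSet]:
        """Gene-structure blocks as IntervalSets (gene_body, exon, intron, UTRs)."""
        cats: dict[str, list[tuple[str, int, int, str]]] = {
            "gene_body": [],
            "exon": [],
            "intron": [],
            "5UTR": [],
            "3UTR": [],
        }
        for g in self.genes.values():
            cats["gene_body"].append((g.chrom, g.start, g.end, g.strand))
            for s, e in _merge(g.exons):
                cats["exon"].append((g.chrom, s, e, g.strand))
            for s, e in g.introns:
                cats["intron"].append((g.chrom, s, e, g.strand))
            for s, e in g.utr5:
                cats["5UTR"].append((g.chrom, s, e, g.strand))
            for s, e in g.utr3:
                cats["3UTR"].append((g.chrom, s, e, g.strand))
        out = {}
        for name, blocks in cats.items():
            out[name] = IntervalSet(
                [b[0] for b in blocks],
                [b[1] for b in blocks],
                [b[2] for b in blocks],
                strands=[b[3] for b in blocks],
                source_label=name,
            )
        return out


_UTR5_TYPES = {"five_prime_utr", "5utr", "five_prime_UTR"}
_UTR3_TYPES = {"three_prime_utr", "3utr", "three_prime_UTR"}


def read_gtf_gene_models(path: str | Path) -> GeneModelSet:
    """Parse a GTF into one :class:`GeneModel` per gene id via ``gffutils``.

    Accepts GTFs with explicit ``gene`` features or infers gene extents from
    transcripts/exons (gffutils' default inference).  Raises on missing
    strand or unparseable attributes.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}

    def _gene_id(feature) -> str:
        try:
            return feature.attributes["gene_id"][0]
        except (KeyError, IndexError) as exc:
            raise BedParseError(
                f"{Path(path).name}: feature at {feature.seqid}:{feature.start} lacks gene_id"
            ) from exc

    for feature in db.all_features():
        if feature.strand not in ("+", "-"):
            raise BedParseError(
                f"{Path(path).name}: feature at {feature.seqid}:{feature.start} lacks strand"
            )
        gid = _gene_id(feature)
        start0, end0 = feature.start - 1, feature.end  # 1-based closed -> 0-based half-open
        model = genes.get(gid)
        if model is None:
            model = genes[gid] = GeneModel(gid, feature.seqid, start0, end0, feature.strand)
        model.start = min(model.start, start0)
        model.end = max(model.end, end0)
        ftype = feature.featuretype.lower()
        if ftype == "exon":
            model.exons.append((start0, end0))
        elif ftype in _UTR5_TYPES:
            model.utr5.append((start0, end0))
        elif ftype in _UTR3_TYPES:
            model.utr3.append((start0, end0))
    return GeneModelSet(genes)
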