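"""Genomic intervals: the universal currency of every test in this package.

Coordinates are BED-native throughout: 0-based, half-open ``[start, end)``.
An :class:`IntervalSet` is a thin, always-sorted wrapper around parallel
numpy arrays; :class:`GenomicInterval` is the scalar record used at module
boundaries and in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import BedParseError, ValidationError

#: Sentinel for a record whose source lacked a strand column.
STRAND_UNKNOWN = "."

_VALID_STRANDS = {"+", "-", STRAND_UNKNOWN}

#: Lines beginning with these tokens are skipped when reading BED.
_BED_SKIP_PREFIXES = ("track", "browser", "#")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic region.

    Parameters
    ----------
    chrom : chromosome identifier, taken literally (no "chr" aliasing).
    start, end : 0-based half-open bounds, ``0 <= start < end``.
    name : optional label; ``"."`` when absent.
    score : optional real number (the per-region score ``Si`` in ranking
        mode); ``None`` when the source record had no column 5.
    strand : ``"+"``, ``"-"`` or ``"."`` (unknown; only when the source
        record lacked column 6).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"zero- or negative-length interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered, coordinate-sorted collection of genomic intervals.

    Backed by parallel numpy arrays for vectorised overlap/distance work.
    Duplicate identical records are retained; counts must reflect the file
    as given.  Sorting is total and deterministic: ``(chrom, start, end,
    name, strand)``.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        names: Sequence[str] | None = None,
        scores: Sequence[float] | None = None,
        strands: Sequence[str] | None = None,
        source_label: str = "intervals",
        _presorted: bool = False,
    ) -> None:
        n = len(chroms)
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.names = (
            np.asarray(names, dtype=object)
            if names is not None
            else np.full(n, ".", dtype=object)
        )
        self.scores = (
            np.asarray(scores, dtype=float)
            if scores is not None
            else np.full(n, np.nan, dtype=float)
        )
        self.strands = (
            np.asarray(strands, dtype=object)
            if strands is not None
            else np.full(n, STRAND_UNKNOWN, dtype=object)
        )
        self.source_label = source_label
        if np.any(self.starts < 0) or np.any(self.ends <= self.starts):
            bad = int(np.flatnonzero((self.starts < 0) | (self.ends <= self.starts))[0])
            raise ValidationError(
                f"invalid interval {self.chroms[bad]}:{self.starts[bad]}-{self.ends[bad]}"
            )
        if not _presorted:
            self._sort()

    def _sort(self) -> None:
        order = np.lexsort(
            (
                self.strands.astype(str),
                self.names.astype(str),
                self.ends,
                self.starts,
                self.chroms.astype(str),
            )
        )
        for attr in ("chroms", "starts", "ends", "names", "scores", "strands"):
            setattr(self, attr, getattr(self, attr)[order])

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[GenomicInterval], source_label: str = "intervals"
    ) -> "IntervalSet":
        return cls(
            [iv.chrom for iv in intervals],
            [iv.start for iv in intervals],
            [iv.end for iv in intervals],
            [iv.name for iv in intervals],
            [np.nan if iv.score is None else iv.score for iv in intervals],
            [iv.strand for iv in intervals],
            source_label=source_label,
        )

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> GenomicInterval:
        score = self.scores[i]
        return GenomicInterval(
            str(self.chroms[i]),
            int(self.starts[i]),
            int(self.ends[i]),
            str(self.names[i]),
            None if np.isnan(score) else float(score),
            str(self.strands[i]),
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        for i in range(len(self)):
            yield self[i]

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def has_scores(self) -> bool:
        return len(self) > 0 and not np.any(np.isnan(self.scores))

    @property
    def has_strands(self) -> bool:
        return len(self) > 0 and not np.any(self.strands == STRAND_UNKNOWN)

    def chrom_names(self) -> set[str]:
        return set(self.chroms.tolist())

    def subset(self, indices: np.ndarray | Sequence[int]) -> "IntervalSet":
        """New (re-sorted) set containing the selected records."""
        idx = np.asarray(indices, dtype=np.int64)
        return IntervalSet(
            self.chroms[idx],
            self.starts[idx],
            self.ends[idx],
            self.names[idx],
            self.scores[idx],
            self.strands[idx],
            source_label=self.source_label,
        )

    def concat(self, other: "IntervalSet", source_label: str | None = None) -> "IntervalSet":
        return IntervalSet(
            np.concatenate([self.chroms, other.chroms]),
            np.concatenate([self.starts, other.starts]),
            np.concatenate([self.ends, other.ends]),
            np.concatenate([self.names, other.names]),
            np.concatenate([self.scores, other.scores]),
            np.concatenate([self.strands, other.strands]),
            source_label=source_label or self.source_label,
        )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return format(score, "g")


def read_bed(path: str | Path, require_score: bool = False, label: str | None = None) -> IntervalSet:
    """Read a 3–6+ column BED file into a sorted :class:`IntervalSet`.

    Columns beyond 6 are ignored; missing name/score/strand are filled with
    ``"."`` / absent / unknown.  Lines starting with ``track``, ``browser``
    or ``#`` are skipped.  With ``require_score``, column 5 must parse as a
    real number on every record (ranking mode).
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    scores: list[float] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path.name}:{lineno}: malformed coordinates {fields[1]!r}/{fields[2]!r}"
                ) from exc
            if start < 0 or end <= start:
                raise ValidationError(
                    f"{path.name}:{lineno}: invalid interval [{start}, {end}) (zero-length or negative)"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "" else "."
            score = np.nan
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    if require_score:
                        raise ValidationError(
                            f"{path.name}:{lineno}: non-numeric score {fields[4]!r}"
                        ) from exc
            elif require_score:
                raise ValidationError(f"{path.name}:{lineno}: missing score in column 5")
            strand = STRAND_UNKNOWN
            if len(fields) > 5 and fields[5] in ("+", "-"):
                strand = fields[5]
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            names.append(name)
            scores.append(score)
            strands.append(strand)
    return IntervalSet(
        chroms, starts, ends, names, scores, strands, source_label=label or path.name
    )


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write a 6-column BED (``.`` fillers for absent name/score/strand)."""
    with open(path, "w") as fh:
        for i in range(len(intervals)):
            score = intervals.scores[i]
            fh.write(
                "\t".join(
                    [
                        str(intervals.chroms[i]),
                        str(int(intervals.starts[i])),
                        str(int(intervals.ends[i])),
                        str(intervals.names[i]),
                        "." if np.isnan(score) else _format_score(float(score)),
                        str(intervals.strands[i]),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA sequence content
# ---------------------------------------------------------------------------

_AT = frozenset("ATat")
_GC = frozenset("GCgc")


def at_gc_content(interval: GenomicInterval, genome) -> tuple[float, float]:
    """AT and GC fraction of an interval's sequence (case-insensitive).

    ``genome`` is a ``pyfaidx.Fasta`` handle.  ``N`` and other ambiguity
    codes are excluded from both numerators but kept in the denominator, so
    ``at + gc + ambiguous == 1``.
    """
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} absent from FASTA")
    chrom_len = len(genome[interval.chrom])
    if interval.end > chrom_len:
        raise ValidationError(
            f"interval end {interval.end} exceeds {interval.chrom} length {chrom_len}"
        )
    seq = str(genome[interval.chrom][interval.start : interval.end])
    n = len(seq)
    at = sum(1 for b in seq if b in _AT)
    gc = sum(1 for b in seq if b in _GC)
    return at / n, gc / n


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column text file: chromosome, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{Path(path).name}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def chrom_sizes_from_fasta(genome) -> dict[str, int]:
    return {name: len(genome[name]) for name in genome.keys()}


def warn_if_disjoint_chromosomes(a: IntervalSet, b: IntervalSet) -> None:
    """Mismatched chromosome naming between files is the user's problem,
    but zero shared names almost always means a naming-convention clash."""
    if a.chrom_names() and b.chrom_names() and not (a.chrom_names() & b.chrom_names()):
        warnings.warn(
            f"{a.source_label} and {b.source_label} share no chromosome names; "
            "check naming conventions (e.g. 'chr1' vs '1')",
            stacklevel=2,
        )
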