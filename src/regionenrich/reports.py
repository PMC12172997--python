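"""Result-table serialisation (the published 7-column schema)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .randomization import ZResult

COLUMNS = ("Z-Score", "Type", "p-value", "Target", "Real", "Random", "sd")


def _fmt_real(value: float) -> str:
    if float(value).is_integer():
        return str(int(value))
    return f"{value:.2f}"


def format_row(r: ZResult) -> list[str]:
    """Z and means/SD to 2 decimals, p in scientific notation with 2
    significant digits — the published table rendering."""
    return [
        f"{r.z:.2f}",
        r.test_type,
        f"{r.p_value:.2e}",
        r.target_label,
        _fmt_real(r.real),
        f"{r.random_mean:.2f}",
        f"{r.random_sd:.2f}",
    ]


def write_result_table(results: Sequence[ZResult], path: str | Path) -> None:
    """One row per (target, test type), tab-separated, fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in results:
            fh.write("\t".join(format_row(r)) + "\n")


def write_ranked_table(curve, regions, path: str | Path) -> None:
    """Per-region ranked output: rank, region, score, hit/distance, leading flag."""
    is_es = hasattr(curve, "running")
    with open(path, "w") as fh:
        if is_es:
            fh.write("rank\tchrom\tstart\tend\tname\tscore\thit\trunning_ES\tleading\n")
        else:
            fh.write("rank\tchrom\tstart\tend\tname\tscore\tdistance\ts_real\tleading\n")
        leading = set(curve.leading_ranks.tolist())
        for rank, idx in enumerate(curve.order):
            iv = regions[int(idx)]
            if is_es:
                extra = [str(int(curve.hits_in_order[rank])), f"{curve.running[rank]:.4f}"]
            else:
                extra = [
                    f"{curve.distances_in_order[rank]:.0f}",
                    f"{curve.s_real[rank]:.4f}",
                ]
            fh.write(
                "\t".join(
                    [
                        str(rank + 1),
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name,
                        f"{iv.score:g}" if iv.score is not None else ".",
                        *extra,
                        str(int(rank in leading)),
                    ]
                )
                + "\n"
            )
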