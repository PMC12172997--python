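"""Figure writers: null-density plot with observed-value marker, ranked
enrichment/cumulative-distance plots, and the per-category Z heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns
from scipy import stats

from .ranking import DistanceCurve, ESCurve


def write_density_plot(
    null_values, real: float, path: str | Path, title: str | None = None
) -> None:
    """Kernel density of the null sample with a red dashed marker at the
    observed value and a black dashed marker at the null mean.  Falls back
    to a histogram when the null is degenerate (sd = 0), where a KDE is
    undefined."""
    values = np.asarray(null_values, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(values) > 1 and np.std(values) > 0:
        kde = stats.gaussian_kde(values)
        lo = min(values.min(), real)
        hi = max(values.max(), real)
        pad = 0.1 * (hi - lo) if hi > lo else 1.0
        xs = np.linspace(lo - pad, hi + pad, 512)
        ax.plot(xs, kde(xs), color="steelblue")
        ax.fill_between(xs, kde(xs), alpha=0.3, color="steelblue")
    else:
        ax.hist(values, bins=10, color="steelblue", alpha=0.6)
    ax.axvline(real, color="red", linestyle="--", label="observed")
    ax.axvline(float(np.mean(values)), color="black", linestyle="--", label="null mean")
    ax.set_xlabel("statistic")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_es_plot(curve: ESCurve | DistanceCurve, path: str | Path, title: str | None = None) -> None:
    """Running enrichment curve with peak marker, hit tick-marks and
    leading-region shading (intersect variant), or real-vs-shuffled mean
    cumulative distance curves (closest variant)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    if isinstance(curve, ESCurve):
        ranks = np.arange(1, len(curve.running) + 1)
        ax.plot(ranks, curve.running, color="tab:blue", label="running ES")
        ax.axhline(0.0, color="gray", linewidth=0.8)
        for r in ranks[curve.hits_in_order]:
            ax.axvline(r, color="gray", linestyle="--", alpha=0.25, linewidth=0.7)
        ax.plot(
            curve.peak_index + 1,
            curve.es_signed,
            "o",
            color="red",
            label=f"max ES = {curve.es_signed:+.3f}",
        )
        if len(curve.leading_ranks):
            ax.axvspan(
                curve.leading_ranks[0] + 1,
                curve.leading_ranks[-1] + 1,
                alpha=0.12,
                color="orange",
                label="leading regions",
            )
        ax.set_ylabel("enrichment score")
        if title is None and curve.p_value is not None:
            title = f"ES = {curve.es_final:.3f}, p = {curve.p_value:.3g}"
    else:
        ranks = np.arange(1, len(curve.s_real) + 1)
        ax.plot(ranks, curve.s_real, color="tab:blue", label="real cumulative distance")
        ax.plot(ranks, curve.s_shuffle_mean, color="red", label="shuffled mean")
        ax.plot(curve.peak_index + 1, curve.s_real[curve.peak_index], "o", color="red")
        if len(curve.leading_ranks):
            ax.axvspan(
                curve.leading_ranks[0] + 1,
                curve.leading_ranks[-1] + 1,
                alpha=0.12,
                color="orange",
                label="leading regions",
            )
        ax.set_ylabel("normalized cumulative distance")
        if title is None:
            title = f"ES = {curve.es * curve.es_sign:+.3f}, KS p = {curve.ks_p:.3g}"
    ax.set_xlabel("rank")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_z_heatmap(z_matrix, path: str | Path, title: str | None = None) -> None:
    """Z-score heatmap (rows: categories or targets) from a DataFrame."""
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * z_matrix.shape[1], 0.6 * z_matrix.shape[0] + 1.5))
    sns.heatmap(z_matrix, annot=True, fmt=".2f", cmap="vlag", center=0.0, ax=ax)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
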