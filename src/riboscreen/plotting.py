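"""Diagnostic plot: the classic two-cloud active-translation scatter."""

from __future__ import annotations

import pandas as pd


def plot_score_scatter(
    morf_scores: pd.DataFrame,
    linc_scores: pd.DataFrame,
    thresholds=None,
    ax=None,
):
    """Scatter of log10 RRS (x) vs ORF score (y) for mORFs and lincORFs.

    Dashed lines mark the calibrated thresholds when given. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    for df, label, color in (
        (morf_scores, "mORF", "tab:blue"),
        (linc_scores, "lincORF", "tab:purple"),
    ):
        sub = df.dropna(subset=["log10_rrs"])
        ax.scatter(sub["log10_rrs"], sub["orf_score"], s=6, alpha=0.5,
                   label=label, color=color)
    if thresholds is not None:
        ax.axvline(thresholds.rrs_threshold, ls="--", c="grey", lw=1)
        ax.axhline(thresholds.orfscore_threshold, ls="--", c="grey", lw=1)
    ax.set_xlabel("log10 RRS")
    ax.set_ylabel("ORF score")
    ax.legend(frameon=False)
    return ax
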