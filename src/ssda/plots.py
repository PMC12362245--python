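"""Volcano / effect plot exports.

The tested surface is the exported table: everything needed to draw a
volcano plot (difference vs -log10 expected q) and an effect plot
(within-group dispersion vs between-group difference), with each feature
classified by how its significance responds to the scale model.  Rendering
is optional and cosmetic (requires matplotlib).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: mutually exclusive significance classes
CLASSES = ("robust", "scale-sensitive", "scale-emergent", "ns")


def export_plot_data(
    rt: pd.DataFrame,
    naive_rt: pd.DataFrame | None = None,
    q_max: float = 0.05,
    min_abs_diff: float = 1.4,
    test: str = "t",
) -> pd.DataFrame:
    """Per-feature plot table with significance classes.

    Classes compare the scaled analysis ``rt`` against the scale-naive
    analysis ``naive_rt`` (same features, e.g. a gamma = 0 run): ``robust``
    (significant under both), ``scale-sensitive`` (naive only),
    ``scale-emergent`` (scaled only), ``ns`` (neither).  Without a naive
    table the classes collapse to significant/ns under the scaled scheme.
    ``sig_dual`` additionally applies the |difference| >= ``min_abs_diff``
    fold-change cutoff to the naive scheme (the practice scale uncertainty
    replaces).
    """
    qcol = {"t": "eq_t", "w": "eq_w"}[test]
    out = rt[["feature_id", "diff_btw", "diff_win"]].copy()
    out["neg_log10_eq"] = -np.log10(np.maximum(rt[qcol].to_numpy(), 1e-300))
    sig_scaled = rt[qcol].to_numpy() <= q_max
    if naive_rt is not None:
        if list(naive_rt["feature_id"]) != list(rt["feature_id"]):
            raise ValueError("naive and scaled tables must cover the same features in order")
        sig_naive = naive_rt[qcol].to_numpy() <= q_max
        sig_dual = sig_naive & (naive_rt["diff_btw"].abs().to_numpy() >= min_abs_diff)
    else:
        sig_naive = sig_scaled
        sig_dual = sig_scaled & (rt["diff_btw"].abs().to_numpy() >= min_abs_diff)
    out["sig_naive"] = sig_naive
    out["sig_scaled"] = sig_scaled
    out["sig_dual"] = sig_dual
    cls = np.where(
        sig_scaled & sig_naive, "robust",
        np.where(sig_naive, "scale-sensitive", np.where(sig_scaled, "scale-emergent", "ns")),
    )
    if naive_rt is None:
        cls = np.where(sig_scaled, "significant", "ns")
    out["sig_class"] = cls
    return out


def render_plots(
    plot_df: pd.DataFrame, volcano_path: str | None = None,
    effect_path: str | None = None, lfc_line: float = 1.4,
) -> None:
    """Optional rendering of the exported table (dashed +/- lfc guides)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"robust": "red", "scale-sensitive": "orange",
              "scale-emergent": "royalblue", "significant": "red", "ns": "black"}
    c = plot_df["sig_class"].map(colors).fillna("grey")
    if volcano_path:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(plot_df["diff_btw"], plot_df["neg_log10_eq"], s=4, c=c, alpha=0.6)
        for x in (-lfc_line, lfc_line):
            ax.axvline(x, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("between-group difference (log2)")
        ax.set_ylabel("-log10 expected q")
        fig.tight_layout()
        fig.savefig(volcano_path, dpi=150)
        plt.close(fig)
    if effect_path:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(plot_df["diff_win"], plot_df["diff_btw"], s=4, c=c, alpha=0.6)
        for y in (-lfc_line, lfc_line):
            ax.axhline(y, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("within-group dispersion (log2)")
        ax.set_ylabel("between-group difference (log2)")
        fig.tight_layout()
        fig.savefig(effect_path, dpi=150)
        plt.close(fig)
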