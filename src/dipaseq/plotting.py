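"""Volcano and DiPa scatter plots with the classification geometry drawn."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from dipaseq.de import ALPHA_DEFAULT, TAU_DEFAULT
from dipaseq.dipa import EXTREME_LOG2_DEFAULT


def volcano_plot(cr: pd.DataFrame, tau: float = TAU_DEFAULT, alpha: float = ALPHA_DEFAULT, use_adjusted: bool = True, ax=None):
    """Volcano scatter: log2 fold change vs -log10 p with threshold lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    p = cr["p_adj"] if use_adjusted else cr["p_raw"]
    neglog = -np.log10(np.clip(p, 1e-300, None))
    sig = (p < alpha) & (cr["log2fc"].abs() >= tau)
    ax.scatter(cr.loc[~sig, "log2fc"], neglog[~sig], s=4, c="black", alpha=0.5)
    ax.scatter(cr.loc[sig, "log2fc"], neglog[sig], s=4, c="red", alpha=0.7)
    for v in (tau, -tau):
        ax.axvline(v, ls=":", c="grey")
    ax.axhline(-np.log10(alpha), ls=":", c="grey")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    return ax


def dipa_plot(dt: pd.DataFrame, tau: float = TAU_DEFAULT, extreme_log2: float = EXTREME_LOG2_DEFAULT, ax=None):
    """DiPa scatter (x = BDL/sham, y = treated/sham) with region boundaries."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5.5))
    dereg = dt["dereg"] != "ns"
    ax.scatter(dt.loc[~dereg, "x"], dt.loc[~dereg, "y"], s=4, c="grey", alpha=0.4)
    ax.scatter(dt.loc[dereg, "x"], dt.loc[dereg, "y"], s=5, c="tab:red", alpha=0.6)
    lim = max(1.0, dt["x"].abs().max(), dt["y"].abs().max()) * 1.05
    span = np.array([-lim, lim])
    ax.plot(span, span, c="black", lw=0.8)
    ax.plot(span, span - tau, c="black", lw=0.5, ls="--")
    ax.plot(span, span + tau, c="black", lw=0.5, ls="--")
    for v in (tau, -tau):
        ax.axhline(v, ls=":", c="grey")
        ax.axvline(v, ls=":", c="grey")
    for v in (extreme_log2, -extreme_log2):
        ax.axvline(v, ls="-.", c="tab:blue", lw=0.7)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("log2 (BDL+vehicle / sham)")
    ax.set_ylabel("log2 (BDL+treatment / sham)")
    return ax


def save_dipa_plot(dt: pd.DataFrame, path: str | Path, **kwargs) -> None:
    ax = dipa_plot(dt, **kwargs)
    fig = ax.figure
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
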