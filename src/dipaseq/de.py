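"""Count normalization and per-gene two-group contrasts.

The differential-expression convention is deliberately simple and fully
specified: median-of-ratios size factors, log2(count/factor + pseudocount)
expression, Welch's t-test per gene, Benjamini-Hochberg adjustment, and a
volcano rule at fold-change threshold tau = log2(1.5) and alpha = 0.05.
The pattern-classification layer downstream only consumes (log2fc, p), so
a different per-gene test can be substituted without touching it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Default fold-change threshold on the log2 scale (1.5-fold).
TAU_DEFAULT = float(np.log2(1.5))
ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class VolcanoSummary:
    """Counts of up- / down-regulated and non-significant genes."""

    n_up: int
    n_down: int
    n_ns: int
    fc_threshold: float = TAU_DEFAULT
    alpha: float = ALPHA_DEFAULT

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down + self.n_ns


def filter_genes(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes whose total count across samples is >= ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    kept = counts.loc[counts.sum(axis=1) >= min_total]
    if kept.empty:
        warnings.warn("filter_genes removed every gene", stacklevel=2)
    return kept


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples, computed
    over genes with strictly positive counts in every sample; each
    sample's factor is the median ratio of its counts to that reference.
    If no gene is everywhere-positive the factors fall back to
    total-count ratios (relative to the geometric-mean total), with a
    warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        warnings.warn(
            "no gene with all-positive counts; falling back to total-count size factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("cannot compute size factors: a sample has zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        ref = mat[all_positive]
        log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
        ratios = ref / np.exp(log_geomean)
        factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size factor + pseudocount) expression matrix."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    fac = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(fac)) or np.any(fac <= 0):
        raise ValueError("size factors must be positive and defined for every sample")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / fac + pseudocount),
        index=counts.index,
        columns=counts.columns,
    )


def _select_samples(samples: pd.DataFrame, group: str, stage: str | None, organ: str | None) -> list[str]:
    mask = samples["arm"] == group
    if stage is not None:
        mask &= samples["stage"] == stage
    if organ is not None and "organ" in samples.columns:
        mask &= samples["organ"] == organ
    return samples.loc[mask, "sample_id"].tolist()


def test_contrast(
    em: pd.DataFrame,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    stage: str | None = None,
    organ: str | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test of ``group_b`` vs ``group_a`` (b minus a).

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean
    difference on the log2 scale), ``p_raw`` and BH-adjusted ``p_adj``.
    Genes with zero variance in both groups get p = 1 when the means are
    equal and the smallest positive float when they differ.
    """
    for group in (group_a, group_b):
        if group not in set(samples["arm"]):
            raise ValueError(f"unknown group label {group!r}")
    ids_a = _select_samples(samples, group_a, stage, organ)
    ids_b = _select_samples(samples, group_b, stage, organ)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(ids_a)} for {group_a!r}, "
            f"{len(ids_b)} for {group_b!r})"
        )
    a = em[ids_a].to_numpy(dtype=float)
    b = em[ids_b].to_numpy(dtype=float)

    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p_raw = stats.ttest_ind(b, a, axis=1, equal_var=False)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p_raw = np.where(degenerate & (log2fc == 0), 1.0, p_raw)
    p_raw = np.where(degenerate & (log2fc != 0), np.finfo(float).tiny, p_raw)

    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p_raw, "p_adj": p_adj},
        index=em.index.rename("gene_id"),
    )


test_contrast.__test__ = False  # not a pytest test despite the name


def classify_volcano(
    cr: pd.DataFrame,
    tau: float = TAU_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    use_adjusted: bool = True,
) -> tuple[pd.Series, VolcanoSummary]:
    """Volcano labels (``up`` / ``down`` / ``ns``) and their summary.

    A gene is ``up`` iff log2fc >= tau and p < alpha, ``down`` iff
    log2fc <= -tau and p < alpha, else ``ns``; p is BH-adjusted by
    default.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = cr["p_adj"] if use_adjusted else cr["p_raw"]
    sig = p < alpha
    labels = pd.Series(
        np.select(
            [sig & (cr["log2fc"] >= tau), sig & (cr["log2fc"] <= -tau)],
            ["up", "down"],
            default="ns",
        ),
        index=cr.index,
        name="volcano",
    )
    summary = VolcanoSummary(
        n_up=int((labels == "up").sum()),
        n_down=int((labels == "down").sum()),
        n_ns=int((labels == "ns").sum()),
        fc_threshold=float(tau),
        alpha=float(alpha),
    )
    return labels, summary


def pca_summary(em: pd.DataFrame, n_top_variance_genes: int = 500) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on PC1/PC2 of the top-variance genes.

    Genes are ranked by variance across samples; the selected block is
    centred (not scaled) before the decomposition. Returns coordinates
    (one row per sample) and the explained-variance fractions.
    """
    from sklearn.decomposition import PCA

    if em.shape[1] < 3:
        raise ValueError("pca_summary needs >= 3 samples")
    n_top = n_top_variance_genes
    if n_top > em.shape[0]:
        warnings.warn(
            f"n_top_variance_genes={n_top} exceeds gene count {em.shape[0]}; clamping",
            stacklevel=2,
        )
        n_top = em.shape[0]
    top = em.loc[em.var(axis=1).nlargest(n_top).index]
    x = top.to_numpy(dtype=float).T  # samples x genes
    n_comp = min(2, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    out = pd.DataFrame(coords, index=em.columns.rename("sample_id"), columns=cols)
    return out, pca.explained_variance_ratio_
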