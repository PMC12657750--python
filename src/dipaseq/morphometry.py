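"""Diameter-distribution statistics: Tukey fence and subsampling stability.

Bile-canalicular diameters are measured at every pixel of a canalicular
medial line, so each experimental group (stratum = treatment x timepoint)
contributes a very large sample. Two statistics from that setting live
here:

* the sham-referenced abnormality rule — a diameter is "abnormally wide"
  when it exceeds the Tukey upper fence Q3 + 1.5 (Q3 - Q1) of the sham
  control distribution;
* the stratified-subsampling stability analysis — fixed-size subsamples
  per stratum (e.g. 1,000,000 down to 1,000 by tenths), compared to the
  full stratum via the percent change of mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FenceSpec:
    """Quartiles of a reference distribution and its Tukey upper fence."""

    q1: float
    q3: float
    upper_fence: float

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError("q1 must not exceed q3")
        expected = self.q3 + 1.5 * (self.q3 - self.q1)
        if not np.isclose(self.upper_fence, expected, rtol=0, atol=1e-9 * max(1.0, abs(expected))):
            raise ValueError(f"upper_fence {self.upper_fence} != q3 + 1.5*(q3-q1) = {expected}")


def tukey_fence(reference: Sequence[float] | pd.Series) -> FenceSpec:
    """Tukey upper fence of a reference (sham) stratum.

    Quartiles use linear interpolation (numpy's default, R type 7); the
    fence is Q3 + 1.5 (Q3 - Q1). Requires at least 4 reference values.
    """
    values = np.asarray(reference, dtype=float)
    if values.size < 4:
        raise ValueError(f"need >= 4 reference values, got {values.size}")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return FenceSpec(q1=float(q1), q3=float(q3), upper_fence=float(q3 + 1.5 * (q3 - q1)))


def abnormal_subset(ds: pd.DataFrame, fence: FenceSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Measurements strictly exceeding the fence, with per-stratum fractions.

    ``ds`` has columns ``value`` and ``stratum``. Fractions are computed
    against each stratum's full size; strata with no abnormal values get
    fraction 0.
    """
    mask = ds["value"] > fence.upper_fence
    subset = ds.loc[mask]
    totals = ds.groupby("stratum", sort=True)["value"].size()
    abnormal = subset.groupby("stratum", sort=True)["value"].size().reindex(totals.index, fill_value=0)
    fractions = (abnormal / totals).rename("abnormal_fraction")
    return subset, fractions


def summarize_diameters(
    ds: pd.DataFrame,
    mode: str = "all",
    fence: FenceSpec | None = None,
) -> pd.DataFrame:
    """Per-stratum n, mean and sd, over all values or abnormal-only.

    ``mode="abnormal"`` restricts to values above the fence (which must
    then be given). Strata emptied by the filter appear with n = 0 and
    missing mean/sd rather than erroring. The sd of a single value is 0.
    """
    if mode not in ("all", "abnormal"):
        raise ValueError(f"mode must be 'all' or 'abnormal', got {mode!r}")
    strata = ds.groupby("stratum", sort=True)["value"].size().index
    if mode == "abnormal":
        if fence is None:
            raise ValueError("mode='abnormal' requires a fence")
        data = ds.loc[ds["value"] > fence.upper_fence]
    else:
        data = ds
    rows = []
    for stratum in strata:
        vals = data.loc[data["stratum"] == stratum, "value"].to_numpy(dtype=float)
        n = vals.size
        rows.append(
            {
                "stratum": stratum,
                "n": n,
                "mean": float(vals.mean()) if n else np.nan,
                "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


@dataclass
class SubsampleStabilityReport:
    """Percent changes of mean/sd between subsamples and full strata.

    ``per_stratum`` has one row per (stratum, subset_size) with columns
    ``pct_change_mean`` and ``pct_change_sd`` (100 |subsample - full| /
    |full|); ``per_size_max`` holds the maxima across strata per size.
    """

    per_stratum: pd.DataFrame
    per_size_max: pd.DataFrame
    subset_sizes: list[int]
    seed: int


def _pct_change(sub: float, full: float) -> float:
    if full == 0:
        return float("nan")
    return 100.0 * abs(sub - full) / abs(full)


def subsample_stability(
    ds: pd.DataFrame,
    subset_sizes: Sequence[int],
    seed: int = 0,
) -> SubsampleStabilityReport:
    """One seeded subsample per (stratum, size), compared to the full stratum.

    Sampling is without replacement within the stratum; each (stratum,
    size) pair gets an independent stream derived from ``seed``, so adding
    sizes or strata does not perturb the other draws. Sizes exceeding a
    stratum raise an error naming it.
    """
    sizes = [int(s) for s in subset_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("subset sizes must be >= 1")
    groups = {stratum: g["value"].to_numpy(dtype=float) for stratum, g in ds.groupby("stratum", sort=True)}
    for stratum, vals in groups.items():
        too_big = [s for s in sizes if s > vals.size]
        if too_big:
            raise ValueError(
                f"subset size {too_big[0]} exceeds stratum {stratum!r} (n={vals.size})"
            )
    rows = []
    for i, (stratum, vals) in enumerate(groups.items()):
        full_mean = vals.mean()
        full_sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        for size in sizes:
            rng = np.random.default_rng(np.random.SeedSequence([seed, i, size]))
            if size == vals.size:
                sub = vals
            else:
                sub = vals[rng.choice(vals.size, size, replace=False)]
            sub_sd = sub.std(ddof=1) if sub.size > 1 else 0.0
            rows.append(
                {
                    "stratum": stratum,
                    "subset_size": size,
                    "pct_change_mean": _pct_change(sub.mean(), full_mean),
                    "pct_change_sd": _pct_change(sub_sd, full_sd),
                }
            )
    per_stratum = pd.DataFrame(rows)
    per_size_max = (
        per_stratum.groupby("subset_size", sort=True)[["pct_change_mean", "pct_change_sd"]]
        .max()
        .rename(columns=lambda c: f"max_{c}")
    )
    return SubsampleStabilityReport(
        per_stratum=per_stratum,
        per_size_max=per_size_max,
        subset_sizes=sizes,
        seed=seed,
    )
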