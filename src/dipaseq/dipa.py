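"""DiPa pattern-group classification and rescue percentages.

The DiPa ("differentiation pattern") plot places every gene at
``x`` = log2 ratio of BDL + vehicle vs sham + vehicle and
``y`` = log2 ratio of BDL + treatment vs sham + vehicle. The geometry of
the plane then sorts genes deregulated by BDL into

* ``1a`` / ``1b`` — fully rescued: |y| back inside the normal band
  (|y| < tau, tau = log2 of the fold-change threshold),
* ``2a`` / ``2b`` — partially rescued: moved at least tau back from the
  BDL value but still outside the normal band,
* ``nta`` / ``ntb`` — not treatable: on or beyond the diagonal band
  (within tau of y = x, or past it, i.e. unaffected or worsened),
* ``overshoot_up`` / ``overshoot_down`` — pushed past the normal band to
  the opposite sign,

while genes untouched by BDL can be drug-only responders (``3a`` /
``3b``) or ``unchanged``. The "extreme region" is the subset of
deregulated genes with at least 17-fold BDL deregulation
(|x| >= log2 17).

The rescue percentage summarizes two volcano analyses per direction:
``100 * (1 - n_deregulated_treated / n_deregulated_vehicle)``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dipaseq.de import ALPHA_DEFAULT, TAU_DEFAULT, VolcanoSummary, classify_volcano

#: log2 cutoff of the extreme region ("at least 17-fold" deregulation).
EXTREME_LOG2_DEFAULT = float(np.log2(17.0))


class PatternLabel(str, enum.Enum):
    """Expression pattern groups of the DiPa plane."""

    P1A = "1a"
    P1B = "1b"
    P2A = "2a"
    P2B = "2b"
    P3A = "3a"
    P3B = "3b"
    NTA = "nta"
    NTB = "ntb"
    OVERSHOOT_UP = "overshoot_up"
    OVERSHOOT_DOWN = "overshoot_down"
    UNCHANGED = "unchanged"


PATTERN_LABELS = [label.value for label in PatternLabel]


def assign_pattern(x: float, y: float, dereg: str, y_sig: bool, tau: float = TAU_DEFAULT) -> PatternLabel:
    """Classify a single gene by its DiPa coordinates (scalar oracle).

    ``dereg`` is the volcano status of the x contrast (``up`` / ``down`` /
    ``ns``); ``y_sig`` is whether the y contrast is significant, consulted
    only for the drug-only groups 3a/3b. Boundary values belong to the
    more-rescued group: y = tau or y = x - tau is partially rescued (2a),
    not "not treatable".
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite DiPa coordinates: x={x}, y={y}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dereg == "up":
        if abs(y) < tau:
            return PatternLabel.P1A
        if y <= -tau:
            return PatternLabel.OVERSHOOT_DOWN
        if tau <= y <= x - tau:
            return PatternLabel.P2A
        return PatternLabel.NTA
    if dereg == "down":
        if abs(y) < tau:
            return PatternLabel.P1B
        if y >= tau:
            return PatternLabel.OVERSHOOT_UP
        if x + tau <= y <= -tau:
            return PatternLabel.P2B
        return PatternLabel.NTB
    if dereg == "ns":
        if y >= tau and y_sig:
            return PatternLabel.P3A
        if y <= -tau and y_sig:
            return PatternLabel.P3B
        return PatternLabel.UNCHANGED
    raise ValueError(f"unknown deregulation status {dereg!r}")


def label_patterns(
    x: np.ndarray,
    y: np.ndarray,
    dereg: np.ndarray,
    y_sig: np.ndarray,
    tau: float = TAU_DEFAULT,
) -> np.ndarray:
    """Vectorized :func:`assign_pattern` over gene arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite DiPa coordinates")
    if tau <= 0:
        raise ValueError("tau must be positive")
    dereg = np.asarray(dereg)
    y_sig = np.asarray(y_sig, dtype=bool)
    up = dereg == "up"
    down = dereg == "down"
    ns = dereg == "ns"
    bad = ~(up | down | ns)
    if bad.any():
        raise ValueError(f"unknown deregulation status {dereg[bad][0]!r}")

    in_band = np.abs(y) < tau
    labels = np.select(
        [
            up & in_band,
            up & (y <= -tau),
            up & (tau <= y) & (y <= x - tau),
            up,
            down & in_band,
            down & (y >= tau),
            down & (x + tau <= y) & (y <= -tau),
            down,
            ns & (y >= tau) & y_sig,
            ns & (y <= -tau) & y_sig,
        ],
        [
            PatternLabel.P1A.value,
            PatternLabel.OVERSHOOT_DOWN.value,
            PatternLabel.P2A.value,
            PatternLabel.NTA.value,
            PatternLabel.P1B.value,
            PatternLabel.OVERSHOOT_UP.value,
            PatternLabel.P2B.value,
            PatternLabel.NTB.value,
            PatternLabel.P3A.value,
            PatternLabel.P3B.value,
        ],
        default=PatternLabel.UNCHANGED.value,
    )
    return labels


def build_dipa_table(
    cx: pd.DataFrame,
    cy: pd.DataFrame,
    tau: float = TAU_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    use_adjusted: bool = True,
    extreme_log2: float = EXTREME_LOG2_DEFAULT,
) -> pd.DataFrame:
    """Assemble the per-gene DiPa table from the two contrasts.

    ``cx`` is the BDL + vehicle vs sham contrast, ``cy`` the treated vs
    sham contrast (both from :func:`dipaseq.de.test_contrast`). Genes are
    intersected (with a warning if the universes differ); the result has
    columns ``x, y, dereg, y_sig, label, extreme`` indexed by gene.
    """
    common = cx.index.intersection(cy.index)
    if len(common) == 0:
        raise ValueError("the two contrasts share no genes")
    if len(common) < max(len(cx), len(cy)):
        warnings.warn(
            f"contrast gene universes differ; using the {len(common)}-gene intersection",
            stacklevel=2,
        )
    cx = cx.loc[common]
    cy = cy.loc[common]
    dereg, _ = classify_volcano(cx, tau=tau, alpha=alpha, use_adjusted=use_adjusted)
    y_volc, _ = classify_volcano(cy, tau=tau, alpha=alpha, use_adjusted=use_adjusted)
    y_sig = (y_volc != "ns").to_numpy()
    x = cx["log2fc"].to_numpy()
    y = cy["log2fc"].to_numpy()
    labels = label_patterns(x, y, dereg.to_numpy(), y_sig, tau=tau)
    extreme = (dereg.to_numpy() != "ns") & (np.abs(x) >= extreme_log2)
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "dereg": dereg.to_numpy(),
            "y_sig": y_sig,
            "label": labels,
            "extreme": extreme,
        },
        index=common.rename("gene_id"),
    )


def extreme_subset(dt: pd.DataFrame, extreme_log2: float = EXTREME_LOG2_DEFAULT) -> pd.Index:
    """Genes deregulated by BDL with |x| >= log2(17) (the extreme region)."""
    if extreme_log2 <= 0:
        raise ValueError("extreme_log2 must be positive")
    mask = (dt["dereg"] != "ns") & (dt["x"].abs() >= extreme_log2)
    return dt.index[mask]


def pattern_group_sizes(dt: pd.DataFrame) -> dict[str, int]:
    """Gene counts per pattern group, over the full label set."""
    counts = dt["label"].value_counts()
    return {label: int(counts.get(label, 0)) for label in PATTERN_LABELS}


def rescue_percentage(n_vehicle: int, n_treated: int) -> float:
    """Percent of vehicle-deregulated genes no longer deregulated under
    treatment: ``100 * (1 - n_treated / n_vehicle)``, one decimal.

    Negative when treatment deregulates more genes than vehicle; NaN when
    the vehicle count is zero (undefined).
    """
    if n_vehicle < 0 or n_treated < 0:
        raise ValueError("gene counts must be non-negative")
    if n_vehicle == 0:
        return float("nan")
    return round(100.0 * (1.0 - n_treated / n_vehicle), 1)


@dataclass(frozen=True)
class RescueSummary:
    """Rescue percentage for one direction of deregulation."""

    organ: str
    stage: str
    direction: str  # "UP" or "DOWN"
    n_dereg_vehicle: int
    n_dereg_treated: int
    rescue_pct: float


def rescue_summary(
    volc_vehicle: VolcanoSummary,
    volc_treated: VolcanoSummary,
    organ: str,
    stage: str,
) -> tuple[RescueSummary, RescueSummary]:
    """Per-direction rescue summaries from two volcano analyses.

    Both summaries must come from the same gene universe and thresholds.
    """
    if volc_vehicle.n_total != volc_treated.n_total:
        raise ValueError(
            "volcano summaries cover different gene universes "
            f"({volc_vehicle.n_total} vs {volc_treated.n_total} genes)"
        )
    if (volc_vehicle.fc_threshold, volc_vehicle.alpha) != (
        volc_treated.fc_threshold,
        volc_treated.alpha,
    ):
        raise ValueError("volcano summaries use different thresholds")
    up = RescueSummary(
        organ=organ,
        stage=stage,
        direction="UP",
        n_dereg_vehicle=volc_vehicle.n_up,
        n_dereg_treated=volc_treated.n_up,
        rescue_pct=rescue_percentage(volc_vehicle.n_up, volc_treated.n_up),
    )
    down = RescueSummary(
        organ=organ,
        stage=stage,
        direction="DOWN",
        n_dereg_vehicle=volc_vehicle.n_down,
        n_dereg_treated=volc_treated.n_down,
        rescue_pct=rescue_percentage(volc_vehicle.n_down, volc_treated.n_down),
    )
    return up, down
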