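"""Pearson and Manders colocalization coefficients on dual-channel volumes.

Pearson's correlation coefficient

    R_p = sum_i (G_i - G_A)(R_i - R_A)
          / sqrt( sum_i (G_i - G_A)^2 * sum_i (R_i - R_A)^2 )

measures the covariance of the two emissions over all voxels (G_A, R_A are
the channel mean intensities).  It is invariant to affine detector settings
(gain and offset) but is sensitive to noise; it is computed on unthresholded
intensities, optionally restricted to a region of interest.

Manders coefficients express, per channel, the fraction of (above-threshold)
intensity found in voxels where the partner channel is also above its
threshold:

    M_G = sum(G_i colocalized) / sum(G_i),   M_R symmetric,

where a green voxel is "colocalized" when its red partner exceeds the red
background threshold (and symmetrically).  Both denominators run over the
above-threshold voxels of their own channel, so M_G and M_R live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DualChannelStack
from .cohort_stats import summarize

__all__ = [
    "ColocResult",
    "ConstantChannelError",
    "pearson_coloc",
    "manders_coeffs",
    "coloc_map",
    "compare_groups_coloc",
]


class ConstantChannelError(ValueError):
    """Raised when Pearson's coefficient is undefined (a channel has zero variance)."""


@dataclass(frozen=True)
class ColocResult:
    """Colocalization coefficients and the intensity sums behind them."""

    r_p: float
    m_green: float  # alias M_x: Manders coefficient for the green channel
    m_red: float  # alias M_y: Manders coefficient for the red channel
    green_mean: float
    red_mean: float
    green_colocalized: float
    red_colocalized: float
    green_total: float
    red_total: float
    n_voxels: int


def _channels(stack: DualChannelStack, roi: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(stack.green, dtype=np.float64)
    r = np.asarray(stack.red, dtype=np.float64)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != g.shape:
            raise ValueError(f"roi shape {roi.shape} does not match stack shape {g.shape}")
        g, r = g[roi], r[roi]
    return g.ravel(), r.ravel()


def pearson_coloc(stack: DualChannelStack, roi: np.ndarray | None = None) -> float:
    """Pearson's R_p over all voxels in the ROI (no thresholding).

    Raises
    ------
    ConstantChannelError
        If either channel is constant over the ROI, where the correlation is
        undefined; this is reported explicitly rather than returned as NaN.
    """
    g, r = _channels(stack, roi)
    if g.size < 2:
        raise ValueError("Pearson's coefficient needs at least two voxels")
    gd = g - g.mean()
    rd = r - r.mean()
    denom = np.sqrt((gd * gd).sum() * (rd * rd).sum())
    if denom == 0.0:
        raise ConstantChannelError("correlation undefined: a channel is constant over the ROI")
    return float((gd * rd).sum() / denom)


def manders_coeffs(
    stack: DualChannelStack,
    threshold_green: float,
    threshold_red: float,
    roi: np.ndarray | None = None,
) -> tuple[float, float]:
    """Manders (M_G, M_R) with per-channel background thresholds.

    A voxel contributes its green intensity to the M_G numerator when both
    ``G > threshold_green`` and ``R > threshold_red``; the denominator is the
    total green intensity above ``threshold_green`` in the ROI (and
    symmetrically for red).
    """
    g, r = _channels(stack, roi)
    g_above = g > threshold_green
    r_above = r > threshold_red
    g_total = g[g_above].sum()
    r_total = r[r_above].sum()
    if g_total <= 0 or r_total <= 0:
        raise ValueError(
            "Manders coefficients undefined: zero total above-threshold intensity "
            f"(green {g_total}, red {r_total})"
        )
    both = g_above & r_above
    m_g = float(g[both].sum() / g_total)
    m_r = float(r[both].sum() / r_total)
    return m_g, m_r


def coloc_result(
    stack: DualChannelStack,
    threshold_green: float,
    threshold_red: float,
    roi: np.ndarray | None = None,
) -> ColocResult:
    """Bundle R_p and thresholded Manders coefficients for one stack."""
    g, r = _channels(stack, roi)
    m_g, m_r = manders_coeffs(stack, threshold_green, threshold_red, roi)
    both = (g > threshold_green) & (r > threshold_red)
    return ColocResult(
        r_p=pearson_coloc(stack, roi),
        m_green=m_g,
        m_red=m_r,
        green_mean=float(g.mean()),
        red_mean=float(r.mean()),
        green_colocalized=float(g[both].sum()),
        red_colocalized=float(r[both].sum()),
        green_total=float(g.sum()),
        red_total=float(r.sum()),
        n_voxels=int(g.size),
    )


def coloc_map(
    stack: DualChannelStack,
    threshold_green: float | None = None,
    threshold_red: float | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Joint-intensity histogram (scatter map) of green vs red voxel intensities.

    Returns a 256x256 count matrix ``H[g, r]`` (green on the x-axis, red on
    the y-axis when plotted) whose grand total is the voxel count, plus the
    four quadrant totals defined by the thresholds (``None`` thresholds count
    everything as "low").
    """
    g = np.asarray(stack.green).ravel()
    r = np.asarray(stack.red).ravel()
    hist = np.zeros((256, 256), dtype=np.int64)
    np.add.at(hist, (g.astype(np.intp), r.astype(np.intp)), 1)
    tg = -np.inf if threshold_green is None else threshold_green
    tr = -np.inf if threshold_red is None else threshold_red
    g_above = g > tg
    r_above = r > tr
    quadrants = {
        "low_low": int((~g_above & ~r_above).sum()),
        "green_only": int((g_above & ~r_above).sum()),
        "red_only": int((~g_above & r_above).sum()),
        "colocalized": int((g_above & r_above).sum()),
    }
    return hist, quadrants


def compare_groups_coloc(
    per_image: pd.DataFrame,
    measures: tuple[str, ...] = ("r_p", "m_green", "m_red"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise per-image coefficients into subject medians and group median (IQR).

    ``per_image`` needs columns ``subject_id``, ``group`` and one column per
    coefficient.  Subjects are the unit of analysis: each subject's images are
    reduced to a median first, then groups are summarised as median and
    interquartile range of the subject-level values.
    """
    required = {"subject_id", "group", *measures}
    missing = required - set(per_image.columns)
    if missing:
        raise ValueError(f"per-image table missing columns {sorted(missing)}")
    if per_image.empty:
        raise ValueError("per-image table is empty")
    counts = per_image.groupby("group").size()
    if (counts == 0).any():
        raise ValueError("empty group in per-image table")

    subject = (
        per_image.groupby(["group", "subject_id"], sort=True)[list(measures)]
        .median()
        .reset_index()
    )
    rows = []
    for group, sub in subject.groupby("group", sort=True):
        for measure in measures:
            med, (q1, q3) = summarize(sub[measure].to_numpy())
            rows.append(
                {"group": group, "measure": measure, "median": med, "q1": q1, "q3": q3,
                 "n_subjects": len(sub)}
            )
    return subject, pd.DataFrame(rows)
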