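"""Background thresholding and voxel/intensity quantification.

The background rule used throughout the pipeline sets the lower intensity
threshold of a fluorescence channel to the mean voxel intensity plus two
standard deviations (population SD), so that under a roughly Gaussian
background only the upper ~2.3% tail of background voxels survives.  Voxels
*strictly above* the threshold are counted and their intensities summed.
Stain load is compared between images as summed above-threshold intensity
normalised by compartment area (per um^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdResult",
    "IntensityPerArea",
    "background_threshold",
    "voxel_summary",
    "intensity_per_area",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the mean + 2 SD background rule on one channel."""

    channel: str
    mean: float
    sd: float
    threshold: float
    n_voxels_above: int
    intensity_sum_above: float

    def __post_init__(self) -> None:
        if self.threshold < self.mean:
            raise ValueError("threshold must not be below the channel mean")


@dataclass(frozen=True)
class IntensityPerArea:
    """Above-threshold intensity inside a compartment, normalised by its area."""

    intensity_sum: float
    area_um2: float
    value: float  # intensity_sum / area_um2


def _masked(channel: np.ndarray, roi: np.ndarray | None) -> np.ndarray:
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("channel is empty")
    if roi is None:
        return channel.ravel()
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != channel.shape:
        raise ValueError(f"roi shape {roi.shape} does not match channel shape {channel.shape}")
    values = channel[roi]
    if values.size == 0:
        raise ValueError("roi selects no voxels")
    return values


def background_threshold(
    channel: np.ndarray,
    roi: np.ndarray | None = None,
    *,
    channel_id: str = "",
) -> ThresholdResult:
    """Apply the mean + 2 SD background rule to a 2D or 3D intensity array.

    The mean and the population standard deviation are computed over the
    voxels in ``roi`` (or the whole array), and the threshold is
    ``mean + 2 * SD``.  Counts and intensity sums cover voxels strictly above
    the threshold; a constant channel therefore yields SD 0 and zero voxels
    above (valid, not an error).
    """
    values = _masked(channel, roi).astype(np.float64)
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    threshold = mean + 2.0 * sd
    count, total = voxel_summary(values, threshold)
    return ThresholdResult(
        channel=channel_id,
        mean=mean,
        sd=sd,
        threshold=threshold,
        n_voxels_above=count,
        intensity_sum_above=total,
    )


def voxel_summary(
    channel: np.ndarray,
    threshold: float,
    roi: np.ndarray | None = None,
) -> tuple[int, float]:
    """Count voxels strictly above ``threshold`` and sum their intensities."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    values = _masked(channel, roi).astype(np.float64)
    above = values > threshold
    return int(above.sum()), float(values[above].sum())


def intensity_per_area(
    channel: np.ndarray,
    compartment_mask: np.ndarray,
    threshold: float,
    pixel_size: float,
) -> IntensityPerArea:
    """Sum above-threshold intensity inside a compartment and divide by its area.

    ``pixel_size`` is the pixel side in micrometres, so the compartment area
    is ``mask pixel count * pixel_size**2`` (um^2) and the result has units
    of intensity per um^2.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be strictly positive")
    mask = np.asarray(compartment_mask, dtype=bool)
    if not mask.any():
        raise ValueError("compartment mask is empty")
    _, total = voxel_summary(channel, threshold, roi=mask)
    area = float(mask.sum()) * pixel_size**2
    return IntensityPerArea(intensity_sum=total, area_um2=area, value=total / area)
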