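"""Western-blot lane densitometry: lane profiles, band volumes, loading ratios.

A lane is reduced to a 1D intensity profile along the migration axis (mean
across the lane width).  Band "volume" is the profile integral above a local
linear baseline drawn between the integration-window endpoints, and protein
abundance is reported as the ratio of a band's volume to the beta-actin
loading-control volume from the same lane, which cancels loading and
exposure differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LaneProfile",
    "BandQuant",
    "lane_profile",
    "integrate_band",
    "normalize_to_loading",
]


@dataclass(frozen=True)
class LaneProfile:
    """1D intensity profile along the migration axis of one lane."""

    intensity: np.ndarray  # profile values, bands as peaks
    lane_columns: tuple[int, int]  # half-open column range the lane was averaged over

    def __len__(self) -> int:
        return int(self.intensity.size)


@dataclass(frozen=True)
class BandQuant:
    """One band's integrated volume and its loading-normalised ratio."""

    label: str
    window: tuple[int, int]
    volume: float
    ratio_to_control: float | None = None


def lane_profile(
    gel_image: np.ndarray,
    lane_columns: tuple[int, int],
    dark_bands: bool = False,
) -> LaneProfile:
    """Average a lane's columns into a migration-axis profile.

    ``gel_image`` is a 2D grayscale array with migration along axis 0 (rows)
    and lanes side by side along axis 1 (columns); ``lane_columns`` is the
    half-open ``(start, stop)`` column range of the lane.  With
    ``dark_bands=True`` (bands darker than the background, as on a scanned
    film) the profile is inverted about its maximum so bands become peaks.
    """
    img = np.asarray(gel_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale gel image, got ndim={img.ndim}")
    start, stop = lane_columns
    if not (0 <= start < stop <= img.shape[1]):
        raise ValueError(
            f"lane columns {lane_columns} outside image with {img.shape[1]} columns"
        )
    profile = img[:, start:stop].mean(axis=1)
    if dark_bands:
        profile = profile.max() - profile
    return LaneProfile(intensity=profile, lane_columns=(int(start), int(stop)))


def integrate_band(
    profile: LaneProfile | np.ndarray,
    window: tuple[int, int],
    baseline: str = "linear-endpoints",
) -> float:
    """Integrate a band above a linear baseline over a half-open index window.

    The baseline is the straight line joining the profile values at the
    window's first and last sample; the volume is the sum of
    ``profile - baseline`` over the window, clipped below at 0 (a band cannot
    have negative mass).
    """
    values = profile.intensity if isinstance(profile, LaneProfile) else np.asarray(profile)
    values = values.astype(np.float64)
    start, stop = window
    if not (0 <= start < stop <= values.size):
        raise ValueError(f"window {window} outside profile of length {values.size}")
    if baseline != "linear-endpoints":
        raise ValueError(f"unknown baseline model {baseline!r}")
    seg = values[start:stop]
    base = np.linspace(seg[0], seg[-1], seg.size)
    return float(max((seg - base).sum(), 0.0))


def normalize_to_loading(band_volume: float, control_volume: float) -> float:
    """Ratio of a band volume to the loading-control (beta-actin) volume."""
    if band_volume < 0:
        raise ValueError("band volume must be non-negative")
    if control_volume <= 0:
        raise ValueError("loading-control volume must be strictly positive")
    return band_volume / control_volume
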