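"""Synthetic western-blot lanes with bands of known abundance.

Each band renders as a Gaussian peak on the lane's 1D migration profile with
integral proportional to its true abundance; a slow baseline drift and white
Gaussian noise are added on top.  Lanes can also be rasterised into a 2D gel
image (lanes as column blocks) for testing the profile-extraction step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BandSpec", "LaneSpec", "GelSimSpec", "GelSim", "make_gel"]

#: Band labels used in the vitronectin immunoblot layout.
KNOWN_LABELS = ("65kDa", "75kDa", "beta-actin")


@dataclass(frozen=True)
class BandSpec:
    """One band: label, migration position, true abundance and peak width."""

    label: str
    center: float  # migration-axis position, samples
    abundance: float  # true amount; peak integral is abundance * peak_scale
    width: float = 4.0  # Gaussian sigma, samples

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class LaneSpec:
    bands: tuple[BandSpec, ...]


@dataclass(frozen=True)
class GelSimSpec:
    """Parameters of one simulated gel."""

    lanes: tuple[LaneSpec, ...]
    profile_length: int = 400
    peak_scale: float = 1000.0  # intensity integral per unit abundance
    baseline_level: float = 5.0
    drift_amplitude: float = 2.0  # slow sinusoidal baseline drift
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lanes:
            raise ValueError("a gel needs at least one lane")
        for lane in self.lanes:
            bands = sorted(lane.bands, key=lambda b: b.center)
            for b in bands:
                if not 0 <= b.center < self.profile_length:
                    raise ValueError(f"band {b.label!r} centred outside the profile")
            for left, right in zip(bands, bands[1:]):
                if right.center - left.center < 4.0 * (left.width + right.width):
                    raise ValueError(
                        f"bands {left.label!r} and {right.label!r} overlap "
                        "(centres closer than 4 combined sigmas)"
                    )


@dataclass
class GelSim:
    """A realised gel: lane profiles, the truth table and band windows."""

    profiles: np.ndarray  # (n_lanes, profile_length)
    truth: pd.DataFrame  # lane, label, abundance, center, width, window_lo, window_hi
    spec: GelSimSpec

    def window(self, lane: int, label: str) -> tuple[int, int]:
        row = self.truth[(self.truth.lane == lane) & (self.truth.label == label)]
        if row.empty:
            raise KeyError(f"no band {label!r} in lane {lane}")
        return int(row.window_lo.iloc[0]), int(row.window_hi.iloc[0])

    def render_image(self, lane_width: int = 20, gap: int = 5) -> np.ndarray:
        """Rasterise the lanes into a 2D gel image (migration axis = rows)."""
        n_lanes, length = self.profiles.shape
        img = np.zeros((length, n_lanes * (lane_width + gap)))
        for i, profile in enumerate(self.profiles):
            start = i * (lane_width + gap)
            img[:, start : start + lane_width] = profile[:, None]
        return img


def make_gel(spec: GelSimSpec) -> GelSim:
    """Simulate lane profiles with truth abundances and integration windows."""
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.profile_length, dtype=np.float64)
    profiles = np.empty((len(spec.lanes), spec.profile_length))
    rows = []
    for li, lane in enumerate(spec.lanes):
        profile = np.full(spec.profile_length, spec.baseline_level, dtype=np.float64)
        profile += spec.drift_amplitude * np.sin(
            2.0 * math.pi * (x / spec.profile_length + rng.uniform())
        )
        for band in lane.bands:
            area = band.abundance * spec.peak_scale
            profile += (
                area
                / (band.width * math.sqrt(2.0 * math.pi))
                * np.exp(-0.5 * ((x - band.center) / band.width) ** 2)
            )
            lo = max(0, int(math.floor(band.center - 4.0 * band.width)))
            hi = min(spec.profile_length, int(math.ceil(band.center + 4.0 * band.width)) + 1)
            rows.append(
                {
                    "lane": li,
                    "label": band.label,
                    "abundance": band.abundance,
                    "center": band.center,
                    "width": band.width,
                    "window_lo": lo,
                    "window_hi": hi,
                }
            )
        if spec.noise_sd > 0:
            profile += rng.normal(0.0, spec.noise_sd, size=spec.profile_length)
        profiles[li] = profile
    return GelSim(profiles=profiles, truth=pd.DataFrame(rows), spec=spec)
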