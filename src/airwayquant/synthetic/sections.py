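"""Synthetic stained-section label maps with known compartment fractions.

Each compartment is carved out of a smoothed Gaussian random field by
selecting exactly the k highest-field pixels needed to realise the target
fraction, so the realized fractions are pixel-exact (within one pixel of the
target) while the compartment shapes stay organic and spatially coherent.
Compartments are nested the way an airway section is: background around a
tissue region; within tissue, submucosal gland and surface epithelium; within
each of those, a stain-positive sub-compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..io import SectionLabelMap

__all__ = ["SectionSimSpec", "make_section_labelmap"]


@dataclass(frozen=True)
class SectionSimSpec:
    """Parameters of one simulated tissue section.

    ``target_gland_fraction`` is the gland share of *tissue* pixels;
    ``target_positive_fraction_within_gland`` the stain-positive share of
    gland pixels.  ``texture_scale`` (pixels) sets the correlation length of
    the random fields, i.e. how coarse the compartment shapes are.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0  # um per pixel side
    target_gland_fraction: float = 0.39
    target_positive_fraction_within_gland: float = 0.29
    background_fraction: float = 0.12
    epithelium_fraction: float = 0.08  # share of non-gland tissue
    target_positive_fraction_within_epithelium: float = 0.0
    texture_scale: float = 0.08  # correlation length as a fraction of min(shape)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "target_gland_fraction",
            "target_positive_fraction_within_gland",
            "background_fraction",
            "epithelium_fraction",
            "target_positive_fraction_within_epithelium",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(d < 8 for d in self.shape):
            raise ValueError(f"section dimensions must be >= 8, got {self.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be strictly positive")


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def _top_k(field_values: np.ndarray, k: int) -> np.ndarray:
    """Boolean selector of the k largest entries of a 1D array (exact count)."""
    sel = np.zeros(field_values.size, dtype=bool)
    if k > 0:
        sel[np.argpartition(field_values, -k)[-k:]] = True
    return sel


def make_section_labelmap(
    spec: SectionSimSpec,
) -> tuple[SectionLabelMap, dict[str, float]]:
    """Simulate one section label map.

    Returns the map and the realized fractions, each recomputed from the
    emitted pixels: ``gland_fraction`` (of tissue), ``positive_fraction``
    (of gland), ``background_fraction``, ``epithelium_fraction`` (of
    non-gland tissue) and ``positive_epithelium_fraction`` (of epithelium).

    Raises
    ------
    ValueError
        If a nonzero target fraction rounds to zero pixels for the given
        shape (unreachable target).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    n_pixels = h * w
    sigma = max(spec.texture_scale * min(h, w), 1.0)

    labels = np.ones(n_pixels, dtype=np.uint8)  # start as plain tissue

    # background ring/patches
    n_bg = int(round(spec.background_fraction * n_pixels))
    bg_sel = _top_k(_smooth_field((h, w), 2 * sigma, rng).ravel(), n_bg)
    labels[bg_sel] = 0
    tissue_idx = np.flatnonzero(~bg_sel)
    if tissue_idx.size == 0:
        raise ValueError("background_fraction leaves no tissue pixels")

    def carve(parent_idx: np.ndarray, fraction: float, scale: float, name: str) -> np.ndarray:
        """Select round(fraction * |parent|) parent pixels via a smooth field.

        A positive fraction that rounds to zero pixels realises as 0 (still
        within half a pixel of the target); only a parent compartment with no
        pixels at all makes the target unreachable.
        """
        if fraction > 0 and parent_idx.size == 0:
            raise ValueError(
                f"unreachable target: {name}={fraction} requested but the parent "
                "compartment has no pixels"
            )
        k = int(round(fraction * parent_idx.size))
        field = _smooth_field((h, w), scale, rng).ravel()[parent_idx]
        return parent_idx[_top_k(field, k)]

    gland_idx = carve(tissue_idx, spec.target_gland_fraction, sigma, "target_gland_fraction")
    labels[gland_idx] = 2
    pos_idx = carve(
        gland_idx,
        spec.target_positive_fraction_within_gland,
        0.5 * sigma,
        "target_positive_fraction_within_gland",
    )
    labels[pos_idx] = 3

    nongland = np.setdiff1d(tissue_idx, gland_idx, assume_unique=True)
    if spec.epithelium_fraction > 0:
        epi_idx = carve(nongland, spec.epithelium_fraction, sigma, "epithelium_fraction")
        labels[epi_idx] = 4
        pos_epi = carve(
            epi_idx,
            spec.target_positive_fraction_within_epithelium,
            0.5 * sigma,
            "target_positive_fraction_within_epithelium",
        )
        labels[pos_epi] = 5

    labelmap = SectionLabelMap(labels=labels.reshape(h, w), pixel_size=spec.pixel_size)
    counts = labelmap.class_counts()
    n_tissue = n_pixels - counts[0]
    n_gland = counts[2] + counts[3]
    n_epi = counts[4] + counts[5]
    realized = {
        "background_fraction": counts[0] / n_pixels,
        "gland_fraction": n_gland / n_tissue if n_tissue else float("nan"),
        "positive_fraction": counts[3] / n_gland if n_gland else float("nan"),
        "epithelium_fraction": n_epi / (n_tissue - n_gland) if n_tissue - n_gland else 0.0,
        "positive_epithelium_fraction": counts[5] / n_epi if n_epi else 0.0,
    }
    return labelmap, realized
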