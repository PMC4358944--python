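"""Point-grid stereology and area fractions on 2D tissue sections.

Volume fractions are estimated by point counting: a systematic grid of test
points (81 by default, a 9x9 tiling) is overlaid on each section and each
point is classified by the compartment of the pixel it lands on.  Under
uniform-random grid offsets, the fraction of points hitting a compartment is
an unbiased estimator of its area fraction, and (by the Cavalieri argument)
of its volume fraction across serial sections.

Two derived fractions are reported per image:

* ``G_vf`` -- points on submucosal gland / points on any tissue (gland volume
  referenced to bronchial tissue volume);
* ``V_vf`` -- points on stain-positive gland / points on gland (volume of
  positive cells relative to total gland volume).

Pixel-exact area measurements (gland area in mm^2, percent of gland area that
is stain-positive) complement the point-count estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GLAND_CODES, POSITIVE_GLAND_CODE, SectionLabelMap, TISSUE_CODES

__all__ = [
    "PointGrid",
    "StereologyResult",
    "make_grid",
    "classify_points",
    "volume_fractions",
    "area_fraction",
    "stereology_result",
    "subject_summaries",
]


@dataclass(frozen=True)
class PointGrid:
    """Test-point coordinates in pixel space (continuous (y, x) positions)."""

    ys: np.ndarray
    xs: np.ndarray
    spacing: tuple[float, float]
    mode: str  # "centered" or "random"

    @property
    def n_points(self) -> int:
        return int(self.ys.size)


@dataclass(frozen=True)
class StereologyResult:
    """Point counts, volume fractions and pixel-exact areas for one section."""

    p_tissue: int
    p_gland: int
    p_positive: int
    g_vf: float | None
    v_vf: float | None
    gland_area_mm2: float
    percent_gland_positive: float | None

    def __post_init__(self) -> None:
        if not (self.p_positive <= self.p_gland <= self.p_tissue):
            raise ValueError(
                f"inconsistent point counts: positive {self.p_positive} <= "
                f"gland {self.p_gland} <= tissue {self.p_tissue} violated"
            )


def make_grid(
    image_shape: tuple[int, int],
    n_points: int = 81,
    offset_mode: str = "centered",
    rng: np.random.Generator | int | None = None,
) -> PointGrid:
    """Build a systematic r x r point grid over an image.

    The image is tiled into ``r x r`` cells (``r = sqrt(n_points)``); in
    ``"centered"`` mode each point sits at its cell centre, in ``"random"``
    mode one shared uniform offset within the cell is drawn per grid
    (systematic uniform-random sampling, the placement that makes point
    counting unbiased).
    """
    h, w = image_shape
    r = math.isqrt(n_points)
    if r * r != n_points:
        raise ValueError(f"n_points must be a perfect square for a systematic grid, got {n_points}")
    if r > h or r > w:
        raise ValueError(f"{r}x{r} grid does not fit an image of shape {image_shape}")
    sy, sx = h / r, w / r
    if offset_mode == "centered":
        oy, ox = 0.5 * sy, 0.5 * sx
    elif offset_mode == "random":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        oy, ox = gen.uniform(0.0, sy), gen.uniform(0.0, sx)
    else:
        raise ValueError(f"unknown offset_mode {offset_mode!r}")
    iy = oy + sy * np.arange(r)
    ix = ox + sx * np.arange(r)
    ys, xs = np.meshgrid(iy, ix, indexing="ij")
    return PointGrid(ys=ys.ravel(), xs=xs.ravel(), spacing=(sy, sx), mode=offset_mode)


def classify_points(grid: PointGrid, labelmap: SectionLabelMap) -> dict[int, int]:
    """Assign each grid point the class of the pixel containing it.

    Points live in continuous pixel coordinates; the containing pixel is the
    floor of the coordinate, so a point exactly on a pixel boundary belongs to
    the pixel below/right of it.  Counts over all classes sum to ``n_points``.
    """
    h, w = labelmap.shape
    py = np.floor(grid.ys).astype(np.intp)
    px = np.floor(grid.xs).astype(np.intp)
    if py.min() < 0 or px.min() < 0 or py.max() >= h or px.max() >= w:
        raise ValueError("grid points fall outside the label map")
    hits = labelmap.labels[py, px]
    return {code: int(np.count_nonzero(hits == code)) for code in labelmap.legend}


def volume_fractions(counts: dict[int, int]) -> tuple[float | None, float | None]:
    """(G_vf, V_vf) from per-class point counts.

    G_vf = gland points / tissue points; V_vf = positive-gland points / gland
    points.  A zero denominator yields ``None`` (flagged missing with a
    warning), never a silent 0.
    """
    p_tissue = sum(counts.get(c, 0) for c in TISSUE_CODES)
    p_gland = sum(counts.get(c, 0) for c in GLAND_CODES)
    p_pos = counts.get(POSITIVE_GLAND_CODE, 0)
    if p_tissue > 0:
        g_vf = p_gland / p_tissue
    else:
        warnings.warn("no tissue points: G_vf is missing", stacklevel=2)
        g_vf = None
    if p_gland > 0:
        v_vf = p_pos / p_gland
    else:
        warnings.warn("no gland points: V_vf is missing", stacklevel=2)
        v_vf = None
    return g_vf, v_vf


def area_fraction(labelmap: SectionLabelMap) -> tuple[float, float | None]:
    """Pixel-exact gland area (mm^2) and percent of gland area stain-positive.

    Uses the map's ``pixel_size`` (um per pixel side).  With no gland pixels
    the area is 0 and the percentage is missing (``None``).
    """
    labels = labelmap.labels
    gland_mask = np.isin(labels, list(GLAND_CODES))
    n_gland = int(gland_mask.sum())
    area_mm2 = n_gland * (labelmap.pixel_size**2) / 1e6
    if n_gland == 0:
        warnings.warn("no gland pixels: percent positive area is missing", stacklevel=2)
        return area_mm2, None
    n_pos = int(np.count_nonzero(labels == POSITIVE_GLAND_CODE))
    return area_mm2, 100.0 * n_pos / n_gland


def stereology_result(
    labelmap: SectionLabelMap,
    grid: PointGrid | None = None,
) -> StereologyResult:
    """Full point-count + area analysis of one section."""
    if grid is None:
        grid = make_grid(labelmap.shape)
    counts = classify_points(grid, labelmap)
    g_vf, v_vf = volume_fractions(counts)
    area_mm2, pct = area_fraction(labelmap)
    return StereologyResult(
        p_tissue=sum(counts.get(c, 0) for c in TISSUE_CODES),
        p_gland=sum(counts.get(c, 0) for c in GLAND_CODES),
        p_positive=counts.get(POSITIVE_GLAND_CODE, 0),
        g_vf=g_vf,
        v_vf=v_vf,
        gland_area_mm2=area_mm2,
        percent_gland_positive=pct,
    )


def subject_summaries(
    per_image: pd.DataFrame,
    measures: tuple[str, ...] = ("g_vf", "v_vf", "gland_area_mm2", "percent_gland_positive"),
) -> pd.DataFrame:
    """Median across each subject's images for every measure.

    ``per_image`` needs ``subject_id`` and ``group`` columns plus one column
    per measure; missing (NaN) per-image values are ignored in the median.
    The output (one row per subject) is order-invariant in the input rows.
    """
    required = {"subject_id", "group", *measures}
    missing = required - set(per_image.columns)
    if missing:
        raise ValueError(f"per-image table missing columns {sorted(missing)}")
    return (
        per_image.groupby(["group", "subject_id"], sort=True)[list(measures)]
        .median()
        .reset_index()
    )
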