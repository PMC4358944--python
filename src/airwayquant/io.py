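"""Image and table I/O: dual-channel confocal stacks, section label maps, result tables.

Conventions
-----------
* Arrays are indexed ``(z, y, x)`` (stacks) or ``(y, x)`` (sections), 0-based,
  origin at the top-left corner of the first optical section.
* Stacks are written as multi-page TIFF with pages interleaved per z-plane:
  ``z0/green, z0/red, z1/green, z1/red, ...``.  Channel identity and voxel
  size travel in the ImageDescription tag (JSON), not in file names.
* Label maps are single-page TIFF images of integer class codes
  (see :data:`LABEL_LEGEND`).
* Result tables are long-format CSVs with the fixed column set
  ``subject_id, group, image_id, measure, value``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DualChannelStack",
    "SectionLabelMap",
    "LABEL_LEGEND",
    "TISSUE_CODES",
    "GLAND_CODES",
    "POSITIVE_GLAND_CODE",
    "EPITHELIUM_CODES",
    "StackFormatError",
    "LabelMapFormatError",
    "read_stack",
    "write_stack",
    "read_labelmap",
    "write_labelmap",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

#: Class codes of a section label map.  Codes are mutually exclusive; the
#: "positive" codes are refinements (positive-gland pixels are gland pixels
#: that stain positive, likewise for epithelium).
LABEL_LEGEND: dict[int, str] = {
    0: "background",
    1: "tissue",
    2: "gland",
    3: "positive_gland",
    4: "epithelium",
    5: "positive_epithelium",
}

#: Codes counting as bronchial tissue (everything but background).
TISSUE_CODES = frozenset({1, 2, 3, 4, 5})
#: Codes counting as submucosal gland.
GLAND_CODES = frozenset({2, 3})
POSITIVE_GLAND_CODE = 3
#: Codes counting as surface epithelium.
EPITHELIUM_CODES = frozenset({4, 5})
POSITIVE_EPITHELIUM_CODE = 5

RESULT_COLUMNS = ["subject_id", "group", "image_id", "measure", "value"]


class StackFormatError(ValueError):
    """Raised when a stack file violates the documented two-channel 8-bit layout."""


class LabelMapFormatError(ValueError):
    """Raised when a label-map file carries class codes outside the legend."""


@dataclass
class DualChannelStack:
    """Aligned green/red 3D voxel intensity arrays from a confocal z-stack.

    Parameters
    ----------
    green, red
        3D ``(z, y, x)`` integer intensity arrays; must share a shape and fit
        the declared bit depth (8-bit by default, intensities 0-255).
    voxel_size
        Physical voxel dimensions ``(z, y, x)`` in micrometres.  The default
        z-step of 0.3 um matches a typical confocal optical-section spacing.
    """

    green: np.ndarray
    red: np.ndarray
    voxel_size: tuple[float, float, float] = (0.3, 0.116, 0.116)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise StackFormatError(
                f"channel shapes differ: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.green.ndim != 3:
            raise StackFormatError(f"expected 3D (z, y, x) arrays, got ndim={self.green.ndim}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        hi = 2**self.bit_depth - 1
        for name, ch in (("green", self.green), ("red", self.red)):
            if ch.min() < 0 or ch.max() > hi:
                raise StackFormatError(
                    f"{name} channel intensities outside [0, {hi}] for {self.bit_depth}-bit data"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape

    @property
    def n_voxels(self) -> int:
        return int(self.green.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DualChannelStack):
            return NotImplemented
        return (
            np.array_equal(self.green, other.green)
            and np.array_equal(self.red, other.red)
            and self.voxel_size == other.voxel_size
            and self.bit_depth == other.bit_depth
        )


@dataclass
class SectionLabelMap:
    """2D categorical image assigning each pixel to one tissue compartment.

    ``labels`` holds integer codes from :data:`LABEL_LEGEND`; ``pixel_size``
    is the side of a pixel in micrometres.
    """

    labels: np.ndarray
    pixel_size: float = 1.0
    legend: dict[int, str] = field(default_factory=lambda: dict(LABEL_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise LabelMapFormatError(f"expected a 2D label image, got ndim={self.labels.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be strictly positive")
        bad = set(np.unique(self.labels)) - set(self.legend)
        if bad:
            raise LabelMapFormatError(f"unknown class codes {sorted(int(b) for b in bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[int, int]:
        """Pixel count per class code (absent classes reported as 0)."""
        return {code: int(np.count_nonzero(self.labels == code)) for code in self.legend}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SectionLabelMap):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and self.pixel_size == other.pixel_size
            and self.legend == other.legend
        )


def write_stack(stack: DualChannelStack, path) -> None:
    """Write a dual-channel stack as multi-page TIFF (pages: z0/G, z0/R, z1/G, ...)."""
    meta = {
        "layout": "zc",
        "channels": ["green", "red"],
        "voxel_size_um": list(stack.voxel_size),
        "bit_depth": stack.bit_depth,
    }
    pages = np.empty((stack.shape[0] * 2,) + stack.shape[1:], dtype=np.uint8)
    pages[0::2] = stack.green
    pages[1::2] = stack.red
    tifffile.imwrite(path, pages, photometric="minisblack", description=json.dumps(meta))


def read_stack(path) -> DualChannelStack:
    """Read a dual-channel stack written by :func:`write_stack`.

    Raises
    ------
    StackFormatError
        If the file is not 8-bit, does not carry two channels, or lacks the
        channel-layout metadata.
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    if pages.dtype != np.uint8:
        raise StackFormatError(f"expected 8-bit intensities, file is {pages.dtype}")
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        raise StackFormatError("missing channel-layout metadata in ImageDescription")
    if "channels" not in meta or "voxel_size_um" not in meta:
        raise StackFormatError("missing channel-layout metadata in ImageDescription")
    channels = meta.get("channels")
    if channels != ["green", "red"]:
        raise StackFormatError(f"expected two channels ['green', 'red'], got {channels}")
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 2 != 0:
        raise StackFormatError(
            f"expected two channels: odd page count {pages.shape[0]} cannot interleave green/red"
        )
    voxel_size = tuple(float(v) for v in meta["voxel_size_um"])
    return DualChannelStack(
        green=pages[0::2].copy(),
        red=pages[1::2].copy(),
        voxel_size=voxel_size,
        bit_depth=int(meta.get("bit_depth", 8)),
    )


def write_labelmap(labelmap: SectionLabelMap, path) -> None:
    """Write a section label map as a single-page uint8 TIFF with a JSON legend tag."""
    meta = {
        "kind": "section_labelmap",
        "pixel_size_um": labelmap.pixel_size,
        "legend": {str(k): v for k, v in labelmap.legend.items()},
    }
    tifffile.imwrite(
        path,
        labelmap.labels.astype(np.uint8),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_labelmap(path) -> SectionLabelMap:
    """Read a label map, validating every pixel code against the legend."""
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        legend = {int(k): v for k, v in meta["legend"].items()}
        pixel_size = float(meta["pixel_size_um"])
    except (TypeError, KeyError, json.JSONDecodeError):
        legend = dict(LABEL_LEGEND)
        pixel_size = 1.0
    bad = set(np.unique(labels)) - set(legend)
    if bad:
        raise LabelMapFormatError(
            f"label map contains unknown class codes {sorted(int(b) for b in bad)}"
        )
    return SectionLabelMap(labels=labels, pixel_size=pixel_size, legend=legend)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a long-format results table with the stable documented columns.

    An empty table produces a header-only CSV.  Extra columns are rejected so
    downstream readers can rely on the schema.
    """
    if table.empty and not list(table.columns):
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing required columns {missing}")
    table.loc[:, RESULT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
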