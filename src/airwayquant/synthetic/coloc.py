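"""Synthetic dual-channel confocal stacks with a known colocalized fraction.

The green channel carries ellipsoidal "cell" objects with lognormal size; a
chosen fraction of the green-object voxels (selected blob-by-blob so the
colocalized region is spatially coherent) also carries red signal.  Both
channels are then blurred with a Gaussian point-spread approximation,
degraded with Poisson shot noise plus additive Gaussian read noise, and
quantized to 8-bit (0-255), emulating photomultiplier-tube acquisition
without modelling the hardware.

Colocalization is defined at the voxel level *before* blur; the realized
(post-voxel-selection) fraction returned alongside the stack is the reference
truth for recovery tests.  Blur then induces the partial-overlap softening
seen in real stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..io import DualChannelStack

__all__ = ["ColocSimSpec", "BlobPlacementError", "make_coloc_stack"]


class BlobPlacementError(RuntimeError):
    """Raised when blobs cannot be placed inside the volume (overcrowded spec)."""


@dataclass(frozen=True)
class ColocSimSpec:
    """Parameters of one simulated dual-channel stack.

    ``true_coloc_fraction`` is the target fraction of green-object voxels
    that also carry red signal (pre-blur).  Intensities are in arbitrary
    units pre-quantization; after blur and noise both channels are clipped
    and rounded to 8-bit.
    """

    shape: tuple[int, int, int] = (16, 64, 64)
    n_blobs: int = 10
    true_coloc_fraction: float = 0.5
    mean_signal: float = 180.0
    mean_background: float = 8.0
    psf_sigma: float = 0.7  # isotropic Gaussian blur scale, voxels
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    blob_radius_mean: float = 4.0  # lognormal median semi-axis, voxels
    blob_radius_sigma: float = 0.25  # lognormal sigma of semi-axes
    voxel_size: tuple[float, float, float] = (0.3, 0.116, 0.116)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_coloc_fraction <= 1.0:
            raise ValueError("true_coloc_fraction must lie in [0, 1]")
        if any(d < 8 for d in self.shape):
            raise ValueError(f"all stack dimensions must be >= 8, got {self.shape}")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        if self.mean_signal <= self.mean_background:
            raise ValueError("mean_signal must exceed mean_background")
        if self.psf_sigma < 0 or self.read_noise_sd < 0:
            raise ValueError("psf_sigma and read_noise_sd must be non-negative")


def _place_blobs(spec: ColocSimSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Place ellipsoids fully inside the volume; each returned as a voxel-index array."""
    shape = np.array(spec.shape)
    blobs = []
    for _ in range(spec.n_blobs):
        for _attempt in range(200):
            semi = rng.lognormal(np.log(spec.blob_radius_mean), spec.blob_radius_sigma, size=3)
            semi = np.maximum(semi, 1.0)
            lo = np.ceil(semi)
            hi = shape - 1 - np.ceil(semi)
            if np.any(hi < lo):
                continue  # blob too large for the volume; redraw
            center = rng.uniform(lo, hi)
            span_lo = np.floor(center - semi).astype(int)
            span_hi = np.ceil(center + semi).astype(int) + 1
            zz, yy, xx = np.meshgrid(
                np.arange(span_lo[0], span_hi[0]),
                np.arange(span_lo[1], span_hi[1]),
                np.arange(span_lo[2], span_hi[2]),
                indexing="ij",
            )
            d2 = (
                ((zz - center[0]) / semi[0]) ** 2
                + ((yy - center[1]) / semi[1]) ** 2
                + ((xx - center[2]) / semi[2]) ** 2
            )
            inside = d2 <= 1.0
            if inside.any():
                blobs.append(
                    np.stack([zz[inside], yy[inside], xx[inside]], axis=1)
                )
                break
        else:
            raise BlobPlacementError(
                f"could not place blob of median radius {spec.blob_radius_mean} "
                f"inside volume {spec.shape} after 200 attempts"
            )
    return blobs


def _select_colocalized(
    green_mask: np.ndarray,
    blobs: list[np.ndarray],
    fraction: float,
) -> np.ndarray:
    """Mark a coherent subset of green voxels as red-carrying, hitting the target count."""
    red_mask = np.zeros_like(green_mask)
    n_green = int(green_mask.sum())
    target = int(round(fraction * n_green))
    if target <= 0:
        return red_mask
    taken = np.zeros_like(green_mask)
    remaining = target
    for vox in blobs:
        idx = tuple(vox.T)
        new = ~taken[idx]
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if n_new <= remaining:
            red_mask[idx] = True
            taken[idx] = True
            remaining -= n_new
        else:
            # partial blob: take a coherent sub-slab of its new voxels (lowest x first)
            new_vox = vox[new]
            order = np.lexsort((new_vox[:, 1], new_vox[:, 0], new_vox[:, 2]))
            chosen = new_vox[order[:remaining]]
            red_mask[tuple(chosen.T)] = True
            taken[tuple(chosen.T)] = True
            remaining = 0
        if remaining == 0:
            break
    return red_mask


def _render_channel(
    mask: np.ndarray,
    spec: ColocSimSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.where(mask, spec.mean_signal, spec.mean_background).astype(np.float64)
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma)
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_coloc_stack(
    spec: ColocSimSpec,
) -> tuple[DualChannelStack, dict[str, np.ndarray], float]:
    """Simulate a dual-channel stack.

    Returns
    -------
    stack
        The 8-bit quantized :class:`~airwayquant.io.DualChannelStack`.
    masks
        ``{"green": ..., "red": ...}`` boolean ground-truth object masks
        (pre-blur, pre-noise).
    realized_fraction
        Fraction of green-object voxels that carry red signal after the
        discrete voxel selection -- the truth value recovery tests compare
        against.  0.0 when the green mask is empty.
    """
    rng = np.random.default_rng(spec.seed)
    blobs = _place_blobs(spec, rng)
    green_mask = np.zeros(spec.shape, dtype=bool)
    for vox in blobs:
        green_mask[tuple(vox.T)] = True
    red_mask = _select_colocalized(green_mask, blobs, spec.true_coloc_fraction)
    n_green = int(green_mask.sum())
    realized = float(red_mask.sum() / n_green) if n_green else 0.0
    stack = DualChannelStack(
        green=_render_channel(green_mask, spec, rng),
        red=_render_channel(red_mask, spec, rng),
        voxel_size=spec.voxel_size,
    )
    return stack, {"green": green_mask, "red": red_mask}, realized
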