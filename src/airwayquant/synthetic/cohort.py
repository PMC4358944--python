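"""Synthetic study cohorts: subjects, groups and per-image section label maps.

The default design mirrors a three-group airway study: 14 healthy controls,
7 asthmatic and 10 COPD subjects, an average of five stained-section images
per subject, no group difference in gland volume fraction, and a strong group
effect on the vitronectin-positive volume fraction (control location 0.29 vs
0.07 / 0.04 in the disease groups).  Per-subject true positive fractions are
drawn from group-specific beta distributions parameterised by mean and
concentration; each of a subject's images is generated with that subject's
true fraction as its target, so between-image variation comes from the
section-shape randomness and the point-grid sampling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..io import SectionLabelMap
from .sections import SectionSimSpec, make_section_labelmap

__all__ = ["GroupSpec", "CohortSimSpec", "Cohort", "make_cohort"]


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: size and the distribution of its true fraction."""

    name: str
    n_subjects: int
    fraction_mean: float  # beta-distribution mean of the true positive fraction
    fraction_concentration: float = 30.0  # beta a+b; larger = tighter group

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"group {self.name!r} must have at least one subject")
        if not 0.0 < self.fraction_mean < 1.0:
            raise ValueError("fraction_mean must lie strictly inside (0, 1)")
        if self.fraction_concentration <= 0:
            raise ValueError("fraction_concentration must be positive")


def default_groups() -> list[GroupSpec]:
    return [
        GroupSpec("HC", 14, 0.29),
        GroupSpec("asthma", 7, 0.07),
        GroupSpec("COPD", 10, 0.04),
    ]


@dataclass(frozen=True)
class CohortSimSpec:
    """Design of a simulated cohort."""

    groups: tuple[GroupSpec, ...] = field(default_factory=lambda: tuple(default_groups()))
    images_per_subject_mean: float = 5.0  # 1 + Poisson(mean - 1) images per subject
    gland_fraction: float = 0.39
    gland_fraction_concentration: float = 50.0  # between-image beta spread of gland share
    within_subject_concentration: float = 200.0  # image-to-image spread around subject truth
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 2.0  # um per pixel side
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a cohort needs at least two groups")
        if self.images_per_subject_mean < 1:
            raise ValueError("images_per_subject_mean must be >= 1")
        if not 0.0 < self.gland_fraction < 1.0:
            raise ValueError("gland_fraction must lie in (0, 1)")
        if self.gland_fraction_concentration <= 0 or self.within_subject_concentration <= 0:
            raise ValueError("concentration parameters must be positive")


@dataclass
class Cohort:
    """A realised cohort: the truth table and every subject's label maps."""

    truth: pd.DataFrame  # subject_id, group, true_fraction, n_images
    images: dict[str, list[SectionLabelMap]]  # subject_id -> per-image maps
    realized: pd.DataFrame  # subject_id, image_id, realized positive fraction


def make_cohort(spec: CohortSimSpec) -> Cohort:
    """Draw a cohort and generate each subject's section label maps.

    Per group, subject true fractions follow ``Beta(mean * c, (1 - mean) * c)``
    with concentration ``c``; image counts are ``1 + Poisson(mean - 1)``.  Each
    image's gland share and positive fraction are themselves beta draws around
    the cohort gland fraction and the subject's true fraction, so gland area
    and stain load vary from section to section as they do across real
    microscopic fields.  Every image's realized positive fraction
    (pixel-exact, recomputed from the emitted map) is recorded for
    parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)

    def beta_around(mean: float, concentration: float) -> float:
        return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))
    truth_rows, realized_rows = [], []
    images: dict[str, list[SectionLabelMap]] = {}
    for group in spec.groups:
        a = group.fraction_mean * group.fraction_concentration
        b = (1.0 - group.fraction_mean) * group.fraction_concentration
        for s in range(group.n_subjects):
            subject_id = f"{group.name}_{s + 1:02d}"
            true_fraction = float(rng.beta(a, b))
            n_images = 1 + int(rng.poisson(spec.images_per_subject_mean - 1.0))
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group.name,
                    "true_fraction": true_fraction,
                    "n_images": n_images,
                }
            )
            maps = []
            for i in range(n_images):
                section = SectionSimSpec(
                    shape=spec.image_shape,
                    pixel_size=spec.pixel_size,
                    target_gland_fraction=beta_around(
                        spec.gland_fraction, spec.gland_fraction_concentration
                    ),
                    target_positive_fraction_within_gland=beta_around(
                        true_fraction, spec.within_subject_concentration
                    ),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                labelmap, realized = make_section_labelmap(section)
                maps.append(labelmap)
                realized_rows.append(
                    {
                        "subject_id": subject_id,
                        "image_id": f"{subject_id}_img{i + 1:02d}",
                        "realized_positive_fraction": realized["positive_fraction"],
                    }
                )
            images[subject_id] = maps
    return Cohort(
        truth=pd.DataFrame(truth_rows),
        images=images,
        realized=pd.DataFrame(realized_rows),
    )
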