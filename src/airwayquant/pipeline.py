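"""Study orchestration: generate -> quantify -> summarise -> test -> report.

A :class:`StudyConfig` (YAML-loadable) fully determines a synthetic study;
together with its seed it determines every output file byte-for-byte.  Three
study drivers mirror the experimental arms of an airway vitronectin study:

* :func:`run_coloc_study` -- dual-channel confocal stacks per subject,
  background thresholds, Pearson/Manders coefficients, subject medians and
  Kruskal-Wallis + Dunn group comparisons;
* :func:`run_stereology_study` -- stained sections per subject, 81-point-grid
  volume fractions and pixel areas, subject medians, group summary
  (median/IQR per group) and the same test layer;
* :func:`run_densitometry_study` -- western-blot lanes, band volumes
  normalised to beta-actin, two-group t-tests per isoform.

Quantification stages never see diagnosis labels (the analyst-blinding
analogue): group labels join the data only at the statistics step.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_stats import dunn_posthoc, kruskal_wallis, summarize, two_group_t
from .colocalization import coloc_result, compare_groups_coloc
from .densitometry import integrate_band, normalize_to_loading
from .quantify import background_threshold
from .stereology import make_grid, stereology_result, subject_summaries
from .synthetic import (
    BandSpec,
    ColocSimSpec,
    CohortSimSpec,
    GelSimSpec,
    GroupSpec,
    LaneSpec,
    make_cohort,
    make_coloc_stack,
    make_gel,
)

__all__ = [
    "ColocStudyConfig",
    "DensitometryStudyConfig",
    "StudyConfig",
    "run_coloc_study",
    "run_stereology_study",
    "run_densitometry_study",
    "run_all",
    "vvf_study_pvalue",
]

_CSV_FMT = "%.10g"


@dataclass(frozen=True)
class ColocStudyConfig:
    """Design of the colocalization arm: per-group true colocalized fractions."""

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("HC", 7, 0.75),
        GroupSpec("asthma", 6, 0.55),
        GroupSpec("COPD", 4, 0.55),
    )
    images_per_subject_mean: float = 5.0
    stack_shape: tuple[int, int, int] = (12, 48, 48)
    n_blobs: int = 8
    psf_sigma: float = 0.7
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("colocalization study needs at least two groups")
        if self.images_per_subject_mean < 1:
            raise ValueError("images_per_subject_mean must be >= 1")


@dataclass(frozen=True)
class DensitometryStudyConfig:
    """Design of the immunoblot arm: lane counts and true isoform abundances."""

    n_control: int = 3
    n_diseased: int = 9
    control_abundance: dict[str, float] = field(
        default_factory=lambda: {"65kDa": 1.0, "75kDa": 1.0}
    )
    diseased_abundance: dict[str, float] = field(
        default_factory=lambda: {"65kDa": 0.45, "75kDa": 0.85}
    )
    abundance_cv: float = 0.15  # lognormal between-subject spread
    actin_abundance: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_diseased < 2:
            raise ValueError("each immunoblot group needs at least two lanes")


@dataclass(frozen=True)
class StudyConfig:
    """Everything a full synthetic study run needs."""

    seed: int = 0
    outdir: str = "results/study"
    analyses: tuple[str, ...] = ("coloc", "stereology", "densitometry")
    coloc: ColocStudyConfig = field(default_factory=ColocStudyConfig)
    stereology: CohortSimSpec = field(default_factory=CohortSimSpec)
    densitometry: DensitometryStudyConfig = field(default_factory=DensitometryStudyConfig)

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - {"coloc", "stereology", "densitometry"}
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}")

    # -- YAML round trip ---------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "coloc" in data:
            c = dict(data["coloc"])
            if "groups" in c:
                c["groups"] = tuple(GroupSpec(**g) for g in c["groups"])
            if "stack_shape" in c:
                c["stack_shape"] = tuple(c["stack_shape"])
            data["coloc"] = ColocStudyConfig(**c)
        if "stereology" in data:
            s = dict(data["stereology"])
            if "groups" in s:
                s["groups"] = tuple(GroupSpec(**g) for g in s["groups"])
            if "image_shape" in s:
                s["image_shape"] = tuple(s["image_shape"])
            data["stereology"] = CohortSimSpec(**s)
        if "densitometry" in data:
            data["densitometry"] = DensitometryStudyConfig(**data["densitometry"])
        if "analyses" in data:
            data["analyses"] = tuple(data["analyses"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(clean(asdict(self)), fh, sort_keys=False)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FMT)


def _test_layer(
    subject_table: pd.DataFrame, measures: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis + Dunn on subject-level values, one row per measure."""
    omnibus_rows, dunn_frames = [], []
    labels = sorted(subject_table["group"].unique())
    for measure in measures:
        groups = [
            subject_table.loc[subject_table["group"] == g, measure].dropna().to_numpy()
            for g in labels
        ]
        res = kruskal_wallis(groups)
        omnibus_rows.append(
            {"measure": measure, "test": res.name, "statistic": res.statistic,
             "df": res.df, "pvalue": res.pvalue}
        )
        pair = dunn_posthoc(groups, labels=labels)
        pair.insert(0, "measure", measure)
        dunn_frames.append(pair)
    return pd.DataFrame(omnibus_rows), pd.concat(dunn_frames, ignore_index=True)


def _group_summary(subject_table: pd.DataFrame, measures: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for group, sub in subject_table.groupby("group", sort=True):
        for measure in measures:
            values = sub[measure].dropna().to_numpy()
            med, (q1, q3) = summarize(values)
            rows.append(
                {"group": group, "measure": measure, "n_subjects": len(sub),
                 "median": med, "q1": q1, "q3": q3}
            )
    return pd.DataFrame(rows)


def run_coloc_study(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyse the colocalization arm; write tables under ``outdir``."""
    out = Path(outdir if outdir is not None else config.outdir) / "coloc"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    cc = config.coloc
    rows = []
    for group in cc.groups:
        a = group.fraction_mean * group.fraction_concentration
        b = (1.0 - group.fraction_mean) * group.fraction_concentration
        for s in range(group.n_subjects):
            subject_id = f"{group.name}_{s + 1:02d}"
            f_true = float(rng.beta(a, b))
            n_images = 1 + int(rng.poisson(cc.images_per_subject_mean - 1.0))
            for i in range(n_images):
                spec = ColocSimSpec(
                    shape=cc.stack_shape,
                    n_blobs=cc.n_blobs,
                    true_coloc_fraction=f_true,
                    psf_sigma=cc.psf_sigma,
                    read_noise_sd=cc.read_noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                stack, _, realized = make_coloc_stack(spec)
                thr_g = background_threshold(stack.green, channel_id="green")
                thr_r = background_threshold(stack.red, channel_id="red")
                res = coloc_result(stack, thr_g.threshold, thr_r.threshold)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group.name,
                        "image_id": f"{subject_id}_img{i + 1:02d}",
                        "true_fraction": f_true,
                        "realized_fraction": realized,
                        "r_p": res.r_p,
                        "m_green": res.m_green,
                        "m_red": res.m_red,
                        "threshold_green": thr_g.threshold,
                        "threshold_red": thr_r.threshold,
                    }
                )
    per_image = pd.DataFrame(rows)
    subject, group_summary = compare_groups_coloc(per_image)
    omnibus, dunn = _test_layer(subject, ("r_p", "m_green", "m_red"))
    _write(per_image, out / "per_image_coloc.csv")
    _write(subject, out / "subject_medians.csv")
    _write(group_summary, out / "group_summary.csv")
    _write(omnibus, out / "tests.csv")
    _write(dunn, out / "dunn_posthoc.csv")
    config.to_yaml(out / "resolved_config.yaml")
    return {
        "per_image": per_image,
        "subject": subject,
        "group_summary": group_summary,
        "tests": omnibus,
        "dunn": dunn,
        "outdir": out,
    }


def run_stereology_study(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyse the stereology arm; write tables under ``outdir``."""
    out = Path(outdir if outdir is not None else config.outdir) / "stereology"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    cohort = make_cohort(
        CohortSimSpec(
            groups=config.stereology.groups,
            images_per_subject_mean=config.stereology.images_per_subject_mean,
            gland_fraction=config.stereology.gland_fraction,
            image_shape=config.stereology.image_shape,
            pixel_size=config.stereology.pixel_size,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    group_of = dict(zip(cohort.truth["subject_id"], cohort.truth["group"]))
    rows = []
    for subject_id, maps in cohort.images.items():
        for i, labelmap in enumerate(maps):
            grid = make_grid(labelmap.shape, offset_mode="random", rng=rng)
            res = stereology_result(labelmap, grid)
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group_of[subject_id],
                    "image_id": f"{subject_id}_img{i + 1:02d}",
                    "g_vf": res.g_vf,
                    "v_vf": res.v_vf,
                    "gland_area_mm2": res.gland_area_mm2,
                    "percent_gland_positive": res.percent_gland_positive,
                }
            )
    per_image = pd.DataFrame(rows)
    measures = ("g_vf", "v_vf", "gland_area_mm2", "percent_gland_positive")
    subject = subject_summaries(per_image, measures)
    group_summary = _group_summary(subject, measures)
    omnibus, dunn = _test_layer(subject, measures)
    _write(per_image, out / "per_image_stereology.csv")
    _write(subject, out / "subject_medians.csv")
    _write(group_summary, out / "group_summary.csv")
    _write(omnibus, out / "tests.csv")
    _write(dunn, out / "dunn_posthoc.csv")
    _write(cohort.truth, out / "cohort_truth.csv")
    config.to_yaml(out / "resolved_config.yaml")
    return {
        "per_image": per_image,
        "subject": subject,
        "group_summary": group_summary,
        "tests": omnibus,
        "dunn": dunn,
        "truth": cohort.truth,
        "outdir": out,
    }


def run_densitometry_study(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyse the immunoblot arm; write tables under ``outdir``."""
    out = Path(outdir if outdir is not None else config.outdir) / "densitometry"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)
    dc = config.densitometry
    lanes, meta = [], []
    for status, n, abundances in (
        ("control", dc.n_control, dc.control_abundance),
        ("diseased", dc.n_diseased, dc.diseased_abundance),
    ):
        for s in range(n):
            bands = [
                BandSpec("75kDa", center=90.0, abundance=_ln(rng, abundances["75kDa"], dc.abundance_cv)),
                BandSpec("65kDa", center=180.0, abundance=_ln(rng, abundances["65kDa"], dc.abundance_cv)),
                BandSpec("beta-actin", center=300.0, abundance=dc.actin_abundance),
            ]
            lanes.append(LaneSpec(bands=tuple(bands)))
            meta.append({"status": status, "subject_id": f"{status}_{s + 1:02d}"})
    gel = make_gel(
        GelSimSpec(lanes=tuple(lanes), noise_sd=dc.noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
    )
    rows = []
    for li, info in enumerate(meta):
        actin = integrate_band(gel.profiles[li], gel.window(li, "beta-actin"))
        for label in ("65kDa", "75kDa"):
            volume = integrate_band(gel.profiles[li], gel.window(li, label))
            truth_row = gel.truth[(gel.truth.lane == li) & (gel.truth.label == label)]
            rows.append(
                {
                    **info,
                    "band": label,
                    "volume": volume,
                    "actin_volume": actin,
                    "ratio": normalize_to_loading(volume, actin),
                    "true_abundance": float(truth_row.abundance.iloc[0]),
                }
            )
    per_lane = pd.DataFrame(rows)
    test_rows = []
    for label in ("65kDa", "75kDa"):
        band = per_lane[per_lane.band == label]
        res = two_group_t(
            band.loc[band.status == "control", "ratio"],
            band.loc[band.status == "diseased", "ratio"],
        )
        test_rows.append(
            {"band": label, "test": res.name, "statistic": res.statistic,
             "df": res.df, "pvalue": res.pvalue}
        )
    tests = pd.DataFrame(test_rows)
    _write(per_lane, out / "per_lane_ratios.csv")
    _write(tests, out / "tests.csv")
    config.to_yaml(out / "resolved_config.yaml")
    return {"per_lane": per_lane, "tests": tests, "outdir": out}


def vvf_study_pvalue(spec: CohortSimSpec, seed: int) -> float:
    """One end-to-end replicate: cohort -> grids -> subject medians -> omnibus p.

    Simulates a cohort from ``spec``, estimates each image's positive volume
    fraction with a random-offset point grid, reduces to subject medians and
    returns the Kruskal-Wallis p-value for the group comparison of V_vf.
    Used for power and type-I-error studies of the whole chain.
    """
    rng = np.random.default_rng(seed)
    cohort = make_cohort(
        CohortSimSpec(
            groups=spec.groups,
            images_per_subject_mean=spec.images_per_subject_mean,
            gland_fraction=spec.gland_fraction,
            image_shape=spec.image_shape,
            pixel_size=spec.pixel_size,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    group_of = dict(zip(cohort.truth["subject_id"], cohort.truth["group"]))
    rows = []
    for subject_id, maps in cohort.images.items():
        for labelmap in maps:
            grid = make_grid(labelmap.shape, offset_mode="random", rng=rng)
            res = stereology_result(labelmap, grid)
            rows.append(
                {"subject_id": subject_id, "group": group_of[subject_id], "v_vf": res.v_vf}
            )
    per_image = pd.DataFrame(rows)
    subject = per_image.groupby(["group", "subject_id"], sort=True)["v_vf"].median().reset_index()
    groups = [
        subject.loc[subject["group"] == g, "v_vf"].dropna().to_numpy()
        for g in sorted(subject["group"].unique())
    ]
    return kruskal_wallis(groups).pvalue


def _ln(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw with the given mean and coefficient of variation."""
    if cv <= 0:
        return mean
    sigma2 = np.log(1.0 + cv**2)
    return float(rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)))


def run_all(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Run every analysis selected in ``config.analyses``."""
    results = {}
    if "coloc" in config.analyses:
        results["coloc"] = run_coloc_study(config, outdir)
    if "stereology" in config.analyses:
        results["stereology"] = run_stereology_study(config, outdir)
    if "densitometry" in config.analyses:
        results["densitometry"] = run_densitometry_study(config, outdir)
    return results
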