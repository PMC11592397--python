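"""Synthetic PET phantoms and survival cohorts with known ground truth.

Phantoms are spherical hot lesions on a flat background: uptake is the peak
value times a radial profile times a multiplicative Gaussian-random-field
texture, rescaled so the lesion maximum equals the requested peak exactly in
the noise-free case.  Cohorts draw per-subject lesion parameters, then draw
right-censored exponential survival times from a proportional-hazards model
with user-planted log-hazard coefficients on those parameters, so every
downstream stage can be validated against a known signal.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .core import Volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "CovariateDef",
    "SyntheticSubject",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "default_clinical_schema",
    "DEFAULT_PARAM_RANGES",
]

log = logging.getLogger(__name__)


@dataclass
class PhantomSpec:
    """Parameters of a single spherical-lesion PET phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 24)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    lesion_center_mm: tuple[float, float, float] | None = None
    lesion_radius_mm: float = 15.0
    suv_max: float = 10.0
    background_suv: float = 0.5
    texture_scale_mm: float = 6.0
    heterogeneity_sd: float = 0.2
    noise_sd: float = 0.0
    radial_falloff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.lesion_center_mm is None:
            self.lesion_center_mm = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)
            )
        self.lesion_center_mm = tuple(float(c) for c in self.lesion_center_mm)
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid_shape and spacing_mm must be positive")
        if self.lesion_radius_mm <= 0 or self.texture_scale_mm <= 0:
            raise ValueError("lesion_radius_mm and texture_scale_mm must be positive")
        if not (self.suv_max > self.background_suv >= 0):
            raise ValueError(
                f"need suv_max > background_suv >= 0, got {self.suv_max}, {self.background_suv}"
            )
        if not (0 <= self.heterogeneity_sd < 1):
            raise ValueError(f"heterogeneity_sd must be in [0, 1), got {self.heterogeneity_sd}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.radial_falloff < 1):
            raise ValueError(f"radial_falloff must be in [0, 1), got {self.radial_falloff}")
        for axis in range(3):
            lo = self.lesion_center_mm[axis] - self.lesion_radius_mm
            hi = self.lesion_center_mm[axis] + self.lesion_radius_mm
            extent = (self.grid_shape[axis] - 1) * self.spacing_mm[axis]
            if lo < 0 or hi > extent:
                raise ValueError(
                    f"lesion sphere leaves the grid on axis {axis}: "
                    f"[{lo:.1f}, {hi:.1f}] mm vs extent [0, {extent:.1f}] mm"
                )


def _texture_field(shape, spacing_mm, scale_mm, sd, rng) -> np.ndarray:
    """Multiplicative Gaussian-random-field texture, mean 1, clipped at 1 +/- 3*sd."""
    if sd == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    sigma_vox = [scale_mm / s for s in spacing_mm]
    smooth = ndi.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return np.clip(1.0 + sd * smooth, 1.0 - 3.0 * sd, 1.0 + 3.0 * sd)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, np.ndarray]:
    """Generate one phantom volume and its exact spherical lesion mask.

    The lesion interior is ``suv_max * profile(r) * texture``, rescaled so its
    maximum is exactly ``suv_max`` before additive noise; ``profile(r) =
    1 - radial_falloff * (r / R)^2``.  Identical specs (same seed) produce
    bitwise-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    axes = [
        spec.spacing_mm[a] * np.arange(spec.grid_shape[a]) - spec.lesion_center_mm[a]
        for a in range(3)
    ]
    dist = np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )
    mask = dist <= spec.lesion_radius_mm
    if not mask.any():
        raise ValueError("lesion sphere contains no voxel centers")

    profile = 1.0 - spec.radial_falloff * (dist / spec.lesion_radius_mm) ** 2
    texture = _texture_field(
        spec.grid_shape, spec.spacing_mm, spec.texture_scale_mm, spec.heterogeneity_sd, rng
    )
    lesion = profile * texture
    peak = lesion[mask].max()
    values = np.full(spec.grid_shape, float(spec.background_suv))
    values[mask] = spec.suv_max * lesion[mask] / peak
    if spec.noise_sd > 0:
        values = values + spec.noise_sd * rng.standard_normal(spec.grid_shape)
        values = np.clip(values, 0.0, None)
    return Volume(values, spec.spacing_mm), mask


@dataclass
class CovariateDef:
    """One clinical covariate: categorical with level probabilities, or continuous."""

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()
    mean: float = 0.0
    sd: float = 1.0
    lo: float = -math.inf
    hi: float = math.inf

    def sample(self, n: int, rng: np.random.Generator):
        if self.kind == "categorical":
            p = np.asarray(self.probs, dtype=float)
            p = p / p.sum()
            return rng.choice(self.levels, size=n, p=p)
        vals = rng.normal(self.mean, self.sd, size=n)
        return np.clip(vals, self.lo, self.hi)


def default_clinical_schema() -> list[CovariateDef]:
    """Covariate definitions mirroring the cohort's published marginal frequencies."""
    return [
        CovariateDef("gender", "categorical", ("Female", "Male"), (59, 40)),
        CovariateDef("age", "continuous", mean=66.0, sd=11.0, lo=30, hi=88),
        CovariateDef("smoking_history", "categorical", ("Ever", "Never"), (76, 23)),
        CovariateDef("m_stage", "categorical", ("M1a", "M1b", "M1c"), (22, 13, 64)),
        CovariateDef(
            "treatment",
            "categorical",
            ("Chemotherapy", "Targeted", "Immunotherapy", "Chemo-Immuno"),
            (56, 30, 9, 4),
        ),
        CovariateDef(
            "histology",
            "categorical",
            ("Adenocarcinoma", "Squamous", "LargeCell", "NOS"),
            (79, 15, 3, 2),
        ),
        CovariateDef("bmi", "continuous", mean=26.0, sd=5.0, lo=14, hi=50),
        CovariateDef("platelet_count", "continuous", mean=280.0, sd=90.0, lo=50, hi=800),
        CovariateDef("neutrophil_count", "continuous", mean=5.5, sd=2.5, lo=0.5, hi=25),
        CovariateDef("copd", "categorical", ("No", "Yes"), (70, 29)),
        CovariateDef("cad", "categorical", ("No", "Yes"), (75, 24)),
    ]


# Per-subject lesion parameter ranges (uniform draws); keys are the names
# planted Cox coefficients may refer to.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "heterogeneity_sd": (0.05, 0.45),
    "texture_scale_mm": (3.0, 9.0),
    "suv_max": (4.0, 16.0),
    "lesion_radius_mm": (9.0, 15.0),
}


@dataclass
class CohortSpec:
    """Ground-truth generative model for a synthetic survival cohort."""

    n_subjects: int = 99
    event_rate_1yr: float = 0.55
    censoring_rate: float = 0.2
    beta_true: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float | None = None  # per day; derived from event_rate_1yr if None
    clinical_schema: list[CovariateDef] = field(default_factory=default_clinical_schema)
    param_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if not (0 < self.event_rate_1yr < 1):
            raise ValueError("event_rate_1yr must be in (0, 1)")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        unknown = set(self.beta_true) - set(self.param_ranges)
        if unknown:
            raise ValueError(f"beta_true refers to unknown parameters: {sorted(unknown)}")
        if self.beta_true and all(b == 0 for b in self.beta_true.values()):
            log.warning("all planted coefficients are zero: null cohort")

    def hazard_rate(self) -> float:
        if self.baseline_hazard is not None:
            return float(self.baseline_hazard)
        return -math.log(1.0 - self.event_rate_1yr) / 365.0


@dataclass
class SyntheticSubject:
    subject_id: str
    volume: Volume | None
    true_mask: np.ndarray | None
    clinical: dict
    lesion_params: dict
    survival_time_days: float
    event: int
    one_year_dead: int


def _standardize(value: float, lo: float, hi: float) -> float:
    # z-score under the uniform(lo, hi) sampling distribution
    mean = (lo + hi) / 2.0
    sd = (hi - lo) / math.sqrt(12.0)
    return (value - mean) / sd


def generate_cohort(
    cspec: CohortSpec,
    pspec_template: PhantomSpec | None = None,
    make_volumes: bool = True,
) -> list[SyntheticSubject]:
    """Draw a full synthetic cohort: lesions, clinical table and survival times.

    Subject hazard is ``h0 * exp(sum_k beta_true[k] * z_k)`` with ``z_k`` the
    standardized lesion parameter; survival times are exponential, censoring is
    an independent exponential clock tuned so roughly ``censoring_rate`` of
    subjects are censored under the null.
    """
    if pspec_template is None:
        pspec_template = PhantomSpec()
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_subjects

    params = {
        name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in cspec.param_ranges.items()
    }
    clin_cols = {c.name: c.sample(n, rng) for c in cspec.clinical_schema}

    h0 = cspec.hazard_rate()
    linpred = np.zeros(n)
    for name, beta in cspec.beta_true.items():
        lo, hi = cspec.param_ranges[name]
        linpred += beta * np.array([_standardize(v, lo, hi) for v in params[name]])
    hazard = h0 * np.exp(linpred)
    t_event = rng.exponential(1.0 / hazard)
    if cspec.censoring_rate > 0:
        lam_c = h0 * cspec.censoring_rate / (1.0 - cspec.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    observed = np.maximum(observed, 1.0)  # day resolution floor

    subjects: list[SyntheticSubject] = []
    for i in range(n):
        vol = true_mask = None
        lesion = {name: float(params[name][i]) for name in params}
        if make_volumes:
            pspec = PhantomSpec(
                grid_shape=pspec_template.grid_shape,
                spacing_mm=pspec_template.spacing_mm,
                lesion_center_mm=pspec_template.lesion_center_mm,
                lesion_radius_mm=lesion.get("lesion_radius_mm", pspec_template.lesion_radius_mm),
                suv_max=lesion.get("suv_max", pspec_template.suv_max),
                background_suv=pspec_template.background_suv,
                texture_scale_mm=lesion.get("texture_scale_mm", pspec_template.texture_scale_mm),
                heterogeneity_sd=lesion.get("heterogeneity_sd", pspec_template.heterogeneity_sd),
                noise_sd=pspec_template.noise_sd,
                radial_falloff=pspec_template.radial_falloff,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, true_mask = generate_phantom(pspec)
        time_days = float(np.round(observed[i]))
        ev = int(event[i])
        subjects.append(
            SyntheticSubject(
                subject_id=f"subj_{i:03d}",
                volume=vol,
                true_mask=true_mask,
                clinical={k: (v[i].item() if hasattr(v[i], "item") else v[i]) for k, v in clin_cols.items()},
                lesion_params=lesion,
                survival_time_days=time_days,
                event=ev,
                one_year_dead=int(ev == 1 and time_days <= 365),
            )
        )
    return subjects


def write_cohort(subjects: list[SyntheticSubject], out_dir: str | Path) -> dict:
    """Serialize a cohort: NRRD volumes/masks, clinical & survival CSVs, JSON manifest."""
    from .io import write_mask, write_volume

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    clinical_fields = list(subjects[0].clinical.keys())
    entries = []
    with open(out / "clinical.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id"] + clinical_fields)
        for s in subjects:
            writer.writerow([s.subject_id] + [s.clinical[k] for k in clinical_fields])
    with open(out / "survival.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "time_days", "event", "one_year_dead"])
        for s in subjects:
            writer.writerow([s.subject_id, s.survival_time_days, s.event, s.one_year_dead])

    for s in subjects:
        entry = {"subject_id": s.subject_id, "lesion_params": s.lesion_params}
        if s.volume is not None:
            vpath = out / "volumes" / f"{s.subject_id}.nrrd"
            mpath = out / "masks" / f"{s.subject_id}.nrrd"
            write_volume(vpath, s.volume)
            write_mask(
                mpath,
                Volume(s.true_mask.astype(np.uint8), s.volume.spacing_mm, s.volume.origin_mm),
            )
            entry["volume"] = str(vpath.relative_to(out))
            entry["mask"] = str(mpath.relative_to(out))
        entries.append(entry)

    manifest = {
        "n_subjects": len(subjects),
        "clinical_csv": "clinical.csv",
        "survival_csv": "survival.csv",
        "clinical_columns": clinical_fields,
        "subjects": entries,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
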