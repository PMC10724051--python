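"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a late-midlife observational cohort
followed with a cognitive composite at roughly two-year intervals: a
three-class mixture of person-level bent-line trajectories (a small
steep-decline class, an intermediate class and a minimal-decline majority),
an irregular visit grid, and class-correlated biomarkers (amyloid PET DVR,
tau PET SUVR composites, plasma pTau217, hippocampal and tissue volumes,
white-matter hyperintensities) and health covariates.

The generator's job is to provide cohorts on which every downstream stage of
the pipeline (trajectory model, clustering, harmonization, comparisons) is
testable with known ground truth.  Defaults mirror cohort-level facts
(class weights 0.072/0.418/0.510, baseline age ~ N(58.4, 6.4) on [40, 74],
~2-year visit intervals, 4-7 visits giving a mean (SD) follow-up of about
9.0 (2.2) years); class-conditional trajectory distributions and the
residual SD are synthetic conventions chosen once for clear, recoverable
class separation, not estimates.

Randomness: one SeedSequence per cohort is split deterministically per
participant, so increasing ``n_participants`` extends the cohort without
reshuffling earlier participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy import special
from sklearn.base import BaseEstimator

from .bentline import LongitudinalSeries, PersonParams, bentline_mean

__all__ = [
    "ConfigError",
    "Normal",
    "ClassParams",
    "GeneratorConfig",
    "SyntheticCohort",
    "CohortGenerator",
    "sample_person_params",
    "sample_visit_schedule",
    "generate_longitudinal",
    "generate_biomarkers",
    "generate_covariates",
    "generate_cohort",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float


@dataclass(frozen=True)
class ClassParams:
    """Per-class distributions of the four bent-line parameters."""

    name: str
    weight: float
    alpha1: Normal  # score at CP [Z]
    alpha2: Normal  # pre-CP slope [Z/year]
    alpha3: Normal  # post-CP slope [Z/year]
    tau: Normal  # CP age [years]


# Baseline (class-shift-free) biomarker distributions, in native units.
# Volumes in litres; HV/WMHV in cm^3; DVR/SUVR unitless; pTau217 in pg/mL.
BIOMARKER_BASE = {
    "dvr": Normal(1.05, 0.07),
    "tau_mtl": Normal(1.00, 0.10),
    "tau_mtc": Normal(1.00, 0.09),
    "ptau217": Normal(0.18, 0.06),
    "gm": Normal(0.62, 0.045),
    "wm": Normal(0.46, 0.040),
    "csf": Normal(0.30, 0.045),
    "wmhv": Normal(2.0, 1.2),
}
# hippocampal volume: base level, slope on TICV (cm^3 per litre) and noise,
# so HV co-varies positively with head size and the TICV regression
# adjustment has something to remove.
HV_BASE = 7.8
HV_TICV_SLOPE = 3.0
HV_NOISE_SD = 0.45
TICV_REF = 1.38


def _default_classes() -> tuple[ClassParams, ...]:
    # Means echo the verbal cluster descriptions (steep: average level at CP,
    # earlier CP, fast post-CP decline; intermediate: low-average level,
    # later CP, weakening trajectory; minimal: high level, mild decline).
    # SDs are synthetic conventions giving clearly separated classes.
    return (
        ClassParams(
            "steep",
            0.072,
            alpha1=Normal(0.0, 0.12),
            alpha2=Normal(0.0, 0.010),
            alpha3=Normal(-0.60, 0.050),
            tau=Normal(57.0, 1.5),
        ),
        ClassParams(
            "intermediate",
            0.418,
            alpha1=Normal(-0.45, 0.12),
            alpha2=Normal(-0.05, 0.010),
            alpha3=Normal(-0.15, 0.020),
            tau=Normal(64.0, 1.5),
        ),
        ClassParams(
            "minimal",
            0.510,
            alpha1=Normal(0.45, 0.12),
            alpha2=Normal(0.04, 0.010),
            alpha3=Normal(-0.05, 0.020),
            tau=Normal(67.0, 1.5),
        ),
    )


def _default_biomarker_effects() -> dict:
    """Per-class additive mean shifts, worse A/T/N/V in steeper classes."""
    return {
        "dvr": (0.22, 0.05, 0.0),
        "tau_mtl": (0.45, 0.08, 0.0),
        "tau_mtc": (0.40, 0.07, 0.0),
        "ptau217": (0.22, 0.04, 0.0),
        "hv": (-0.80, -0.20, 0.0),
        "csf": (0.06, 0.02, 0.0),
        "gm": (-0.04, -0.01, 0.0),
        "wm": (0.0, 0.0, 0.0),
        "wmhv": (2.5, 0.8, 0.0),
    }


def _default_covariate_prevalences() -> dict:
    # Per-class probabilities for binary covariates; the female and APOE e4
    # rows reproduce the printed per-group percentages, whose weighted
    # averages give marginals of ~0.691 and ~0.381 under the class weights.
    return {
        "female": (0.727, 0.558, 0.794),
        "apoe4": (0.597, 0.361, 0.367),
        "family_history": (0.805, 0.726, 0.750),
        "college": (0.610, 0.543, 0.712),
        "hypertension": (0.429, 0.346, 0.297),
        "diabetes": (0.156, 0.096, 0.066),
        "high_cholesterol": (0.688, 0.533, 0.502),
        "self_reported_depression": (0.30, 0.22, 0.20),
        "memory_problem": (0.40, 0.25, 0.15),
        "cu_at_reference": (0.67, 0.80, 0.97),
    }


def _default_continuous_covariates() -> dict:
    """name -> per-class Normal(mean, sd); counts are rounded and clipped."""
    return {
        "bmi": (Normal(28.6, 5.5), Normal(29.2, 5.6), Normal(28.2, 5.4)),
        "cesd": (Normal(10.0, 7.0), Normal(8.5, 6.5), Normal(7.5, 6.0)),
        "libra": (Normal(1.8, 2.1), Normal(1.6, 2.1), Normal(0.8, 2.0)),
        "rx_count": (Normal(4.2, 2.8), Normal(3.4, 2.5), Normal(3.0, 2.3)),
        "comorbidity_tally": (Normal(2.6, 1.7), Normal(2.2, 1.6), Normal(2.0, 1.5)),
        "whr_female": (Normal(0.845, 0.075), Normal(0.840, 0.075), Normal(0.825, 0.07)),
        "whr_male": (Normal(0.97, 0.06), Normal(0.97, 0.06), Normal(0.95, 0.055)),
    }


def _default_likert() -> dict:
    # srh on 1-5 (higher = better health), memory_rating on 1-7 (higher =
    # fewer problems); steeper classes report worse health/memory.
    return {
        "srh": (
            (0.04, 0.07, 0.35, 0.34, 0.20),
            (0.02, 0.04, 0.41, 0.33, 0.20),
            (0.02, 0.03, 0.34, 0.36, 0.25),
        ),
        "memory_rating": (
            (0.06, 0.09, 0.10, 0.26, 0.25, 0.15, 0.09),
            (0.03, 0.04, 0.06, 0.24, 0.28, 0.20, 0.15),
            (0.01, 0.02, 0.03, 0.21, 0.29, 0.24, 0.20),
        ),
    }


@dataclass
class GeneratorConfig:
    """Full generative specification of a synthetic cohort."""

    n_participants: int = 1068
    classes: tuple = field(default_factory=_default_classes)
    baseline_age_mean: float = 58.4
    baseline_age_sd: float = 6.4
    baseline_age_lower: float = 40.0
    baseline_age_upper: float = 74.0
    visit_interval_mean: float = 2.0
    visit_interval_sd: float = 0.35
    n_visits_min: int = 4
    n_visits_max: int = 7
    residual_sd: float = 0.05
    biomarker_effects: dict = field(default_factory=_default_biomarker_effects)
    covariate_prevalences: dict = field(default_factory=_default_covariate_prevalences)
    continuous_covariates: dict = field(default_factory=_default_continuous_covariates)
    likert_probs: dict = field(default_factory=_default_likert)
    missingness: dict = field(
        default_factory=lambda: {
            "dvr": 0.0,
            "tau_mtl": 0.0,
            "tau_mtc": 0.0,
            "ptau217": 0.0,
            "mri": 0.0,
        }
    )
    param_correlation: object = None  # optional 4x4 correlation matrix
    #: emulate the unimpaired-at-entry selection effect: participants are
    #: enrolled before their change point, so the per-person CP law is
    #: truncated below at (first visit age + 0.5 y) and CPs before the first
    #: visit are essentially absent, as such cohorts report.
    enroll_before_cp: bool = True
    seed: int = 0

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        w = np.array([c.weight for c in self.classes], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError("class weights must be >= 0 and sum to 1")
        if self.n_visits_min < 3:
            raise ConfigError("n_visits_min must be >= 3 (inclusion rule)")
        if self.n_visits_max < self.n_visits_min:
            raise ConfigError("n_visits_max < n_visits_min")
        if not self.baseline_age_lower < self.baseline_age_upper:
            raise ConfigError("baseline age bounds must satisfy lower < upper")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be > 0")
        if self.visit_interval_mean <= 0:
            raise ConfigError("visit_interval_mean must be > 0")
        if self.param_correlation is not None:
            c = np.asarray(self.param_correlation, dtype=float)
            if c.shape != (4, 4) or not np.allclose(c, c.T):
                raise ConfigError("param_correlation must be a symmetric 4x4 matrix")

    @property
    def class_names(self) -> list:
        return [c.name for c in self.classes]

    @property
    def tau_bounds(self) -> tuple:
        # CP truncated wider than the baseline-age range so that CPs before
        # the first or after the last visit occur.
        return (self.baseline_age_lower - 10.0, self.baseline_age_upper + 15.0)

    # -- presets -----------------------------------------------------------

    @classmethod
    def default(cls, n_participants: int = 1068, seed: int = 0) -> "GeneratorConfig":
        return cls(n_participants=n_participants, seed=seed)

    @classmethod
    def parameter_recovery(
        cls, n_participants: int = 100, seed: int = 0
    ) -> "GeneratorConfig":
        """Single-class design for parameter-recovery simulation studies.

        One population with a clearly identifiable slope change (pre-CP
        slope ~ 0, post-CP slope -0.2 Z/y), 6 visits per participant and
        residual SD 0.3; the CP distribution N(63, 4) straddles the
        observation windows so both observed and unobserved change points
        occur.
        """
        cfg = cls(n_participants=n_participants, seed=seed)
        cfg.classes = (
            ClassParams(
                "all",
                1.0,
                alpha1=Normal(0.0, 0.3),
                alpha2=Normal(-0.01, 0.015),
                alpha3=Normal(-0.2, 0.05),
                tau=Normal(63.0, 4.0),
            ),
        )
        cfg.n_visits_min = cfg.n_visits_max = 6
        cfg.residual_sd = 0.3
        cfg.enroll_before_cp = False  # CPs straddle windows on both sides
        return cfg

    @classmethod
    def mostly_unobserved_cp(
        cls, n_participants: int = 1068, seed: int = 0
    ) -> "GeneratorConfig":
        """Preset whose CP distribution puts most CPs outside observation
        windows (late, dispersed CPs), mirroring cohorts where the large
        majority of change points have not yet been observed."""
        cfg = cls(n_participants=n_participants, seed=seed)
        cfg.classes = tuple(
            replace(c, tau=Normal(75.0, 7.0)) for c in cfg.classes
        )
        return cfg

    # -- (de)serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_config_to_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return _config_from_dict(raw)


def _config_to_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["classes"] = [
        {
            "name": c.name,
            "weight": c.weight,
            **{
                p: [getattr(c, p).mean, getattr(c, p).sd]
                for p in ("alpha1", "alpha2", "alpha3", "tau")
            },
        }
        for c in cfg.classes
    ]
    d["continuous_covariates"] = {
        k: [[nv.mean, nv.sd] for nv in v]
        for k, v in cfg.continuous_covariates.items()
    }
    if cfg.param_correlation is not None:
        d["param_correlation"] = np.asarray(cfg.param_correlation).tolist()
    return d


def _config_from_dict(raw: dict) -> GeneratorConfig:
    raw = dict(raw)
    classes = tuple(
        ClassParams(
            name=c["name"],
            weight=float(c["weight"]),
            **{
                p: Normal(float(c[p][0]), float(c[p][1]))
                for p in ("alpha1", "alpha2", "alpha3", "tau")
            },
        )
        for c in raw.pop("classes")
    )
    cont = {
        k: tuple(Normal(float(m), float(s)) for m, s in v)
        for k, v in raw.pop("continuous_covariates").items()
    }
    likert = {k: tuple(tuple(p) for p in v) for k, v in raw.pop("likert_probs").items()}
    return GeneratorConfig(
        classes=classes, continuous_covariates=cont, likert_probs=likert, **raw
    )


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def _truncnorm(mean, sd, lower, upper, rng, size=None):
    """Inverse-CDF draw from a truncated normal (fast, vectorized)."""
    if sd == 0:
        val = np.clip(mean, lower, upper)
        return np.full(size, val) if size else float(val)
    fa = special.ndtr((lower - mean) / sd)
    fb = special.ndtr((upper - mean) / sd)
    if fb - fa < 1e-14:
        # far-tail truncation underflows the CDF; the conditional law then
        # concentrates at the bound nearest the mean
        val = float(np.clip(mean, lower, upper))
        return np.full(size, val) if size else val
    u = rng.uniform(fa, fb, size)
    out = np.clip(mean + sd * special.ndtri(u), lower, upper)
    return out if size else float(out)


def _class_index(config: GeneratorConfig, class_label) -> int:
    names = config.class_names
    if isinstance(class_label, str):
        if class_label not in names:
            raise ConfigError(f"unknown class label {class_label!r}; known: {names}")
        return names.index(class_label)
    idx = int(class_label)
    if not 0 <= idx < len(names):
        raise ConfigError(f"class index {idx} out of range for {len(names)} classes")
    return idx


def sample_person_params(
    class_label, config: GeneratorConfig, rng, tau_lower: float | None = None
) -> PersonParams:
    """Draw one participant's bent-line parameters from their class.

    Parameters are independent normals by default; an optional 4x4
    correlation matrix in the config induces cross-parameter dependence.
    The CP age is truncated to a window wider than the baseline-age range so
    that unobserved CPs occur; ``tau_lower`` optionally raises the lower
    truncation bound (used by the cohort assembly to emulate the
    unimpaired-at-entry selection effect, under which change points before
    the first visit are essentially absent).
    """
    idx = _class_index(config, class_label)
    cp = config.classes[idx]
    means = np.array([cp.alpha1.mean, cp.alpha2.mean, cp.alpha3.mean, cp.tau.mean])
    sds = np.array([cp.alpha1.sd, cp.alpha2.sd, cp.alpha3.sd, cp.tau.sd])
    lo, hi = config.tau_bounds
    if tau_lower is not None:
        lo = min(max(lo, tau_lower), hi - 1e-6)
    if config.param_correlation is not None:
        corr = np.asarray(config.param_correlation, dtype=float)
        cov = corr * np.outer(sds, sds)
        draw = rng.multivariate_normal(means, cov)
        draw[3] = np.clip(draw[3], lo, hi)
    else:
        draw = means + sds * rng.standard_normal(4)
        if sds[3] > 0:
            draw[3] = _truncnorm(means[3], sds[3], lo, hi, rng)
        else:
            draw[3] = np.clip(means[3], lo, hi)
    return PersonParams(*draw)


def sample_visit_schedule(config: GeneratorConfig, rng) -> np.ndarray:
    """Draw a strictly increasing visit-age vector for one participant."""
    baseline = _truncnorm(
        config.baseline_age_mean,
        config.baseline_age_sd,
        config.baseline_age_lower,
        config.baseline_age_upper,
        rng,
    )
    n_visits = int(rng.integers(config.n_visits_min, config.n_visits_max + 1))
    gaps = _truncnorm(
        config.visit_interval_mean,
        config.visit_interval_sd,
        0.0,
        np.inf,
        rng,
        size=n_visits - 1,
    )
    return baseline + np.concatenate([[0.0], np.cumsum(gaps)])


def generate_longitudinal(
    params: PersonParams, visit_ages, residual_sd: float, rng, participant_id=None
) -> LongitudinalSeries:
    """Noisy bent-line scores at the given visit ages."""
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    ages = np.asarray(visit_ages, dtype=float)
    if not np.all(np.diff(ages) > 0):
        raise ValueError("visit ages must be strictly increasing")
    scores = bentline_mean(ages, params)
    if residual_sd > 0:
        scores = scores + rng.normal(0.0, residual_sd, ages.size)
    return LongitudinalSeries(participant_id, ages, np.asarray(scores, dtype=float))


def generate_biomarkers(class_label, covariates: dict, config: GeneratorConfig, rng) -> dict:
    """One participant's biomarker row (native units), class-shifted.

    Tissue volumes GM/WM/CSF are drawn first; TICV = GM + WM + CSF by
    construction, and hippocampal volume is generated with positive
    dependence on TICV so the head-size regression adjustment is exercised.
    """
    idx = _class_index(config, class_label)
    eff = config.biomarker_effects
    row = {}
    for name in ("gm", "wm", "csf"):
        base = BIOMARKER_BASE[name]
        shift = eff.get(name, (0.0,) * len(config.classes))[idx]
        row[name] = max(base.mean + shift + base.sd * rng.standard_normal(), 0.05)
    row["ticv"] = row["gm"] + row["wm"] + row["csf"]
    hv_shift = eff.get("hv", (0.0,) * len(config.classes))[idx]
    row["hv"] = max(
        HV_BASE
        + HV_TICV_SLOPE * (row["ticv"] - TICV_REF)
        + hv_shift
        + HV_NOISE_SD * rng.standard_normal(),
        1.0,
    )
    for name in ("dvr", "tau_mtl", "tau_mtc", "ptau217", "wmhv"):
        base = BIOMARKER_BASE[name]
        shift = eff.get(name, (0.0,) * len(config.classes))[idx]
        row[name] = max(base.mean + shift + base.sd * rng.standard_normal(), 0.01)
    row["cu_flag"] = bool(covariates.get("cu_at_reference", True))
    row["assessment_age"] = float(covariates.get("age_last", np.nan))
    return row


def generate_covariates(class_label, config: GeneratorConfig, rng) -> dict:
    """One participant's covariate record from class-conditional laws."""
    idx = _class_index(config, class_label)
    rec = {}
    for name, probs in config.covariate_prevalences.items():
        rec[name] = bool(rng.random() < probs[idx])
    cont = config.continuous_covariates
    for name in ("bmi", "cesd", "libra"):
        nv = cont[name][idx]
        rec[name] = float(max(nv.mean + nv.sd * rng.standard_normal(), 0.0)) if name != "libra" else float(
            nv.mean + nv.sd * rng.standard_normal()
        )
    rec["bmi"] = max(rec["bmi"], 14.0)
    whr_key = "whr_female" if rec.get("female", False) else "whr_male"
    nv = cont[whr_key][idx]
    rec["whr"] = float(max(nv.mean + nv.sd * rng.standard_normal(), 0.5))
    for name in ("rx_count", "comorbidity_tally"):
        nv = cont[name][idx]
        rec[name] = int(np.clip(round(nv.mean + nv.sd * rng.standard_normal()), 0, 15))
    for name, levels in (("srh", 5), ("memory_rating", 7)):
        probs = np.asarray(config.likert_probs[name][idx], dtype=float)
        probs = probs / probs.sum()
        rec[name] = int(rng.choice(np.arange(1, levels + 1), p=probs))
    rec["sex"] = "female" if rec.get("female", False) else "male"
    return rec


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Generated cohort: long scores, per-person truth, biomarkers, covariates."""

    long: pd.DataFrame  # participant_id, visit_age_years, pacc3_z
    truth: pd.DataFrame  # participant_id, class, alpha1..tau
    biomarkers: pd.DataFrame
    covariates: pd.DataFrame
    config: GeneratorConfig

    @property
    def series(self) -> list[LongitudinalSeries]:
        out = []
        for pid, grp in self.long.groupby("participant_id", sort=False):
            out.append(
                LongitudinalSeries(
                    pid, grp["visit_age_years"].to_numpy(), grp["pacc3_z"].to_numpy()
                )
            )
        return out

    def write_csvs(self, out_dir) -> dict:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("cohort_long", self.long),
            ("truth", self.truth),
            ("biomarkers", self.biomarkers),
            ("covariates", self.covariates),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def generate_cohort(config: GeneratorConfig | None = None, seed=None) -> SyntheticCohort:
    """Generate a full cohort from a validated configuration.

    The cohort seed is split per participant, so the first ``k`` participants
    are identical across runs that differ only in ``n_participants``.
    """
    config = config or GeneratorConfig.default()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    weights = np.array([c.weight for c in config.classes], dtype=float)
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)

    long_rows, truth_rows, bio_rows, cov_rows = [], [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i:05d}"
        k = int(rng.choice(len(weights), p=weights))
        ages = sample_visit_schedule(config, rng)
        tau_lower = float(ages[0]) + 0.5 if config.enroll_before_cp else None
        params = sample_person_params(k, config, rng, tau_lower=tau_lower)
        series = generate_longitudinal(params, ages, config.residual_sd, rng, pid)
        cov = generate_covariates(k, config, rng)
        cov["age_baseline"] = float(ages[0])
        cov["age_last"] = float(ages[-1])
        cov["age"] = cov["age_baseline"]
        bio = generate_biomarkers(k, cov, config, rng)
        # independent Bernoulli missingness per modality
        miss = config.missingness
        if rng.random() < miss.get("dvr", 0.0):
            bio["dvr"] = np.nan
        for key, mkey in (
            ("tau_mtl", "tau_mtl"),
            ("tau_mtc", "tau_mtc"),
            ("ptau217", "ptau217"),
        ):
            if rng.random() < miss.get(mkey, 0.0):
                bio[key] = np.nan
        if rng.random() < miss.get("mri", 0.0):
            for key in ("hv", "gm", "wm", "csf", "ticv", "wmhv"):
                bio[key] = np.nan

        for a, s in zip(series.ages, series.scores):
            long_rows.append({"participant_id": pid, "visit_age_years": a, "pacc3_z": s})
        truth_rows.append(
            {
                "participant_id": pid,
                "class": config.classes[k].name,
                "alpha1": params.alpha1,
                "alpha2": params.alpha2,
                "alpha3": params.alpha3,
                "tau": params.tau,
            }
        )
        bio_rows.append({"participant_id": pid, **bio})
        cov_rows.append({"participant_id": pid, **cov})

    return SyntheticCohort(
        long=pd.DataFrame(long_rows),
        truth=pd.DataFrame(truth_rows),
        biomarkers=pd.DataFrame(bio_rows),
        covariates=pd.DataFrame(cov_rows),
        config=config,
    )


class CohortGenerator(BaseEstimator):
    """sklearn-style front end over :func:`generate_cohort`.

    ``sample()`` (or ``fit_transform`` style usage) returns a
    :class:`SyntheticCohort`.
    """

    def __init__(self, config: GeneratorConfig | None = None, seed: int = 0):
        self.config = config
        self.seed = seed

    def sample(self) -> SyntheticCohort:
        cfg = self.config or GeneratorConfig.default()
        return generate_cohort(cfg, seed=self.seed)
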