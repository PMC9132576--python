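"""Synthetic cohorts with known ground truth for every downstream stage.

The generator emulates the statistical structure the analysis assumes — not
real UK-Biobank-like data, but data in which every estimand is known:

* demographics (age 50-80, sex, education, blood pressure with a planted
  hypertension rate, menopause/hormone status, BMI, head-size factor);
* diabetes status with a self-reported onset age at up to three visits
  (truth plus integer-rounded recall noise, SD 1 year);
* regional gray-matter volumes that are linear in age with region-specific
  slopes, plus for cases a volume offset proportional to the age-slope
  (vulnerability) vector and a duration slope equal to ``acceleration``
  times the age slope — so the overlap correlation and the acceleration
  ratio both have closed-form planted values;
* per-domain cognitive scores, linear in age with an additive case offset
  and configurable missingness;
* band-limited fMRI voxel time series with cluster-localized amplitude
  effects.

Overlap truth: the case offset vector is ``k * age_slopes + perturbation``
with the perturbation made orthogonal (Gram-Schmidt) to both the constant
vector and the age-slope vector and scaled to ``m`` times the centered norm
of ``k * age_slopes``.  The population Pearson correlation between the case
offsets and the age slopes is then exactly ``1 / sqrt(1 + m^2)``.

All generators are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .alff import VoxelTimeSeries
from .filters import derive_fields

AGE_REF = 50.0  # years; intercepts are interpretable at cohort entry


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """Population parameters of a synthetic matched-cohort study."""

    n_subjects: int = 2000
    age_range: tuple[int, int] = (50, 80)
    t2dm_prevalence: float = 0.05
    sex_ratio: float = 0.5          # proportion female
    education_rate: float = 0.33    # proportion with a college degree
    hypertension_rate: float = 0.35
    onset_min: float = 40.0         # years; type-1-diabetes guard
    duration_max: float = 31.0      # years since diagnosis
    metformin_rate: float = 0.49    # of cases: metformin only
    unmedicated_rate: float = 0.35  # of cases: no antidiabetic medication
    menopause_rate: float = 0.85    # of females
    hormone_therapy_rate: float = 0.08  # of females
    mean_duration: float = 8.5      # years, before truncation
    onset_report_sd: float = 1.0    # recall noise, years
    report_missing_rate: float = 0.15  # visits 2 and 3 only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        lo, hi = self.age_range
        if not lo <= hi:
            raise ValueError("age_range must be a nonempty interval")
        for name in ("t2dm_prevalence", "sex_ratio", "education_rate",
                     "hypertension_rate", "metformin_rate", "unmedicated_rate",
                     "menopause_rate", "hormone_therapy_rate",
                     "report_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.metformin_rate + self.unmedicated_rate > 1.0:
            raise ValueError("medication class proportions exceed 1")


def _truncated_exponential(rng, scale: float, upper: np.ndarray) -> np.ndarray:
    """Exponential(scale) truncated to [0, upper], by inverse CDF."""
    u = rng.random(upper.shape)
    cap = -np.expm1(-upper / scale)          # F(upper)
    return -scale * np.log1p(-u * cap)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One synthetic cohort table, one row per subject.

    Cases carry ground-truth columns ``onset_true`` and ``duration_true``
    alongside the noisy per-visit reports; derived fields (``hypertension``,
    ``onset_age``, ``duration``) are computed exactly as the analysis
    pipeline computes them.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lo, hi = spec.age_range

    age = rng.integers(lo, hi + 1, size=n).astype(float)
    female = rng.random(n) < spec.sex_ratio
    education = (rng.random(n) < spec.education_rate).astype(float)

    hyper = rng.random(n) < spec.hypertension_rate
    sbp = np.empty(n)
    dbp = np.empty(n)
    nh = ~hyper
    # normotensive: both clauses of the rule must fail (sbp <= 140, dbp <= 90)
    sbp[nh] = truncnorm.rvs((95 - 128) / 12, (140 - 128) / 12, loc=128, scale=12,
                            size=nh.sum(), random_state=rng)
    dbp[nh] = truncnorm.rvs((55 - 78) / 8, (90 - 78) / 8, loc=78, scale=8,
                            size=nh.sum(), random_state=rng)
    # hypertensive: systolic-driven in ~70%, isolated diastolic otherwise
    n_h = int(hyper.sum())
    systolic_driven = rng.random(n_h) < 0.7
    sbp_h = np.where(systolic_driven,
                     truncnorm.rvs((141 - 155) / 12, (200 - 155) / 12, loc=155,
                                   scale=12, size=n_h, random_state=rng),
                     truncnorm.rvs((110 - 133) / 8, (140 - 133) / 8, loc=133,
                                   scale=8, size=n_h, random_state=rng))
    dbp_h = np.where(systolic_driven,
                     truncnorm.rvs((60 - 88) / 9, (110 - 88) / 9, loc=88,
                                   scale=9, size=n_h, random_state=rng),
                     truncnorm.rvs((91 - 95) / 4, (110 - 95) / 4, loc=95,
                                   scale=4, size=n_h, random_state=rng))
    sbp[hyper] = sbp_h
    dbp[hyper] = dbp_h
    dbp = np.minimum(dbp, sbp - 10.0)  # keep the pulse pressure physical

    menopause = np.full(n, np.nan)
    hormone = np.full(n, np.nan)
    nf = int(female.sum())
    menopause[female] = (rng.random(nf) < spec.menopause_rate).astype(float)
    hormone[female] = (rng.random(nf) < spec.hormone_therapy_rate).astype(float)

    t2dm = (rng.random(n) < spec.t2dm_prevalence).astype(float)
    cases = t2dm == 1.0
    n_c = int(cases.sum())

    onset_true = np.full(n, np.nan)
    duration_true = np.full(n, np.nan)
    if n_c:
        max_dur = np.minimum(spec.duration_max, age[cases] - spec.onset_min)
        max_dur = np.maximum(max_dur, 0.0)
        dur = _truncated_exponential(rng, spec.mean_duration, max_dur)
        duration_true[cases] = dur
        onset_true[cases] = age[cases] - dur

    reports = np.full((n, 3), np.nan)
    if n_c:
        if spec.onset_report_sd > 0:
            # recall error plus the integer rounding of a questionnaire answer
            noise = rng.normal(0.0, spec.onset_report_sd, size=(n_c, 3))
            rep = np.round(onset_true[cases, None] + noise)
        else:
            rep = np.repeat(onset_true[cases, None], 3, axis=1)
        rep = np.clip(rep, 0.0, age[cases, None])
        miss = rng.random((n_c, 3)) < spec.report_missing_rate
        miss[:, 0] = False                     # the first visit always reports
        rep[miss] = np.nan
        reports[cases] = rep

    metformin = np.zeros(n)
    other_med = np.zeros(n)
    if n_c:
        u = rng.random(n_c)
        met_only = u < spec.metformin_rate
        unmed = (u >= spec.metformin_rate) & \
                (u < spec.metformin_rate + spec.unmedicated_rate)
        other = ~met_only & ~unmed
        met_c = np.zeros(n_c)
        oth_c = np.zeros(n_c)
        met_c[met_only] = 1.0
        oth_c[other] = 1.0
        met_c[other] = (rng.random(int(other.sum())) < 0.5).astype(float)
        metformin[cases] = met_c
        other_med[cases] = oth_c

    bmi = np.where(cases, rng.normal(30.5, 5.0, n), rng.normal(27.0, 4.0, n))
    bmi = np.clip(bmi, 16.0, 55.0)
    head_size = np.clip(rng.normal(1.0, 0.08, n), 0.7, 1.3)

    table = pd.DataFrame({
        "id": [f"S{i:06d}" for i in range(n)],
        "age": age,
        "sex": np.where(female, "F", "M"),
        "education": education,
        "sbp": sbp,
        "dbp": dbp,
        "t2dm": t2dm,
        "onset_report_1": reports[:, 0],
        "onset_report_2": reports[:, 1],
        "onset_report_3": reports[:, 2],
        "onset_true": onset_true,
        "duration_true": duration_true,
        "menopause": menopause,
        "hormone_therapy": hormone,
        "metformin": metformin,
        "other_t2dm_medication": other_med,
        "bmi": bmi,
        "head_size": head_size,
    })
    return derive_fields(table)


# ---------------------------------------------------------------------------
# regional gray-matter volumes

# (region, baseline bilateral gray-matter volume mm^3, age slope %/year)
# Age slopes follow the vulnerability ordering of the aging literature:
# steepest in the ventral striatum and Heschl's gyrus, shallowest in the
# thalamus and caudate.
_REGION_TABLE: list[tuple[str, float, float]] = [
    ("frontal pole",               13500, -0.55),
    ("superior frontal gyrus",     21000, -0.60),
    ("middle frontal gyrus",       19500, -0.55),
    ("inferior frontal gyrus",     11000, -0.50),
    ("orbitofrontal cortex",       15500, -0.45),
    ("precentral gyrus",           17000, -0.50),
    ("premotor cortex",            12500, -0.55),
    ("supplementary motor cortex",  9000, -0.50),
    ("paracentral lobule",          6500, -0.45),
    ("postcentral gyrus",          14500, -0.45),
    ("superior parietal lobule",   13000, -0.50),
    ("supramarginal gyrus",        12000, -0.50),
    ("angular gyrus",              10500, -0.45),
    ("precuneus",                  13500, -0.50),
    ("superior temporal gyrus",    12500, -0.60),
    ("middle temporal gyrus",      14000, -0.55),
    ("inferior temporal gyrus",    13000, -0.50),
    ("fusiform gyrus",             11500, -0.45),
    ("parahippocampal gyrus",       4800, -0.40),
    ("temporal pole",               9500, -0.55),
    ("Heschl's gyrus",              2100, -0.90),
    ("planum temporale",            2900, -0.70),
    ("insula",                     10500, -0.55),
    ("frontal operculum",           4200, -0.50),
    ("anterior cingulate cortex",   7800, -0.45),
    ("subgenual area",              1400, -0.40),
    ("mid cingulate cortex",        6200, -0.40),
    ("posterior cingulate cortex",  6800, -0.45),
    ("retrosplenial cortex",        2200, -0.40),
    ("occipital pole",              8200, -0.35),
    ("lateral occipital cortex",   16500, -0.40),
    ("lingual gyrus",               9200, -0.35),
    ("cuneus",                      7400, -0.35),
    ("calcarine cortex",            5800, -0.30),
    ("hippocampus",                 7800, -0.50),
    ("amygdala",                    3200, -0.45),
    ("thalamus",                   15500, -0.28),
    ("caudate",                     7000, -0.30),
    ("putamen",                     9800, -0.65),
    ("pallidum",                    3600, -0.50),
    ("ventral striatum",            1300, -1.00),
    ("ventral diencephalon",        8300, -0.40),
    ("cerebellar cortex",          98000, -0.55),
    ("cerebellar vermis",           9500, -0.50),
    ("brainstem",                  22000, -0.35),
]

N_REGIONS = len(_REGION_TABLE)
assert N_REGIONS == 45

REGION_NAMES = [name for name, _, _ in _REGION_TABLE]


@dataclass
class AtrophySpec:
    """Generative parameters of the regional gray-matter model.

    Per region ``r`` the head-size-normalized volume of a subject is::

        base[r] + age_slope[r] * (age - 50)
        + case * (k * age_slope[r] + perturbation[r])
        + case * acceleration * age_slope[r] * duration
        + Normal(0, noise_sd[r])

    ``t2dm_offset_scale`` (``k``, years) sets how many years of age-slope
    loss a diagnosis is worth in each region; ``acceleration`` is the planted
    duration/age slope ratio; ``perturbation_rel`` (``m``) is the relative
    magnitude of the off-axis component of the case offset, giving a planted
    overlap correlation of ``1 / sqrt(1 + m^2)``.
    """

    region_names: list[str] = field(default_factory=lambda: list(REGION_NAMES))
    base_volumes: np.ndarray = field(
        default_factory=lambda: np.array([b for _, b, _ in _REGION_TABLE]))
    age_slopes: np.ndarray = field(
        default_factory=lambda: np.array([b * s / 100.0
                                          for _, b, s in _REGION_TABLE]))
    t2dm_offset_scale: float = 6.0   # years of age-equivalent loss at diagnosis
    acceleration: float = 0.26       # duration slope = alpha * age slope
    perturbation_rel: float = 0.0    # m; overlap estimand = 1/sqrt(1+m^2)
    perturbation_seed: int = 1234
    noise_sd: np.ndarray | None = None  # default: 8% of baseline volume

    def __post_init__(self) -> None:
        self.base_volumes = np.asarray(self.base_volumes, dtype=float)
        self.age_slopes = np.asarray(self.age_slopes, dtype=float)
        if not (len(self.region_names) == len(self.base_volumes)
                == len(self.age_slopes) == 45):
            raise ValueError("exactly 45 regions are required")
        if np.any(self.base_volumes <= 0):
            raise ValueError("base volumes must be positive")
        if self.noise_sd is None:
            self.noise_sd = 0.08 * self.base_volumes
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be nonnegative")

    @property
    def perturbation(self) -> np.ndarray:
        """Off-axis component of the case offset (zero when ``m`` = 0).

        A seeded Gaussian draw orthogonalized (Gram-Schmidt) against the
        constant vector and the age-slope vector, then scaled so its norm is
        ``m`` times the centered norm of ``k * age_slopes`` — this makes the
        planted Pearson overlap exactly ``1 / sqrt(1 + m^2)``.
        """
        m = self.perturbation_rel
        if m == 0.0:
            return np.zeros(45)
        rng = np.random.default_rng(self.perturbation_seed)
        g = rng.normal(size=45)
        ones = np.ones(45)
        a = self.age_slopes - self.age_slopes.mean()
        g = g - g @ ones / 45.0
        g = g - (g @ a) / (a @ a) * a
        g = g / np.linalg.norm(g)
        return g * m * abs(self.t2dm_offset_scale) * np.linalg.norm(a)

    @property
    def t2dm_offsets(self) -> np.ndarray:
        """The planted per-region case offset vector (mm^3)."""
        return self.t2dm_offset_scale * self.age_slopes + self.perturbation


def default_atrophy_spec(**overrides) -> AtrophySpec:
    """The standard 45-region generative spec; keyword overrides applied."""
    return AtrophySpec(**overrides)


def generate_region_volumes(cohort: pd.DataFrame, spec: AtrophySpec,
                            seed: int = 0,
                            apply_head_size: bool = True) -> pd.DataFrame:
    """Per-subject regional volumes under the linear atrophy model.

    The model operates on head-size-normalized volumes; when
    ``apply_head_size`` is set (the default) the returned "measured" volumes
    are multiplied by the cohort's ``head_size`` column, which the analysis
    divides out again.  Case rows use the ground-truth duration when
    available so the planted acceleration is exact.
    """
    rng = np.random.default_rng(seed)
    age = cohort["age"].astype(float).to_numpy()
    case = cohort["t2dm"].astype(float).to_numpy() == 1.0
    dur_col = "duration_true" if "duration_true" in cohort.columns else "duration"
    dur = np.nan_to_num(cohort[dur_col].astype(float).to_numpy(), nan=0.0)

    n = len(cohort)
    offsets = spec.t2dm_offsets
    vols = (spec.base_volumes[None, :]
            + np.outer(age - AGE_REF, spec.age_slopes)
            + np.outer(case.astype(float), offsets)
            + np.outer(case * dur, spec.acceleration * spec.age_slopes))
    if np.any(spec.noise_sd > 0):
        vols = vols + rng.normal(0.0, 1.0, size=(n, 45)) * spec.noise_sd[None, :]
    if apply_head_size and "head_size" in cohort.columns:
        vols = vols * cohort["head_size"].astype(float).to_numpy()[:, None]
    out = pd.DataFrame(vols, columns=spec.region_names, index=cohort.index)
    out.insert(0, "id", cohort["id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# cognitive scores


@dataclass
class DomainSpec:
    """Generative parameters of one cognitive-domain score."""

    intercept: float = 100.0     # score at age 50, healthy
    age_slope: float = -1.0      # score units per year
    t2dm_offset: float = 0.0     # additive case effect, score units
    noise_sd: float = 15.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def default_domain_specs() -> dict[str, DomainSpec]:
    """Five cognitive domains with planted case deficits.

    Offsets are sized so that, against the healthy-control mean of a uniform
    50-80 cohort (mean age 65), the percent deficits are roughly -13.1%
    (executive function), -6.7% (processing speed), -3.7% (numeric memory),
    -2% (abstract reasoning) and -1% (reaction time).  All synthetic scores
    are oriented higher = better.
    """
    def offset(pct, intercept, slope):
        return pct / 100.0 * (intercept + slope * 15.0)

    return {
        "executive_function": DomainSpec(100.0, -1.0, offset(-13.1, 100, -1.0), 20.0, 0.10),
        "processing_speed": DomainSpec(100.0, -0.8, offset(-6.7, 100, -0.8), 15.0, 0.10),
        "numeric_memory": DomainSpec(100.0, -0.5, offset(-3.7, 100, -0.5), 15.0, 0.15),
        "abstract_reasoning": DomainSpec(100.0, -0.6, offset(-2.0, 100, -0.6), 15.0, 0.05),
        "reaction_time": DomainSpec(100.0, -0.7, offset(-1.0, 100, -0.7), 15.0, 0.05),
    }


def generate_cognitive_scores(cohort: pd.DataFrame,
                              domain_specs: dict[str, DomainSpec] | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Per-domain cognitive scores, linear in age with an additive case offset.

    Missing scores are NaN (never zero); the per-domain missingness emulates
    the varying completion rates of cognitive batteries.
    """
    specs = default_domain_specs() if domain_specs is None else domain_specs
    for name, ds in specs.items():
        if not isinstance(ds, DomainSpec):
            raise TypeError(f"unknown domain spec for {name!r}")
    rng = np.random.default_rng(seed)
    age = cohort["age"].astype(float).to_numpy()
    case = cohort["t2dm"].astype(float).to_numpy()
    out = pd.DataFrame({"id": cohort["id"].to_numpy()}, index=cohort.index)
    for name, ds in specs.items():
        score = (ds.intercept + ds.age_slope * (age - AGE_REF)
                 + ds.t2dm_offset * case)
        if ds.noise_sd > 0:
            score = score + rng.normal(0.0, ds.noise_sd, size=len(cohort))
        if ds.missing_rate > 0:
            score = np.where(rng.random(len(cohort)) < ds.missing_rate,
                             np.nan, score)
        out[name] = score
    return out


# ---------------------------------------------------------------------------
# fMRI


@dataclass
class FmriSpec:
    """Band-limited synthetic BOLD with cluster-localized amplitude effects.

    ``cluster_definitions`` is a list of ``(voxel_index_array, multipliers)``
    where the (k, 3) integer array addresses voxels of the grid and
    ``multipliers`` maps group label -> amplitude multiplier for subjects of
    that group (groups absent from the mapping keep multiplier 1).
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_timepoints: int = 200
    tr: float = 1.0
    band: tuple[float, float] = (0.01, 0.08)
    cluster_definitions: list[tuple[np.ndarray, dict]] = field(default_factory=list)
    noise_sd: float = 1.0
    base_amplitude: float = 1.0
    n_sinusoids: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.n_timepoints < 16:
            raise ValueError("need at least 16 timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        nyq = 0.5 / self.tr
        if not 0.0 < self.band[0] <= self.band[1] < nyq:
            raise ValueError(f"band must lie within (0, Nyquist={nyq:g})")
        for vox, _ in self.cluster_definitions:
            vox = np.asarray(vox)
            if vox.ndim != 2 or vox.shape[1] != 3:
                raise ValueError("cluster voxels must be a (k, 3) index array")
            if np.any(vox < 0) or np.any(vox >= np.array(self.grid_shape)):
                raise ValueError("cluster voxels fall outside the grid")


def generate_fmri(spec: FmriSpec, group_assignment) -> list[VoxelTimeSeries]:
    """One 4D acquisition per subject in ``group_assignment``.

    Every voxel carries a sum of in-band sinusoids (frequencies shared within
    a subject, phases independent per voxel) plus white noise; voxels inside
    a cluster definition have their sinusoid amplitude scaled by the
    subject's group multiplier.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    groups = list(group_assignment)
    shape = tuple(spec.grid_shape)
    n_vox = int(np.prod(shape))
    t = np.arange(spec.n_timepoints) * spec.tr
    mask = np.ones(shape, dtype=bool)

    out = []
    for g in groups:
        amp = np.full(n_vox, spec.base_amplitude)
        for vox, multipliers in spec.cluster_definitions:
            vox = np.asarray(vox)
            flat = np.ravel_multi_index(tuple(vox.T), shape)
            amp[flat] *= float(multipliers.get(g, 1.0))
        freqs = rng.uniform(spec.band[0], spec.band[1], size=spec.n_sinusoids)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_vox, spec.n_sinusoids))
        signal = np.zeros((n_vox, spec.n_timepoints))
        for j in range(spec.n_sinusoids):
            signal += np.sin(2.0 * np.pi * freqs[j] * t[None, :] + phases[:, j:j + 1])
        signal *= amp[:, None] / np.sqrt(spec.n_sinusoids)
        if spec.noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd,
                                         size=(n_vox, spec.n_timepoints))
        data = signal.reshape(*shape, spec.n_timepoints)
        out.append(VoxelTimeSeries(data=data, tr=spec.tr, mask=mask.copy()))
    return out
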