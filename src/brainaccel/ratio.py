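"""Effect-map overlap and the Fieller-interval brain-aging acceleration ratio.

Two questions about shared topography and tempo:

* *Overlap* — do diabetes-related and age-related effects hit the same
  regions?  Measured as the bivariate Pearson correlation between two
  per-region (or per-domain) effect vectors, with a two-sided p from the t
  transform on n - 2 degrees of freedom.

* *Acceleration* — how many extra years of "brain aging" does each year of
  disease duration buy?  Within the diabetic arm, whole-brain gray-matter
  volume is regressed jointly on age and time since diagnosis; the
  acceleration factor is the ratio of the duration coefficient to the age
  coefficient.  Its 95% confidence set comes from Fieller's theorem: with
  ``t*`` the two-sided critical value, the set of ratios ``rho`` satisfying

      (b2^2 - t*^2 v22) rho^2 - 2 (b1 b2 - t*^2 v12) rho + (b1^2 - t*^2 v11) <= 0

  where ``b1, b2`` are the duration and age coefficients and ``v`` their
  covariance.  When the denominator is significantly nonzero
  (``b2^2 > t*^2 v22``) this is a bounded interval; otherwise the set is the
  complement of an interval or the whole line and ``bounded`` is False.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class OverlapResult:
    r: float
    p: float
    n: int


@dataclass
class RatioCI:
    """Fieller point estimate and confidence set for a coefficient ratio.

    When ``bounded`` is False the confidence set is not an interval:
    ``exclusive=True`` means the set is everything *outside*
    ``(ci_low, ci_high)``; ``exclusive=False`` with infinite bounds means the
    whole real line (the data carry no information about the ratio at this
    confidence level).
    """

    ratio: float
    ci_low: float
    ci_high: float
    bounded: bool
    level: float = 0.95
    exclusive: bool = False

    @property
    def half_width(self) -> float:
        """Half-width of a bounded interval (the "+/-" form of a report)."""
        if not self.bounded:
            return float("inf")
        return 0.5 * (self.ci_high - self.ci_low)


def overlap_correlation(map_a, map_b, field: str = "beta") -> OverlapResult:
    """Pearson overlap between two effect maps over shared named entries.

    Accepts the effect-map DataFrames produced by
    :func:`brainaccel.effects.regional_effect_map` (the ``field`` column is
    correlated), plain Series, or dicts keyed by region/domain name.  The
    correlation is computed over entries present and non-missing in both.
    """
    a = _as_series(map_a, field)
    b = _as_series(map_b, field)
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 shared non-missing entries, have {n}")
    if joined["a"].nunique() == 1 or joined["b"].nunique() == 1:
        raise ValueError("zero variance in one of the effect vectors")
    res = stats.pearsonr(joined["a"], joined["b"])
    return OverlapResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def _as_series(m, field: str) -> pd.Series:
    if isinstance(m, pd.DataFrame):
        return m[field].astype(float)
    if isinstance(m, pd.Series):
        return m.astype(float)
    return pd.Series(m, dtype=float)


def fieller_ratio_ci(b1: float, b2: float, v11: float, v22: float, v12: float,
                     df: int | float, level: float = 0.95) -> RatioCI:
    """Fieller confidence set for ``b1 / b2`` from a joint Gaussian fit.

    ``v11, v22, v12`` are the (co)variances of the two estimates and ``df``
    the residual degrees of freedom of the model they came from (t critical
    values; effectively normal above a few hundred df).  With all variances
    zero the set degenerates to the point ratio.
    """
    if v11 < 0 or v22 < 0:
        raise ValueError("variances must be nonnegative")
    if abs(v12) > np.sqrt(v11 * v22) * (1 + 1e-12):
        raise ValueError("covariance inconsistent with the variances")
    if df < 1:
        raise ValueError("df must be >= 1")
    if b2 == 0 and v22 == 0:
        raise ZeroDivisionError("denominator is exactly zero with no uncertainty")

    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    t2 = tcrit * tcrit
    ratio = b1 / b2

    a = b2 * b2 - t2 * v22
    bq = -2.0 * (b1 * b2 - t2 * v12)
    c = b1 * b1 - t2 * v11

    if a == 0 and bq == 0:
        # quadratic degenerates to the constant c
        return RatioCI(ratio=ratio, ci_low=-np.inf, ci_high=np.inf,
                       bounded=False, level=level, exclusive=c > 0)

    if a == 0:
        # linear boundary: one-sided unbounded set
        root = -c / bq
        lo, hi = (root, np.inf) if bq < 0 else (-np.inf, root)
        return RatioCI(ratio=ratio, ci_low=lo, ci_high=hi, bounded=False, level=level)

    disc = bq * bq - 4.0 * a * c
    if disc < 0:
        # no real boundary: the set is empty (a > 0) or the whole line (a < 0)
        return RatioCI(ratio=ratio, ci_low=-np.inf, ci_high=np.inf,
                       bounded=False, level=level, exclusive=a > 0)
    sq = np.sqrt(disc)
    r1 = (-bq - sq) / (2.0 * a)
    r2 = (-bq + sq) / (2.0 * a)
    lo, hi = min(r1, r2), max(r1, r2)
    if a > 0:
        return RatioCI(ratio=ratio, ci_low=lo, ci_high=hi, bounded=True, level=level)
    # a < 0: inequality holds outside (lo, hi) - the exclusive unbounded set
    return RatioCI(ratio=ratio, ci_low=lo, ci_high=hi, bounded=False,
                   level=level, exclusive=True)


def delta_ratio_ci(b1: float, b2: float, v11: float, v22: float, v12: float,
                   df: int | float, level: float = 0.95) -> RatioCI:
    """First-order delta-method interval for ``b1 / b2`` (comparison baseline).

    Agrees with the Fieller set when the denominator is many standard errors
    from zero; unlike Fieller it is always a bounded interval.
    """
    if b2 == 0:
        raise ZeroDivisionError("delta method undefined at b2 = 0")
    ratio = b1 / b2
    var = (v11 + ratio * ratio * v22 - 2.0 * ratio * v12) / (b2 * b2)
    half = stats.t.ppf(0.5 + level / 2.0, df) * np.sqrt(max(var, 0.0))
    return RatioCI(ratio=ratio, ci_low=ratio - half, ci_high=ratio + half,
                   bounded=True, level=level)


def acceleration_estimate(cohort: pd.DataFrame, whole_brain_volume,
                          level: float = 0.95,
                          duration_col: str = "duration",
                          age_col: str = "age") -> RatioCI:
    """Brain-aging acceleration per year of diabetes duration.

    Fits one joint OLS model ``volume ~ 1 + duration + age`` within the
    diabetic subjects of ``cohort`` (both coefficients and their covariance
    come from the same fit, so the Fieller set uses a proper v12) and returns
    the Fieller confidence set for the duration/age coefficient ratio.
    Multiplied by 100 this is the "percent of a year of brain aging per year
    of disease" form.
    """
    t2dm = cohort[cohort["t2dm"].astype(float) == 1.0]
    y = np.asarray(whole_brain_volume, dtype=float)
    if len(y) == len(cohort):
        y = y[(cohort["t2dm"].astype(float) == 1.0).to_numpy()]
    if len(y) != len(t2dm):
        raise ValueError("volume vector does not align with the cohort")
    dur = t2dm[duration_col].astype(float).to_numpy()
    age = t2dm[age_col].astype(float).to_numpy()
    keep = ~(np.isnan(y) | np.isnan(dur) | np.isnan(age))
    y, dur, age = y[keep], dur[keep], age[keep]
    X = np.column_stack([np.ones_like(age), dur, age])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("duration is collinear with age in this sample; "
                         "the ratio of their coefficients is not identified")
    fit = sm.OLS(y, X).fit()
    cov = fit.cov_params()
    return fieller_ratio_ci(b1=float(fit.params[1]), b2=float(fit.params[2]),
                            v11=float(cov[1, 1]), v22=float(cov[2, 2]),
                            v12=float(cov[1, 2]), df=float(fit.df_resid),
                            level=level)
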