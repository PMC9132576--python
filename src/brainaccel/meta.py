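"""Random-effects meta-analysis of standardized mean differences per domain.

Per study and cognitive domain, group summaries (mean, SD, N of the diabetic
and control groups) are converted to Cohen's d with the pooled-SD convention
and the usual large-sample variance.  Per domain, studies are pooled under a
random-effects model: weights ``1 / (v_i + tau^2)`` with the between-study
variance ``tau^2`` estimated by REML (default) or DerSimonian-Laird.
Heterogeneity is summarized by Cochran's Q (computed with fixed-effect
weights) and ``I^2 = max(0, (Q - (k-1)) / Q) * 100``.  Domain-level p-values
are Bonferroni-corrected across domains.

Sign convention: after direction harmonization (domains where a *lower*
score means better performance, such as reaction times, are flipped),
negative d means worse performance in the diabetic group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effects import bonferroni

STUDY_COLUMNS = ["study_id", "domain", "m_t2dm", "sd_t2dm", "n_t2dm",
                 "m_hc", "sd_hc", "n_hc", "direction"]


@dataclass
class StudySummary:
    """One study's group summaries for one cognitive domain.

    ``direction`` is ``+1`` when a higher score means better performance and
    ``-1`` when lower is better (e.g. reaction time, error counts).
    """

    study_id: str
    domain: str
    m_t2dm: float
    sd_t2dm: float
    n_t2dm: int
    m_hc: float
    sd_hc: float
    n_hc: int
    direction: int = 1

    def __post_init__(self) -> None:
        if self.sd_t2dm <= 0 or self.sd_hc <= 0:
            raise ValueError("group SDs must be positive")
        if self.n_t2dm < 2 or self.n_hc < 2:
            raise ValueError("group sizes must be at least 2")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 (higher=better) or -1")


@dataclass
class MetaResult:
    domain: str
    k: int
    d_pooled: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    i2: float
    p: float
    p_bonferroni: float = float("nan")


def cohens_d(summary: StudySummary) -> tuple[float, float]:
    """Cohen's d (pooled-SD) and its variance for one study.

    d = direction * (m_t2dm - m_hc) / s_pooled with
    s_pooled = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2));
    var(d) = (n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)).  After harmonization,
    negative d means the diabetic group performed worse.
    """
    n1, n2 = summary.n_t2dm, summary.n_hc
    pooled_var = (((n1 - 1) * summary.sd_t2dm ** 2 + (n2 - 1) * summary.sd_hc ** 2)
                  / (n1 + n2 - 2))
    if pooled_var == 0:
        raise ZeroDivisionError("pooled SD is zero")
    d = summary.direction * (summary.m_t2dm - summary.m_hc) / np.sqrt(pooled_var)
    var = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    return float(d), float(var)


def hedges_g(summary: StudySummary) -> tuple[float, float]:
    """Small-sample corrected SMD (Hedges' g), offered as an option."""
    d, var = cohens_d(summary)
    m = summary.n_t2dm + summary.n_hc - 2
    j = 1.0 - 3.0 / (4.0 * m - 1.0)
    return d * j, var * j * j


def _tau2_dl(d: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    q = float(np.sum(w * (d - np.sum(w * d) / np.sum(w)) ** 2))
    c = float(np.sum(w) - np.sum(w * w) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - (len(d) - 1)) / c)


def _tau2_reml(d: np.ndarray, v: np.ndarray) -> float:
    """Restricted maximum-likelihood tau^2 by bounded 1D optimization."""

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * d) / np.sum(w)
        return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                      + np.sum(w * (d - mu) ** 2))

    hi = max(_tau2_dl(d, v) * 5.0, float(np.var(d)) * 5.0, 1e-3)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, hi),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    tau2 = float(res.x)
    # snap to the boundary when the optimum sits against zero
    if neg_restricted_ll(0.0) <= res.fun + 1e-12:
        tau2 = 0.0
    return tau2


def random_effects_pool(effects, variances=None, method: str = "reml",
                        domain: str = "") -> MetaResult:
    """Pool per-study SMDs under a random-effects model.

    ``effects`` is either a sequence of (d, variance) pairs or a vector of d
    with ``variances`` given separately.  ``method`` selects the tau^2
    estimator: ``"reml"`` (default) or ``"dl"`` (DerSimonian-Laird).  The
    95% CI is normal-based on the pooled estimate; Q uses fixed-effect
    weights regardless of method.
    """
    if variances is None:
        pairs = np.asarray(list(effects), dtype=float)
        d, v = pairs[:, 0], pairs[:, 1]
    else:
        d = np.asarray(effects, dtype=float)
        v = np.asarray(variances, dtype=float)
    k = len(d)
    if k < 2:
        raise ValueError("random-effects pooling needs at least 2 studies")
    if np.any(v <= 0):
        raise ValueError("study variances must be positive")

    w_fixed = 1.0 / v
    d_fixed = float(np.sum(w_fixed * d) / np.sum(w_fixed))
    q = float(np.sum(w_fixed * (d - d_fixed) ** 2))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0

    if method == "dl":
        tau2 = _tau2_dl(d, v)
    elif method == "reml":
        tau2 = _tau2_reml(d, v)
    else:
        raise ValueError(f"unknown tau^2 method {method!r}")

    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * d) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = stats.norm.ppf(0.975) * se
    return MetaResult(domain=domain, k=k, d_pooled=pooled,
                      ci_low=pooled - half, ci_high=pooled + half,
                      tau2=float(tau2), q=q, i2=float(i2), p=p)


def pool_domains(studies: pd.DataFrame, method: str = "reml",
                 average_within_study: bool = True,
                 hedges: bool = False) -> pd.DataFrame:
    """Per-domain random-effects pooling with Bonferroni across domains.

    ``studies`` carries the :data:`STUDY_COLUMNS`.  When a study contributes
    several tests to one domain its effects are averaged within study first
    (``average_within_study=True``, the default) so no study is double
    counted.  Domains with a single study are reported with missing pooled
    statistics and a warning.  Returns one row per domain.
    """
    esize = hedges_g if hedges else cohens_d
    rows = []
    for domain, grp in studies.groupby("domain", sort=True):
        per_study = []
        for study_id, sgrp in grp.groupby("study_id", sort=True):
            dvs = [esize(StudySummary(**{c: r[c] for c in STUDY_COLUMNS}))
                   for _, r in sgrp.iterrows()]
            if average_within_study:
                dd = float(np.mean([d for d, _ in dvs]))
                vv = float(np.mean([v for _, v in dvs]) / len(dvs))
                per_study.append((dd, vv))
            else:
                per_study.extend(dvs)
        if len(per_study) < 2:
            warnings.warn(f"domain {domain!r} has a single study; not pooled",
                          stacklevel=2)
            d0, v0 = per_study[0]
            rows.append(MetaResult(domain=domain, k=1, d_pooled=np.nan,
                                   ci_low=np.nan, ci_high=np.nan, tau2=np.nan,
                                   q=np.nan, i2=np.nan, p=np.nan))
            continue
        rows.append(random_effects_pool(per_study, method=method, domain=domain))
    out = pd.DataFrame([vars(r) for r in rows])
    pooled_mask = out["p"].notna()
    m = int(pooled_mask.sum())
    out.loc[pooled_mask, "p_bonferroni"] = bonferroni(
        out.loc[pooled_mask, "p"].to_numpy(), m)
    return out


def funnel_data(effects, variances=None, pooled: float | None = None,
                level: float = 0.95) -> dict[str, pd.DataFrame]:
    """Per-study (d, SE) points plus the pseudo confidence funnel boundary.

    The funnel apex sits at the pooled estimate at SE = 0; the boundary at a
    given SE is ``pooled +/- z* SE``.  Returns ``{"points": ..., "boundary":
    ...}`` DataFrames ready for plotting or export; in a symmetric,
    bias-free literature the points scatter evenly inside the funnel.
    """
    if variances is None:
        pairs = np.asarray(list(effects), dtype=float)
        d, v = pairs[:, 0], pairs[:, 1]
    else:
        d = np.asarray(effects, dtype=float)
        v = np.asarray(variances, dtype=float)
    se = np.sqrt(v)
    if pooled is None:
        if len(d) >= 2:
            pooled = random_effects_pool(d, v).d_pooled
        else:
            pooled = float(d[0])
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    se_grid = np.linspace(0.0, max(se.max() * 1.1, 1e-12), 50)
    points = pd.DataFrame({"d": d, "se": se})
    boundary = pd.DataFrame({"se": se_grid,
                             "lower": pooled - zcrit * se_grid,
                             "upper": pooled + zcrit * se_grid})
    return {"points": points, "boundary": boundary}
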