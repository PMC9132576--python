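"""Linear-model effect estimation on cognitive and regional-volume outcomes.

A factor effect (diabetes status, age, disease duration, metformin) is the
OLS coefficient of that factor on the outcome, with an intercept and optional
covariates, a two-sided t test and a t-based 95% confidence interval.  For
interpretability, effects are also expressed as percent of the matched
healthy-control mean outcome: ``100 * beta / hc_mean``, with the CI bounds
scaled identically.  Regional gray-matter maps are fitted per region on
head-size-normalized volumes across exactly 45 bilateral regions and carry a
Bonferroni-adjusted p (m = 45).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

N_REGIONS = 45


@dataclass
class EffectEstimate:
    """One factor's OLS coefficient with its inference."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    n: int
    factor: str
    covariates: tuple[str, ...] = ()
    n_dropped_missing: int = 0


@dataclass
class PercentEffect:
    """An effect rescaled to percent of the healthy-control mean outcome."""

    percent: float
    percent_ci_low: float
    percent_ci_high: float
    hc_mean: float


def fit_effect(outcome, cohort: pd.DataFrame, factor: str,
               covariates: tuple[str, ...] | list[str] = ()) -> EffectEstimate:
    """OLS fit of ``outcome ~ 1 + factor + covariates``; inference on the factor.

    Rows with a missing outcome or any missing model variable are dropped and
    counted.  Boolean factors are coded 0/1.  A rank-deficient design (for
    instance a constant factor) raises with the offending terms named.
    """
    covariates = tuple(covariates)
    y = np.asarray(outcome, dtype=float)
    cols = {factor: cohort[factor].astype(float).to_numpy()}
    for c in covariates:
        cols[c] = cohort[c].astype(float).to_numpy()
    X = np.column_stack(list(cols.values()))
    keep = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[keep], X[keep]
    n = int(keep.sum())
    if n <= X.shape[1] + 1:
        raise ValueError(f"need more than {X.shape[1] + 1} complete rows, have {n}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = ["const", factor, *covariates]
        bad = [nm for j, nm in enumerate(names)
               if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    j = 1  # the factor is the first regressor after the intercept
    return EffectEstimate(beta=float(fit.params[j]), se=float(fit.bse[j]),
                          ci_low=float(ci[j, 0]), ci_high=float(ci[j, 1]),
                          t=float(fit.tvalues[j]), p=float(fit.pvalues[j]),
                          n=n, factor=factor, covariates=covariates,
                          n_dropped_missing=int((~keep).sum()))


def percent_effect(est: EffectEstimate, hc_mean: float) -> PercentEffect:
    """Express an effect as percent of the healthy-control mean outcome."""
    if hc_mean == 0:
        raise ZeroDivisionError("healthy-control mean is zero; percent effect undefined")
    scale = 100.0 / hc_mean
    lo, hi = est.ci_low * scale, est.ci_high * scale
    return PercentEffect(percent=est.beta * scale,
                         percent_ci_low=min(lo, hi), percent_ci_high=max(lo, hi),
                         hc_mean=hc_mean)


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m); m defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, p * m)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def regional_effect_map(volumes: pd.DataFrame, cohort: pd.DataFrame, factor: str,
                        covariates: tuple[str, ...] | list[str] = (),
                        head_size_col: str = "head_size",
                        hc_mask=None) -> pd.DataFrame:
    """Per-region effect map over the 45 bilateral gray-matter regions.

    ``volumes`` holds one column per region (any non-``id`` column), aligned
    row-wise with ``cohort``.  Each regional volume is divided by the
    subject's head-size scaling factor before fitting, so intracranial-size
    differences do not masquerade as factor effects.  Percent effects are
    computed against the mean normalized volume of the control arm: rows
    flagged by ``hc_mask``, or ``cohort[factor] == 0`` for a binary factor,
    or everyone for a continuous factor such as age.

    Returns a DataFrame indexed by region with columns beta, se, ci_low,
    ci_high, t, p, p_bonferroni, percent, percent_ci_low, percent_ci_high, n.
    """
    regions = [c for c in volumes.columns if c != "id"]
    if len(regions) != N_REGIONS:
        raise ValueError(f"expected {N_REGIONS} region columns, found {len(regions)}")
    if head_size_col not in cohort.columns:
        raise KeyError(f"head-size column {head_size_col!r} missing from cohort")
    if len(volumes) != len(cohort):
        raise ValueError("volumes and cohort must be row-aligned")

    head = cohort[head_size_col].astype(float).to_numpy()
    fac = cohort[factor].astype(float).to_numpy()
    if hc_mask is not None:
        hc = np.asarray(hc_mask, dtype=bool)
    elif set(np.unique(fac[~np.isnan(fac)])) <= {0.0, 1.0}:
        hc = fac == 0.0
    else:
        hc = np.ones(len(cohort), dtype=bool)

    rows = {}
    for region in regions:
        norm_vol = volumes[region].astype(float).to_numpy() / head
        est = fit_effect(norm_vol, cohort, factor, covariates)
        pct = percent_effect(est, float(np.nanmean(norm_vol[hc])))
        rows[region] = {"beta": est.beta, "se": est.se, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "t": est.t, "p": est.p,
                        "percent": pct.percent,
                        "percent_ci_low": pct.percent_ci_low,
                        "percent_ci_high": pct.percent_ci_high,
                        "n": est.n}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy(), N_REGIONS)
    out.attrs["factor"] = factor
    return out[["beta", "se", "ci_low", "ci_high", "t", "p", "p_bonferroni",
                "percent", "percent_ci_low", "percent_ci_high", "n"]]


def coarse_grain_bilateral(volumes: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Sum left/right (or finer) regional volumes into bilateral regions.

    ``mapping`` has columns ``source`` (a column of ``volumes``) and
    ``target`` (the bilateral region it contributes to); targets are summed.
    """
    out = pd.DataFrame(index=volumes.index)
    if "id" in volumes.columns:
        out["id"] = volumes["id"]
    for target, grp in mapping.groupby("target", sort=False):
        srcs = [s for s in grp["source"]]
        missing = [s for s in srcs if s not in volumes.columns]
        if missing:
            raise KeyError(f"mapping sources absent from volume table: {missing}")
        out[target] = volumes[srcs].astype(float).sum(axis=1)
    return out
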