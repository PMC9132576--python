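"""Eligibility rules and derived variables applied to a cohort before matching.

A cohort table is a pandas DataFrame with one row per subject.  Expected
columns (missing values are NaN, never zero):

========================  =====================================================
``id``                    unique subject token
``age``                   years (integer for matching purposes)
``sex``                   ``"F"`` / ``"M"``
``education``             1 = college degree, 0 = none
``sbp``, ``dbp``          systolic / diastolic blood pressure, mmHg
``t2dm``                  1 = type 2 diabetes case, 0 = control
``onset_report_1..3``     self-reported age of diabetes onset at up to three
                          visits, years
``menopause``             1 = reported menopause (females)
``hormone_therapy``       1 = ongoing hormone replacement therapy (females)
``metformin``             1 = taking metformin
``other_t2dm_medication`` 1 = taking any other antidiabetic medication
``bmi``                   kg/m^2
========================  =====================================================

Derived columns added by :func:`derive_fields`: ``hypertension`` (from the
blood-pressure rule), ``onset_age`` (mean of the available onset reports) and
``duration`` (age minus mean reported onset, cases only).

Eligibility, in the order applied (a subject is attributed to the first rule
it fails, so the per-rule exclusion counts plus the retained count always sum
to the input count):

1. females who did not report menopause, or who report ongoing hormone
   therapy, are excluded (menopausal-transition confound);
2. diabetic subjects whose mean self-reported onset age is below 40 years are
   excluded (minimises type 1 diabetes contamination); diabetic subjects with
   no usable onset report at all cannot be checked against the rule and are
   excluded as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ONSET_REPORT_COLUMNS = ["onset_report_1", "onset_report_2", "onset_report_3"]

#: Age (years) below which a self-reported diabetes onset is treated as
#: probable type 1 diabetes; onset exactly at the threshold is eligible.
MIN_ONSET_AGE = 40.0


@dataclass
class ExclusionLog:
    """Per-rule exclusion accounting for one :func:`apply_eligibility` call."""

    n_input: int = 0
    n_retained: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:  # structured text, one rule per line
        lines = [f"input\t{self.n_input}"]
        lines += [f"excluded:{rule}\t{n}" for rule, n in self.counts.items()]
        lines.append(f"retained\t{self.n_retained}")
        return "\n".join(lines)


def label_hypertension(sbp, dbp):
    """Hypertension flag from measured blood pressure.

    True iff systolic > 140 mmHg or diastolic > 90 mmHg (strict inequalities,
    so 140/90 exactly is *not* hypertensive).  Accepts scalars or aligned
    array-likes; a missing measurement yields a missing flag rather than
    False, because absence of evidence must not enter a matching key.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    flag = np.where(np.isnan(sbp) | np.isnan(dbp), np.nan,
                    ((sbp > 140.0) | (dbp > 90.0)).astype(float))
    if flag.ndim == 0:
        return float(flag) if np.isnan(flag) else bool(flag)
    return flag


def average_onset_age(reports) -> float:
    """Arithmetic mean of the available (non-missing) onset reports.

    Reports are averaged across visits to reduce recall error in the
    self-reported age of diagnosis.  All-missing input yields NaN.
    """
    arr = np.asarray(list(reports), dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def derive_fields(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``hypertension``, ``onset_age`` and ``duration`` added.

    ``duration`` (years since diagnosis) is only defined for diabetic subjects
    with at least one onset report; it is clipped below at 0 in case reporting
    noise places the mean onset after the current age.
    """
    out = table.copy()
    out["hypertension"] = label_hypertension(out["sbp"].to_numpy(),
                                             out["dbp"].to_numpy())
    reports = out.reindex(columns=ONSET_REPORT_COLUMNS).to_numpy(dtype=float)
    counts = np.sum(~np.isnan(reports), axis=1)
    with np.errstate(invalid="ignore"):
        onset = np.where(counts > 0, np.nansum(reports, axis=1) / np.maximum(counts, 1),
                         np.nan)
    onset = np.where(out["t2dm"].to_numpy(dtype=float) == 1.0, onset, np.nan)
    out["onset_age"] = onset
    out["duration"] = np.clip(out["age"].to_numpy(dtype=float) - onset, 0.0, None)
    return out


def apply_eligibility(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the pre-matching eligibility rules; returns (subset, log).

    Idempotent: re-applying to its own output excludes nobody.  Derived
    fields are computed on the fly if absent.
    """
    if "onset_age" not in table.columns or "hypertension" not in table.columns:
        table = derive_fields(table)

    log = ExclusionLog(n_input=len(table))
    remaining = table

    female = remaining["sex"].astype(str).str.upper().str.startswith("F")
    menop = remaining.get("menopause")
    hrt = remaining.get("hormone_therapy")
    menop = pd.Series(np.nan, index=remaining.index) if menop is None else menop
    hrt = pd.Series(np.nan, index=remaining.index) if hrt is None else hrt
    fail_menopause = female & ((menop.fillna(0.0) != 1.0) | (hrt.fillna(0.0) == 1.0))
    log.counts["female_premenopausal_or_hrt"] = int(fail_menopause.sum())
    remaining = remaining[~fail_menopause]

    is_case = remaining["t2dm"].fillna(0.0) == 1.0
    fail_onset = is_case & ~(remaining["onset_age"] >= MIN_ONSET_AGE)
    log.counts["t2dm_onset_before_40_or_unknown"] = int(fail_onset.sum())
    remaining = remaining[~fail_onset]

    log.n_retained = len(remaining)
    return remaining.copy(), log
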