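"""Exact and coarse (binned) 1:1 case-control matching.

Cases and controls are paired only within strata defined by the exact keys
(e.g. integer age, sex, education, hypertension status) together with the bin
index of any coarse keys (e.g. age in 5-year bins, disease duration in 3-year
bins for the medication contrast).  Within a stratum, pairing is greedy in
sorted-id order, which attains the maximum 1:1 matching size
``sum over strata of min(#cases, #controls)`` — exact-key compatibility is an
equivalence relation, so no cleverer assignment can do better.  An optional
seed shuffles the within-stratum order instead, for sensitivity analyses.

Bins are half-open intervals ``[origin + j*w, origin + (j+1)*w)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MatchSpec:
    """Which covariates must agree exactly, and which only within a bin.

    ``binned_keys`` entries are ``(column, bin width, bin origin)`` in the
    covariate's native units.
    """

    exact_keys: list[str] = field(default_factory=list)
    binned_keys: list[tuple[str, float, float]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        exact = set(self.exact_keys)
        binned = {k for k, _, _ in self.binned_keys}
        if exact & binned:
            raise ValueError(f"keys listed both exact and binned: {sorted(exact & binned)}")
        for k, w, _ in self.binned_keys:
            if not w > 0:
                raise ValueError(f"bin width for {k!r} must be > 0, got {w}")


@dataclass
class MatchedPairs:
    """Result of a matching run: (case id, control id) pairs plus bookkeeping."""

    pairs: list[tuple[str, str]]
    unmatched_cases: list[str]
    n_cases_dropped_missing_key: int = 0
    n_controls_dropped_missing_key: int = 0

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [h for _, h in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id"])


def bin_index(value: float, width: float, origin: float = 0.0) -> int:
    """Index of the half-open bin [origin + j*w, origin + (j+1)*w) holding value."""
    return math.floor((value - origin) / width)


def _stratum_keys(table: pd.DataFrame, spec: MatchSpec) -> tuple[pd.Series, pd.Series]:
    """Per-row stratum label; second return flags rows with a missing key."""
    for key in spec.exact_keys + [k for k, _, _ in spec.binned_keys]:
        if key not in table.columns:
            raise KeyError(f"unknown matching key {key!r}")
    parts = []
    for key in spec.exact_keys:
        col = table[key]
        # integer-valued floats (ages, flags) compare reliably as integers
        if pd.api.types.is_float_dtype(col) or pd.api.types.is_bool_dtype(col):
            col = col.astype(float)
        parts.append(col)
    for key, width, origin in spec.binned_keys:
        vals = table[key].astype(float)
        parts.append(np.floor((vals - origin) / width))
    missing = pd.Series(False, index=table.index)
    for p in parts:
        missing |= pd.isna(pd.Series(np.asarray(p), index=table.index))
    labels = pd.Series(list(zip(*[np.asarray(p) for p in parts])), index=table.index) \
        if parts else pd.Series([()] * len(table), index=table.index)
    return labels, missing


def match(cases: pd.DataFrame, controls: pd.DataFrame, spec: MatchSpec) -> MatchedPairs:
    """Maximal 1:1 matching of cases to controls within exact/binned strata.

    Subjects with a missing value in any key are dropped (and counted) rather
    than treated as matchable on the missing value.  The result is invariant
    under permutation of input row order because pairing follows sorted ids.
    """
    case_strata, case_missing = _stratum_keys(cases, spec)
    ctrl_strata, ctrl_missing = _stratum_keys(controls, spec)

    n_case_dropped = int(case_missing.sum())
    n_ctrl_dropped = int(ctrl_missing.sum())

    case_tbl = pd.DataFrame({"id": cases.loc[~case_missing, "id"].astype(str),
                             "stratum": case_strata[~case_missing]})
    ctrl_tbl = pd.DataFrame({"id": controls.loc[~ctrl_missing, "id"].astype(str),
                             "stratum": ctrl_strata[~ctrl_missing]})

    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None

    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    ctrl_groups = {s: sorted(g["id"]) for s, g in ctrl_tbl.groupby("stratum", sort=False)}
    for stratum, group in sorted(case_tbl.groupby("stratum", sort=False),
                                 key=lambda kv: repr(kv[0])):
        case_ids = sorted(group["id"])
        ctrl_ids = ctrl_groups.get(stratum, [])
        if rng is not None:
            rng.shuffle(case_ids)
            ctrl_ids = list(ctrl_ids)
            rng.shuffle(ctrl_ids)
        k = min(len(case_ids), len(ctrl_ids))
        pairs.extend(zip(case_ids[:k], ctrl_ids[:k]))
        unmatched.extend(case_ids[k:])
    return MatchedPairs(pairs=pairs, unmatched_cases=sorted(unmatched),
                        n_cases_dropped_missing_key=n_case_dropped,
                        n_controls_dropped_missing_key=n_ctrl_dropped)


def balance_report(pairs: MatchedPairs, cases: pd.DataFrame, controls: pd.DataFrame,
                   spec: MatchSpec) -> pd.DataFrame:
    """Covariate distributions of the two matched arms, one row per key level.

    Exact keys must come out with identical case/control frequencies; binned
    keys agree at the bin level (within-pair absolute difference bounded by
    the bin width).
    """
    if not pairs.pairs:
        return pd.DataFrame(columns=["key", "level", "n_cases", "n_controls"])
    case_rows = cases.set_index(cases["id"].astype(str)).loc[pairs.case_ids]
    ctrl_rows = controls.set_index(controls["id"].astype(str)).loc[pairs.control_ids]
    records = []
    keys = list(spec.exact_keys) + [k for k, _, _ in spec.binned_keys]
    for key in keys:
        binned = next(((w, o) for k, w, o in spec.binned_keys if k == key), None)
        cvals = case_rows[key]
        hvals = ctrl_rows[key]
        if binned is not None:
            w, o = binned
            cvals = np.floor((cvals.astype(float) - o) / w)
            hvals = np.floor((hvals.astype(float) - o) / w)
        cfreq = pd.Series(cvals).value_counts()
        hfreq = pd.Series(hvals).value_counts()
        for level in sorted(set(cfreq.index) | set(hfreq.index)):
            records.append({"key": key, "level": level,
                            "n_cases": int(cfreq.get(level, 0)),
                            "n_controls": int(hfreq.get(level, 0))})
    return pd.DataFrame.from_records(records)


def medication_arms(t2dm_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a diabetic cohort into the medication-contrast arms.

    Returns (metformin-only, unmedicated): metformin-only subjects take
    metformin and no other antidiabetic medication; unmedicated subjects take
    neither.  Subjects on other medication (with or without metformin) belong
    to neither arm.
    """
    met = t2dm_table["metformin"].fillna(0.0) == 1.0
    other = t2dm_table["other_t2dm_medication"].fillna(0.0) == 1.0
    return t2dm_table[met & ~other].copy(), t2dm_table[~met & ~other].copy()
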