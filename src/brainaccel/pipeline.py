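"""Stage runner binding the library into the three cohort analyses plus meta.

Each stage reads its inputs (from the run directory or paths named in the
config), writes new files into the run directory — inputs are never mutated —
and appends an entry to ``manifest.json`` recording the stage, the config
hash, the seed, the input paths and the outputs, which is sufficient to
re-run any stage bit-identically.

Configuration is one YAML file with per-stage sections; command-line flags
(see :mod:`brainaccel.cli`) override file values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alff import (VoxelTimeSeries, aggregate_regions, subject_alff,
                   threshold_clusters, voxelwise_group_stats)
from .effects import fit_effect, percent_effect, regional_effect_map
from .filters import apply_eligibility
from .io import read_nifti, read_table, write_nifti, write_table
from .matching import MatchSpec, balance_report, match
from .meta import funnel_data, pool_domains
from .ratio import acceleration_estimate, overlap_correlation
from .synthetic import (AtrophySpec, CohortSpec, FmriSpec, generate_cohort,
                        generate_cognitive_scores, generate_fmri,
                        generate_region_volumes)

STAGES = ("simulate", "filter", "match", "effects", "alff", "overlap",
          "accelerate", "meta", "report")


class ConfigError(ValueError):
    """Invalid or incomplete configuration (exit code 2)."""


class DataError(RuntimeError):
    """Missing or inconsistent input data (exit code 3)."""


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _record(run_dir: Path, stage: str, config: dict, inputs: list[str],
            outputs: list[str]) -> None:
    manifest = run_dir / "manifest.json"
    entries = json.loads(manifest.read_text()) if manifest.exists() else []
    entries.append({"stage": stage, "config_hash": _config_hash(config),
                    "seed": config.get("seed"), "version": __version__,
                    "inputs": inputs, "outputs": outputs})
    manifest.write_text(json.dumps(entries, indent=2))


def _require(path: Path) -> Path:
    if not path.exists():
        raise DataError(f"required input does not exist: {path}")
    return path


def _stage_cfg(config: dict, stage: str) -> dict:
    sub = config.get(stage) or {}
    if not isinstance(sub, dict):
        raise ConfigError(f"config section {stage!r} must be a mapping")
    return sub


def run_subcommand(name: str, config: dict, run_dir: str | Path) -> list[str]:
    """Run one named stage; returns the list of files written."""
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; choose from {STAGES}")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    outputs = _DISPATCH[name](config, run_dir)
    return outputs


# --- stages ----------------------------------------------------------------


def _stage_simulate(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "simulate")
    seed = int(config.get("seed", 0))
    cohort_kwargs = {k: v for k, v in cfg.items()
                     if k in CohortSpec.__dataclass_fields__}
    try:
        cspec = CohortSpec(seed=seed, **{k: v for k, v in cohort_kwargs.items()
                                         if k != "seed"})
        aspec = AtrophySpec(**{k: v for k, v in cfg.items()
                               if k in ("t2dm_offset_scale", "acceleration",
                                        "perturbation_rel", "perturbation_seed")})
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    cohort = generate_cohort(cspec)
    volumes = generate_region_volumes(cohort, aspec, seed=seed + 1)
    scores = generate_cognitive_scores(cohort, seed=seed + 2)
    out = [run_dir / "cohort.csv", run_dir / "volumes.csv", run_dir / "cognition.csv"]
    write_table(cohort, out[0])
    write_table(volumes, out[1])
    write_table(scores, out[2])
    if cfg.get("fmri", False):
        fspec = FmriSpec(seed=seed + 3, **{k: v for k, v in cfg.get("fmri_options", {}).items()
                                           if k in FmriSpec.__dataclass_fields__ and k != "seed"})
        n_per_group = int(cfg.get("fmri_subjects_per_group", 4))
        groups = [0] * n_per_group + [1] * n_per_group
        series = generate_fmri(fspec, groups)
        rows = []
        for i, (vol, g) in enumerate(zip(series, groups)):
            p = run_dir / f"bold_sub{i:03d}.nii.gz"
            write_nifti(vol.data, p, tr=vol.tr)
            rows.append({"subject": f"F{i:03d}", "group": g, "path": str(p)})
            out.append(p)
        series_tbl = run_dir / "fmri_series.csv"
        write_table(pd.DataFrame(rows), series_tbl)
        out.append(series_tbl)
    _record(run_dir, "simulate", config, [], [str(p) for p in out])
    return [str(p) for p in out]


def _stage_filter(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "filter")
    src = _require(Path(cfg.get("cohort", run_dir / "cohort.csv")))
    cohort = read_table(src)
    eligible, log = apply_eligibility(cohort)
    out_tbl = run_dir / "eligible.csv"
    out_log = run_dir / "exclusions.log"
    write_table(eligible, out_tbl)
    out_log.write_text(str(log) + "\n")
    _record(run_dir, "filter", config, [str(src)], [str(out_tbl), str(out_log)])
    return [str(out_tbl), str(out_log)]


def _stage_match(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "match")
    src = _require(Path(cfg.get("cohort", run_dir / "eligible.csv")))
    cohort = read_table(src)
    case_col = cfg.get("case_column", "t2dm")
    try:
        spec = MatchSpec(
            exact_keys=list(cfg.get("exact_keys",
                                    ["age", "sex", "education", "hypertension"])),
            binned_keys=[tuple(b) for b in cfg.get("binned_keys", [])],
            seed=cfg.get("tie_break_seed"))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    cases = cohort[cohort[case_col].astype(float) == 1.0]
    controls = cohort[cohort[case_col].astype(float) == 0.0]
    pairs = match(cases, controls, spec)
    out_pairs = run_dir / "pairs.csv"
    out_balance = run_dir / "balance.csv"
    out_log = run_dir / "matching.log"
    write_table(pairs.to_frame(), out_pairs)
    write_table(balance_report(pairs, cases, controls, spec), out_balance)
    out_log.write_text(
        f"pairs\t{len(pairs.pairs)}\n"
        f"unmatched_cases\t{len(pairs.unmatched_cases)}\n"
        f"cases_dropped_missing_key\t{pairs.n_cases_dropped_missing_key}\n"
        f"controls_dropped_missing_key\t{pairs.n_controls_dropped_missing_key}\n")
    _record(run_dir, "match", config, [str(src)],
            [str(out_pairs), str(out_balance), str(out_log)])
    return [str(out_pairs), str(out_balance), str(out_log)]


def _matched_cohort(run_dir: Path, cfg: dict) -> pd.DataFrame:
    """Eligible cohort restricted to the matched ids, when pairs exist."""
    cohort = read_table(_require(Path(cfg.get("cohort", run_dir / "eligible.csv"))))
    pairs_path = Path(cfg.get("pairs", run_dir / "pairs.csv"))
    if pairs_path.exists():
        pairs = read_table(pairs_path)
        keep = pd.concat([pairs["case_id"], pairs["control_id"]]).astype(str)
        cohort = cohort[cohort["id"].astype(str).isin(set(keep))]
    return cohort.reset_index(drop=True)


def _stage_effects(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "effects")
    factor = cfg.get("factor", "t2dm")
    covariates = list(cfg.get("covariates", []))
    cohort = _matched_cohort(run_dir, cfg)
    outputs = []

    vol_path = Path(cfg.get("volumes", run_dir / "volumes.csv"))
    if vol_path.exists():
        volumes = read_table(vol_path)
        volumes = volumes.set_index(volumes["id"].astype(str))
        volumes = volumes.loc[cohort["id"].astype(str)].reset_index(drop=True)
        emap = regional_effect_map(volumes, cohort, factor, covariates)
        out = run_dir / f"effects_regional_{factor}.csv"
        write_table(emap.reset_index(), out)
        outputs.append(str(out))

    cog_path = Path(cfg.get("cognition", run_dir / "cognition.csv"))
    if cog_path.exists():
        scores = read_table(cog_path)
        scores = scores.set_index(scores["id"].astype(str))
        scores = scores.loc[cohort["id"].astype(str)].reset_index(drop=True)
        fac = cohort[factor].astype(float).to_numpy()
        binary = set(np.unique(fac[~np.isnan(fac)])) <= {0.0, 1.0}
        hc = fac == 0.0 if binary else np.ones(len(cohort), dtype=bool)
        rows = {}
        for domain in [c for c in scores.columns if c != "id"]:
            y = scores[domain].astype(float).to_numpy()
            est = fit_effect(y, cohort, factor, covariates)
            pct = percent_effect(est, float(np.nanmean(y[hc])))
            rows[domain] = {"beta": est.beta, "se": est.se,
                            "ci_low": est.ci_low, "ci_high": est.ci_high,
                            "t": est.t, "p": est.p, "percent": pct.percent,
                            "percent_ci_low": pct.percent_ci_low,
                            "percent_ci_high": pct.percent_ci_high, "n": est.n}
        dmap = pd.DataFrame.from_dict(rows, orient="index")
        dmap.index.name = "domain"
        from .effects import bonferroni
        dmap["p_bonferroni"] = bonferroni(dmap["p"].to_numpy(), len(dmap))
        out = run_dir / f"effects_cognitive_{factor}.csv"
        write_table(dmap.reset_index(), out)
        outputs.append(str(out))

    if not outputs:
        raise DataError("effects stage found neither a volume nor a cognition table")
    _record(run_dir, "effects", config, [str(vol_path), str(cog_path)], outputs)
    return outputs


def _stage_alff(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "alff")
    series_tbl = _require(Path(cfg.get("series_table", run_dir / "fmri_series.csv")))
    table = read_table(series_tbl)
    band = tuple(cfg.get("band", (0.01, 0.08)))
    fwhm = float(cfg.get("fwhm", 5.0))
    q = float(cfg.get("fdr_q", 0.05))
    min_size = int(cfg.get("min_cluster_voxels", 12))
    smooth_first = bool(cfg.get("smooth_first", True))
    if not 0 < q < 1:
        raise ConfigError(f"fdr_q must lie in (0,1), got {q}")

    mask = None
    if cfg.get("mask"):
        mask, _ = read_nifti(_require(Path(cfg["mask"])))
        mask = mask > 0.5
    maps, groups = [], []
    for _, row in table.iterrows():
        data, zooms = read_nifti(_require(Path(row["path"])))
        tr = zooms[3] if len(zooms) > 3 else float(cfg.get("tr", 1.0))
        m = mask if mask is not None else np.ones(data.shape[:3], dtype=bool)
        vol = VoxelTimeSeries(data=data, tr=tr, mask=m,
                              voxel_size=tuple(zooms[:3]))
        maps.append(subject_alff(vol, band=band, fwhm=fwhm,
                                 smooth_first=smooth_first))
        groups.append(float(row["group"]))
    z = voxelwise_group_stats(maps, np.asarray(groups))
    clusters = threshold_clusters(z, q=q, min_size=min_size)
    out_z = run_dir / "zmap.nii.gz"
    out_cl = run_dir / "clusters.csv"
    write_nifti(np.nan_to_num(z), out_z)
    write_table(clusters.to_frame(), out_cl)
    outputs = [str(out_z), str(out_cl)]
    if cfg.get("region_labels"):
        labels, _ = read_nifti(_require(Path(cfg["region_labels"])))
        regional = aggregate_regions(z, labels.astype(int))
        out_reg = run_dir / "zmap_regional.csv"
        write_table(regional.rename("z").reset_index(), out_reg)
        outputs.append(str(out_reg))
    _record(run_dir, "alff", config, [str(series_tbl)], outputs)
    return outputs


def _stage_overlap(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "overlap")
    try:
        path_a = _require(Path(cfg["map_a"]))
        path_b = _require(Path(cfg["map_b"]))
    except KeyError as exc:
        raise ConfigError(f"overlap stage needs map_a and map_b: {exc}") from exc
    field = cfg.get("field", "beta")
    index_col = cfg.get("index_column", "region")
    map_a = read_table(path_a).set_index(index_col)
    map_b = read_table(path_b).set_index(index_col)
    res = overlap_correlation(map_a, map_b, field=field)
    out = run_dir / "overlap.csv"
    write_table(pd.DataFrame([{"r": res.r, "p": res.p, "n": res.n,
                               "field": field}]), out)
    _record(run_dir, "overlap", config, [str(path_a), str(path_b)], [str(out)])
    return [str(out)]


def _stage_accelerate(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "accelerate")
    cohort = _matched_cohort(run_dir, cfg)
    volumes = read_table(_require(Path(cfg.get("volumes", run_dir / "volumes.csv"))))
    volumes = volumes.set_index(volumes["id"].astype(str))
    volumes = volumes.loc[cohort["id"].astype(str)].reset_index(drop=True)
    region_cols = [c for c in volumes.columns if c != "id"]
    whole = volumes[region_cols].astype(float).sum(axis=1).to_numpy()
    if "head_size" in cohort.columns:
        whole = whole / cohort["head_size"].astype(float).to_numpy()
    try:
        res = acceleration_estimate(cohort, whole,
                                    level=float(cfg.get("level", 0.95)))
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    out = run_dir / "acceleration.csv"
    write_table(pd.DataFrame([{"ratio": res.ratio, "ci_low": res.ci_low,
                               "ci_high": res.ci_high, "bounded": res.bounded,
                               "level": res.level,
                               "percent": 100.0 * res.ratio,
                               "percent_half_width": 100.0 * res.half_width}]),
                out)
    _record(run_dir, "accelerate", config, [], [str(out)])
    return [str(out)]


def _stage_meta(config: dict, run_dir: Path) -> list[str]:
    cfg = _stage_cfg(config, "meta")
    src = _require(Path(cfg.get("studies", run_dir / "studies.csv")))
    studies = read_table(src)
    method = cfg.get("tau2_method", "reml")
    if method not in ("reml", "dl"):
        raise ConfigError(f"tau2_method must be 'reml' or 'dl', got {method!r}")
    results = pool_domains(studies, method=method,
                           average_within_study=bool(
                               cfg.get("average_within_study", True)),
                           hedges=bool(cfg.get("hedges", False)))
    out = run_dir / "meta_results.csv"
    write_table(results, out)
    outputs = [str(out)]
    from .meta import StudySummary, cohens_d  # per-domain funnel exports
    for domain, grp in studies.groupby("domain"):
        dvs = [cohens_d(StudySummary(**{c: r[c] for c in grp.columns
                                        if c in StudySummary.__dataclass_fields__}))
               for _, r in grp.iterrows()]
        if len(dvs) < 2:
            continue
        fd = funnel_data(dvs)
        out_f = run_dir / f"funnel_{domain}.csv"
        write_table(fd["points"], out_f)
        outputs.append(str(out_f))
    _record(run_dir, "meta", config, [str(src)], outputs)
    return outputs


def _stage_report(config: dict, run_dir: Path) -> list[str]:
    manifest = run_dir / "manifest.json"
    if not manifest.exists():
        raise DataError(f"no manifest in {run_dir}; nothing to report")
    entries = json.loads(manifest.read_text())
    lines = [f"run directory: {run_dir}", f"stages run: {len(entries)}"]
    for e in entries:
        lines.append(f"- {e['stage']} (seed={e['seed']}, config={e['config_hash']})")
        for o in e["outputs"]:
            lines.append(f"    {o}")
    out = run_dir / "report.txt"
    out.write_text("\n".join(lines) + "\n")
    _record(run_dir, "report", config, [str(manifest)], [str(out)])
    return [str(out)]


_DISPATCH = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "match": _stage_match,
    "effects": _stage_effects,
    "alff": _stage_alff,
    "overlap": _stage_overlap,
    "accelerate": _stage_accelerate,
    "meta": _stage_meta,
    "report": _stage_report,
}
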