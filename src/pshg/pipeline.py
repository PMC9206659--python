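"""Stage orchestration: simulate -> reconstruct -> features -> stats -> classify.

Each stage writes its artifacts under the configured output directory and
is resumable: a stage whose outputs already exist for the current config
hash is skipped on rerun, so downstream stages can be iterated without
recomputing expensive upstream ones.  The run log records the package
version, seeds, the calibrated R-ratio branch and all drop counters, so
the pixel/tile/row exclusions are auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    CvProtocol,
    fit_logistic_cv,
    predict_held_out,
    select_predictors,
    subset_experiment,
)
from .config import RunConfig, config_hash
from .io import read_parameter_maps, read_stack, write_parameter_maps
from .polarimetry import compute_parameter_maps, reconstruct_stokes, snr_mask
from .stats import significance_matrix
from .synthetic import (
    NoiseModel,
    default_presets,
    generate_dataset,
    icp_background_stats,
    write_dataset,
)
from .texture import build_feature_table, feature_columns

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "reconstruct", "features", "stats", "classify")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _log(out: Path) -> dict:
    p = out / "run_log.json"
    return json.loads(p.read_text()) if p.exists() else {}


def _write_log(out: Path, log: dict) -> None:
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))


def _stage_done(out: Path, stage: str, chash: str) -> bool:
    log = _log(out)
    return log.get("stages", {}).get(stage, {}).get("config_hash") == chash


def _mark_done(out: Path, stage: str, chash: str, info: dict) -> None:
    log = _log(out)
    log.setdefault("version", __version__)
    log.setdefault("stages", {})[stage] = {"config_hash": chash, **info}
    _write_log(out, log)


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested pipeline stages; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    log = _log(out)
    log.update({"config_hash": chash, "seed": cfg.seed, "version": __version__})
    _write_log(out, log)

    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid: {STAGES}")
        if _stage_done(out, stage, chash):
            continue
        try:
            info = _RUNNERS[stage](cfg, out)
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise StageError(stage, exc) from exc
        _mark_done(out, stage, chash, info)
    return out


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    presets = default_presets()
    if cfg.simulate.presets_file:
        import yaml

        from .synthetic import GroupPreset

        raw = yaml.safe_load(Path(cfg.simulate.presets_file).read_text())
        presets = {k: GroupPreset(label=k, **v) for k, v in raw.items()}
    ds = generate_dataset(
        cfg.simulate.n_cores_per_group,
        presets=presets,
        core_size=cfg.simulate.core_size,
        seed=cfg.seed,
    )
    sim_dir = write_dataset(ds, out / "sim")
    return {"n_cores": len(ds.cores), "dir": str(sim_dir)}


def _core_list(cfg: RunConfig, out: Path) -> list[tuple[str, Path, str]]:
    """(core_id, stack path, label) triples from config or the sim stage."""
    if cfg.input_stacks:
        return [(cid, Path(p), lab) for cid, p, lab in cfg.input_stacks]
    manifest = json.loads((out / "sim" / "manifest.json").read_text())
    return [
        (c["core_id"], out / "sim" / f"{c['core_id']}_stack.tif", c["label"])
        for c in manifest["cores"]
    ]


def _noise_model_for(cfg: RunConfig, out: Path) -> NoiseModel:
    sim_manifest = out / "sim" / "manifest.json"
    if sim_manifest.exists() and not cfg.input_stacks:
        manifest = json.loads(sim_manifest.read_text())
        return NoiseModel(**next(iter(manifest["groups"].values()))["noise"])
    raise ValueError(
        "background statistics unavailable: provide simulated input or a "
        "background region via the API"
    )


def _stage_reconstruct(cfg: RunConfig, out: Path) -> dict:
    maps_dir = out / "maps"
    noise = _noise_model_for(cfg, out)
    # dark-subtracted reconstruction: ICP background is zero-mean with
    # SD sigma/sqrt(2) (see synthetic.icp_background_stats)
    bg = (0.0, icp_background_stats(noise)[1])
    qc_all = {}
    for core_id, path, _ in _core_list(cfg, out):
        stack = read_stack(path)
        st = reconstruct_stokes(
            stack,
            sign_s1=cfg.polarimetry.sign_s1,
            sign_s3=cfg.polarimetry.sign_s3,
            dark_offset=noise.background_mean,
        )
        from .polarimetry import compute_icp

        mask = snr_mask(compute_icp(st), bg, cfg.polarimetry.snr_threshold)
        params = compute_parameter_maps(
            st,
            signal_mask=mask,
            branch=cfg.polarimetry.r_branch,
            r_probe=cfg.polarimetry.r_probe,
        )
        write_parameter_maps(params, maps_dir, core_id)
        qc_all[core_id] = params.qc
    (maps_dir / "qc_summary.json").write_text(json.dumps(qc_all, indent=2, sort_keys=True))
    branches = {qc["r_branch"] for qc in qc_all.values()}
    return {"n_cores": len(qc_all), "r_branch": sorted(branches), "background": bg}


def _stage_features(cfg: RunConfig, out: Path) -> dict:
    maps_dir = out / "maps"
    tables = []
    dropped = {}
    for core_id, _, label in _core_list(cfg, out):
        params = read_parameter_maps(maps_dir, core_id)
        t = build_feature_table(
            params,
            core_id,
            label,
            tiles_per_side=cfg.texture.tiles_per_side,
            n_g=cfg.texture.n_g,
            d=cfg.texture.d,
            min_density_frac=cfg.texture.min_density_frac,
            printed_correlation_sign=cfg.texture.printed_correlation_sign,
        )
        dropped[core_id] = t.attrs.get("n_dropped_tiles", 0)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "features.csv", index=False)
    return {"n_rows": len(table), "dropped_tiles": dropped}


def _stage_stats(cfg: RunConfig, out: Path) -> dict:
    table = pd.read_csv(out / "features.csv")
    cols = [c for c in feature_columns() if c in table.columns]
    records, excluded = significance_matrix(
        table,
        cols,
        reference_group=cfg.stats.reference_group,
        trim=(cfg.stats.trim_lo, cfg.stats.trim_hi),
    )
    records.to_csv(out / "significance.csv", index=False)
    (out / "exclusion.json").write_text(json.dumps({"excluded": excluded}, indent=2))
    return {"n_records": len(records), "n_excluded": len(excluded)}


def _stage_classify(cfg: RunConfig, out: Path) -> dict:
    table = pd.read_csv(out / "features.csv")
    excluded = json.loads((out / "exclusion.json").read_text())["excluded"]
    protocol = CvProtocol(
        k_folds=cfg.classify.k_folds,
        repeats=cfg.classify.repeats,
        threshold=cfg.classify.threshold,
        seed=cfg.seed,
        ridge_alpha=cfg.classify.ridge_alpha,
    )
    held_out = list(cfg.classify.held_out_cores)
    train_table = table[~table["core_id"].isin(held_out)] if held_out else table
    cols = select_predictors(train_table, excluded)
    complete = train_table.dropna(subset=cols)
    y = (complete["label"] == cfg.classify.positive_label).astype(int).to_numpy()
    panel, per_repeat = fit_logistic_cv(
        complete[cols].to_numpy(float), y, protocol
    )
    subsets = subset_experiment(
        train_table, protocol, exclude=excluded, positive_label=cfg.classify.positive_label
    )
    result = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_rows": int(len(complete)),
        "n_predictors": len(cols),
        "panel": panel.to_dict(),
        "subsets": {k: v.to_dict() for k, v in subsets.items()},
    }
    if held_out:
        pred = predict_held_out(
            table,
            held_out,
            cols,
            threshold=cfg.classify.threshold,
            positive_label=cfg.classify.positive_label,
            ridge_alpha=cfg.classify.ridge_alpha,
        )
        result["held_out"] = {
            "cores": held_out,
            "metrics": pred["metrics"],
        }
        pred["tiles"].to_csv(out / "predicted_tiles.csv", index=False)
    per_repeat.to_csv(out / "metrics_per_repeat.csv", index=False)
    (out / "metrics.json").write_text(
        json.dumps(result, indent=2, sort_keys=True, default=float)
    )
    return {"n_predictors": len(cols), "n_rows": int(len(complete))}


_RUNNERS = {
    "simulate": _stage_simulate,
    "reconstruct": _stage_reconstruct,
    "features": _stage_features,
    "stats": _stage_stats,
    "classify": _stage_classify,
}
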