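"""End-to-end orchestration of the multi-task NIR study workflow.

Stages: simulate/load -> preprocessing (fixed chain or MCPS selection) ->
2:1:1 partitioning (random test holdout + SPXY) -> feature extraction
(deep network under STL/MTL with Bayesian optimization, VIP wavelength
selection, or raw spectra) -> downstream chemometric models (PLSR or SVR
per regression task, PLS-DA for authentication) -> full metric report.
Every stage writes a JSON/CSV artifact and the run ends with a manifest
recording seeds, timings and artifact hashes.

All randomness flows from one global seed, expanded per stage with a fixed
multiplicative scheme so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .boa_opt import (MTLFitness, TaskWeights, cv_fitness,
                      default_search_space, optimize)
from .chemo_models import fit_plsda, fit_plsr, fit_svr_grid, select_lvs_mccv
from .deep_features import (NetworkConfig, TrainConfig, build_network,
                            count_parameters, extract_features, train_mtl,
                            train_stl)
from .metrics_eval import (classification_metrics, paired_consistency_ttest,
                           regression_metrics)
from .partition import SplitConfig, split_dataset
from .preprocess import (PreprocessMethod, apply_chain, select_preprocessing)
from .spectra_core import (SpectralDataset, read_dataset, subset,
                           write_dataset)
from .synthgen import GeneratorConfig, generate_study
from .vip_select import vip_sweep

_STAGES = ("data", "preprocess", "split", "features", "models", "evaluate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-mappable)."""

    outdir: str = "run"
    seed: int = 0
    input_csv: str | None = None          # None -> simulate the study design
    preprocess: str = "mcps"              # "mcps", "none", or a chain spec
    test_fraction: float = 0.25
    cal_val_ratio: tuple = (2, 1)
    feature_mode: str = "network"         # "network" | "vip" | "raw"
    arch: str = "cnn_lstm_mha"
    strategy: str = "mtl"                 # "stl" | "mtl"
    stl_task: str = "alcohol"             # head trained when strategy=stl
    boa_iters: int = 10
    boa_init: int = 5
    cv_folds: int = 3
    epochs: int = 15
    batch_size: int = 16
    reduced_space: bool = True
    norms: tuple | None = None            # override MTL normalization
    regression_model: str = "svr"         # "svr" | "plsr"
    mccv_splits: int = 30
    svr_cv_folds: int = 5


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 2654435761 + 7919 * stage) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, TaskWeights):
        return obj.as_tuple()
    if isinstance(obj, (NetworkConfig, PreprocessMethod)):
        return asdict(obj)
    return str(obj)


def _dump(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, default=_json_default))


def _point_to_config(arch: str, point: dict) -> tuple[NetworkConfig,
                                                      TaskWeights | None]:
    point = dict(point)
    weights = point.pop("task_weights", None)
    return NetworkConfig(arch=arch, **point), weights


def _norm_floor(value: float, n_cal: int) -> float:
    # CVER can legitimately reach 0 on separable classes; floor each
    # normalization factor at the resolution of one CV miss so WJE stays
    # defined without distorting nonzero norms
    return max(value, 1.0 / n_cal)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": asdict(cfg), "stages": {}}
    timer = {}

    def record(stage: str, artifact: Path) -> None:
        manifest["stages"][stage] = {
            "artifact": artifact.name, "sha256": _sha256(artifact),
            "seconds": round(timer[stage], 3),
            "seed": _stage_seed(cfg.seed, _STAGES.index(stage))}

    # -- stage 1: data ---------------------------------------------------
    t0 = time.perf_counter()
    if cfg.input_csv is None:
        ds = generate_study(GeneratorConfig(seed=_stage_seed(cfg.seed, 0)))
    else:
        ds = read_dataset(cfg.input_csv)
    if cfg.strategy == "mtl" and not ds.has_targets("alcohol", "wort",
                                                    "classify"):
        raise ValueError("mtl requires all three targets")
    data_path = outdir / "data.csv"
    write_dataset(ds, data_path)
    timer["data"] = time.perf_counter() - t0
    record("data", data_path)

    # -- stage 2: preprocessing -------------------------------------------
    t0 = time.perf_counter()
    pp_info: dict = {"mode": cfg.preprocess}
    if cfg.preprocess == "none":
        treated = ds
    elif cfg.preprocess == "mcps":
        method, scores, table = select_preprocessing(
            ds, seed=_stage_seed(cfg.seed, 1))
        treated = apply_chain(ds, method)
        pp_info.update({
            "selected": method.name,
            "mcps": {m.name: float(s)
                     for m, s in zip(table.methods, scores)},
            "errors": table.errors})
    else:
        method = PreprocessMethod.from_spec(cfg.preprocess)
        treated = apply_chain(ds, method)
        pp_info["selected"] = method.name
    pp_path = outdir / "preprocess.json"
    _dump(pp_info, pp_path)
    timer["preprocess"] = time.perf_counter() - t0
    record("preprocess", pp_path)

    # -- stage 3: partitioning --------------------------------------------
    t0 = time.perf_counter()
    split = split_dataset(treated, SplitConfig(
        test_fraction=cfg.test_fraction, cal_val_ratio=cfg.cal_val_ratio,
        seed=_stage_seed(cfg.seed, 2)))
    split_path = outdir / "split.json"
    split.save(split_path)
    timer["split"] = time.perf_counter() - t0
    record("split", split_path)

    ds_cal = subset(treated, split.calibration)

    # -- stage 4: features -------------------------------------------------
    t0 = time.perf_counter()
    feat_seed = _stage_seed(cfg.seed, 3)
    feat_info: dict = {"mode": cfg.feature_mode}
    if cfg.feature_mode == "network":
        features, net_info = _network_features(cfg, treated, ds_cal,
                                               feat_seed)
        feat_info.update(net_info)
        task_features = {t: features for t in ("alcohol", "wort",
                                               "classify")}
    elif cfg.feature_mode == "vip":
        task_features = {}
        for task in ("alcohol", "wort", "classify"):
            sweep = vip_sweep(ds_cal, task, seed=feat_seed,
                              k=min(10, cfg.cv_folds * 2),
                              mccv_splits=cfg.mccv_splits)
            task_features[task] = treated.absorbance[:, sweep.selected]
            feat_info[task] = {
                "best_threshold": sweep.best_threshold,
                "n_selected": int(sweep.selected.size),
                "n_lv": sweep.n_lv}
    elif cfg.feature_mode == "raw":
        task_features = {t: treated.absorbance
                         for t in ("alcohol", "wort", "classify")}
    else:
        raise ValueError(f"unknown feature_mode {cfg.feature_mode!r}")
    feat_path = outdir / "features.json"
    _dump(feat_info, feat_path)
    timer["features"] = time.perf_counter() - t0
    record("features", feat_path)

    # -- stage 5 & 6: downstream models + evaluation -----------------------
    t0 = time.perf_counter()
    model_seed = _stage_seed(cfg.seed, 4)
    report: dict = {}
    model_info: dict = {}
    subsets = {"calibration": split.calibration,
               "validation": split.validation, "test": split.test}
    for task in ("alcohol", "wort"):
        if not treated.has_targets(task):
            continue
        Xf = task_features[task]
        y = treated.target(task)
        cal = split.calibration
        if cfg.regression_model == "plsr":
            n_lv, _ = select_lvs_mccv(Xf[cal], y[cal],
                                      n_splits=cfg.mccv_splits,
                                      seed=model_seed)
            model = fit_plsr(Xf[cal], y[cal], n_lv)
            model_info[task] = {"model": "plsr", "n_lv": n_lv}
        else:
            model = fit_svr_grid(Xf[cal], y[cal], k=cfg.svr_cv_folds,
                                 seed=model_seed)
            model_info[task] = {"model": "svr", "C": model.C,
                                "gamma": model.gamma,
                                "cv_rmse": model.cv_rmse}
        report[task] = {}
        for name, idx in subsets.items():
            pred = model.predict(Xf[idx])
            entry = regression_metrics(y[idx], pred).as_dict()
            if name in ("validation", "test"):
                _, p_val, _, _ = paired_consistency_ttest(y[idx], pred)
                entry["ttest_p"] = p_val
            report[task][name] = entry
    if treated.has_targets("classify"):
        Xf = task_features["classify"]
        labels = treated.target("classify")
        cal = split.calibration
        n_lv = min(10, Xf.shape[1], len(cal) - 1)
        model = fit_plsda(Xf[cal], labels[cal], n_lv)
        model_info["classify"] = {"model": "plsda", "n_lv": model.n_lv}
        report["classify"] = {
            name: classification_metrics(labels[idx],
                                         model.predict(Xf[idx])).as_dict()
            for name, idx in subsets.items()}
    model_path = outdir / "models.json"
    _dump(model_info, model_path)
    timer["models"] = time.perf_counter() - t0
    record("models", model_path)

    t0 = time.perf_counter()
    eval_path = outdir / "evaluation.json"
    _dump(report, eval_path)
    timer["evaluate"] = time.perf_counter() - t0
    record("evaluate", eval_path)

    manifest["report"] = report
    _dump(manifest, outdir / "manifest.json")
    return manifest


def _final_cfg(train_cfg: TrainConfig) -> TrainConfig:
    # CV fitness ranks configurations on 2/3-size folds; the final extractor
    # is refit on the full calibration set with twice the epoch budget
    return TrainConfig(train_cfg.epochs * 2, train_cfg.batch_size,
                       train_cfg.lr_drop_period, train_cfg.seed)


def _network_features(cfg: RunConfig, treated: SpectralDataset,
                      ds_cal: SpectralDataset, seed: int):
    """Optimize, train and apply a deep feature extractor."""
    train_cfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                            seed=seed)
    X_cal = ds_cal.absorbance
    info: dict = {"arch": cfg.arch, "strategy": cfg.strategy}
    if cfg.strategy == "mtl":
        if cfg.norms is not None:
            norms = tuple(cfg.norms)
        else:
            # single-task benchmark fitness of the default configuration
            # provides the per-task normalization factors
            norms = tuple(
                _norm_floor(cv_fitness(NetworkConfig(arch=cfg.arch),
                                       ds_cal, task=task, k=cfg.cv_folds,
                                       seed=seed, train_cfg=train_cfg),
                            ds_cal.n_samples)
                for task in ("alcohol", "wort", "classify"))
        info["norms"] = norms
        space = default_search_space(cfg.arch, include_weights=True,
                                     reduced=cfg.reduced_space)

        def objective(point):
            net_cfg, weights = _point_to_config(cfg.arch, point)
            fit = cv_fitness(net_cfg, ds_cal, weights=weights, norms=norms,
                             k=cfg.cv_folds, seed=seed, train_cfg=train_cfg)
            return fit.wje if isinstance(fit, MTLFitness) else fit

        result = optimize(space, objective, n_iter=cfg.boa_iters,
                          n_init=cfg.boa_init, seed=seed)
        best_cfg, best_weights = _point_to_config(cfg.arch,
                                                  result.best_point)
        net = build_network(best_cfg, treated.n_wavelengths,
                            ("alcohol", "wort", "classify"), init_seed=seed)
        extractor = train_mtl(net, X_cal, ds_cal.alcohol, ds_cal.wort,
                              ds_cal.class_label, best_weights.as_tuple(),
                              _final_cfg(train_cfg))
        info["task_weights"] = best_weights.as_tuple()
    else:
        space = default_search_space(cfg.arch, include_weights=False,
                                     reduced=cfg.reduced_space)

        def objective(point):
            net_cfg, _ = _point_to_config(cfg.arch, point)
            return cv_fitness(net_cfg, ds_cal, task=cfg.stl_task,
                              k=cfg.cv_folds, seed=seed,
                              train_cfg=train_cfg)

        result = optimize(space, objective, n_iter=cfg.boa_iters,
                          n_init=cfg.boa_init, seed=seed)
        best_cfg, _ = _point_to_config(cfg.arch, result.best_point)
        net = build_network(best_cfg, treated.n_wavelengths,
                            (cfg.stl_task,), init_seed=seed)
        extractor = train_stl(net, X_cal, ds_cal.target(cfg.stl_task),
                              cfg.stl_task, _final_cfg(train_cfg))
    info.update({
        "best_fitness": result.best_fitness,
        "best_config": asdict(best_cfg),
        "parameter_count": count_parameters(net),
        "trace": [{"fitness": v, "best": b} for _, v, b in result.trace]})
    features = extract_features(extractor, treated.absorbance)
    return features.values, info
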