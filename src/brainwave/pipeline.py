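"""End-to-end orchestration: generate -> invert -> enhance -> evaluate.

A single :class:`RunConfig` (serializable to YAML, hash-stamped into every
artifact) drives four stages, each resumable via a ``done.json`` marker in
its stage directory:

1. ``dataset``  — training set plus held-out normal and anomaly test sets
2. ``fcernn``   — per-block reconstruction sub-models
3. ``unet``     — slice-wise enhancement model (trained on reconstructions
                  of training phantoms across the noise-level menu)
4. ``benchmark``— misfit tables for both stages across noise levels

All randomness derives from the single root seed through fixed named
offsets, so a rerun with the same config reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .dataset import DatasetConfig, generate_dataset, load_dataset
from .evaluate import (
    anomaly_detection_report,
    benchmark_to_csv,
    model_misfit,
    run_benchmark,
)
from .fcernn import (
    FcernnSpec,
    NormStats,
    TrainConfig,
    build_fcernn,
    load_run,
    partition_volume,
    predict_volume,
    save_run,
    train_fcernn,
)
from .geometry import build_array
from .measure import ScatterRecord, add_noise
from .phantom import ANOMALY_RADII_M, AnomalySpec
from .unet import (
    Unet,
    UnetSpec,
    UnetTrainConfig,
    build_unet,
    enhance_volume,
    pad_slices,
    slice_volume,
    train_unet,
)

# named substream offsets from the root seed
_SEED_DATASET = 0
_SEED_TEST_NORMAL = 400_000
_SEED_TEST_ANOMALY = 500_000
_SEED_SPLIT = 600_000
_SEED_FCERNN = 700_000
_SEED_UNET = 800_000
_SEED_BENCH = 900_000


@dataclass
class RunConfig:
    """Desk-scale pipeline configuration."""

    out_dir: str = "run"
    seed: int = 1
    # domain / data
    grid_n: int = 24
    domain_side_m: float = 0.24
    frequency_hz: float = 300e6
    n_train: int = 100
    n_test_normal: int = 6
    n_test_anomaly: int = 3
    anomaly_fraction: float = 0.5
    forward_method: str = "born"
    solver_tol: float = 1e-6
    val_fraction: float = 0.15
    # stage 1 network
    n_blocks: int = 8
    encoder_channels: tuple[int, ...] = (16, 16, 32, 32, 64, 64, 128, 128)
    decoder_channels: tuple[int, ...] = (64, 32, 16)
    reshape_side: int = 1
    fcernn_epochs: int = 40
    fcernn_batch: int = 25
    fcernn_lr: float = 2e-3
    # stage 2 network
    unet_base_channels: int = 8
    unet_epochs: int = 12
    unet_batch: int = 32
    unet_lr: float = 1e-3
    # evaluation
    noise_levels: tuple[float | None, ...] = (None, -10.0, -20.0, -30.0, -40.0)
    with_data_misfit: bool = True
    eval_grid_factor: float = 1.0  # >1 evaluates data misfit on a finer grid

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("encoder_channels", "decoder_channels", "noise_levels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage_done(stage_dir: Path, cfg: "RunConfig") -> bool:
    marker = stage_dir / "done.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg.config_hash()
    except (json.JSONDecodeError, OSError):
        return False


def _mark_done(stage_dir: Path, cfg: RunConfig, payload: dict | None = None) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "done.json").write_text(
        json.dumps({"config_hash": cfg.config_hash(), **(payload or {})},
                   indent=2, default=str)
    )


def _block_shape(cfg: RunConfig) -> tuple[int, int, int]:
    m = round(cfg.n_blocks ** (1 / 3))
    return (cfg.grid_n // m,) * 3


def stage_dataset(cfg: RunConfig, run_dir: Path, verbose: bool = False) -> dict:
    d = run_dir / "dataset"
    paths = {
        "train": d / "train.h5",
        "test_normal": d / "test_normal.h5",
        "test_anomaly": d / "test_anomaly.h5",
    }
    if _stage_done(d, cfg):
        return {k: str(v) for k, v in paths.items()}
    array = build_array(frequency_hz=cfg.frequency_hz)
    base_cfg = DatasetConfig(
        grid_n=cfg.grid_n,
        domain_side_m=cfg.domain_side_m,
        frequency_hz=cfg.frequency_hz,
        anomaly_fraction=cfg.anomaly_fraction,
        method=cfg.forward_method,
        solver_tol=cfg.solver_tol,
        base_seed=cfg.seed + 11,  # one shared base anatomy for all splits
    )
    generate_dataset(cfg.n_train, base_cfg, cfg.seed + _SEED_DATASET,
                     paths["train"], array=array, verbose=verbose)
    from dataclasses import replace

    generate_dataset(
        cfg.n_test_normal,
        replace(base_cfg, anomaly_fraction=0.0),
        cfg.seed + _SEED_TEST_NORMAL,
        paths["test_normal"], array=array,
    )
    generate_dataset(
        cfg.n_test_anomaly,
        replace(base_cfg, forced_anomaly_radii=tuple(ANOMALY_RADII_M)),
        cfg.seed + _SEED_TEST_ANOMALY,
        paths["test_anomaly"], array=array,
    )
    _mark_done(d, cfg)
    return {k: str(v) for k, v in paths.items()}


def _train_val_split(cfg: RunConfig, n: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(cfg.seed + _SEED_SPLIT)
    perm = rng.permutation(n)
    n_val = max(2, int(round(cfg.val_fraction * n)))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def stage_fcernn(cfg: RunConfig, run_dir: Path, data_paths: dict,
                 verbose: bool = False) -> dict:
    d = run_dir / "fcernn"
    if _stage_done(d, cfg):
        metrics = json.loads((d / "done.json").read_text())
        return metrics
    data = load_dataset(data_paths["train"])
    tr_idx, val_idx = _train_val_split(cfg, data["inputs"].shape[0])
    stats = NormStats.from_training(
        data["inputs"][tr_idx], data["eps"][tr_idx], data["sigma"][tr_idx]
    )
    blocks = partition_volume((cfg.grid_n,) * 3, cfg.n_blocks)
    spec = FcernnSpec(
        input_len=data["inputs"].shape[1],
        encoder_channels=cfg.encoder_channels,
        decoder_channels=cfg.decoder_channels,
        reshape_side=cfg.reshape_side,
        block_shape=_block_shape(cfg),
    )
    models = [build_fcernn(spec, seed=cfg.seed + _SEED_FCERNN + bi)
              for bi in range(len(blocks))]
    hist = train_fcernn(
        models, blocks,
        data["inputs"][tr_idx], data["eps"][tr_idx], data["sigma"][tr_idx],
        stats,
        TrainConfig(epochs=cfg.fcernn_epochs, batch_size=cfg.fcernn_batch,
                    lr=cfg.fcernn_lr),
        seed=cfg.seed + _SEED_FCERNN,
        verbose=verbose,
    )
    save_run(d, models, blocks, stats, hist,
             extra_meta={"config_hash": cfg.config_hash()})
    # validation misfit vs. constant-volume baselines
    full_shape = (cfg.grid_n,) * 3
    val_mis, base_tr, base_val = [], [], []
    mean_tr = (data["eps"][tr_idx].mean(axis=0), data["sigma"][tr_idx].mean(axis=0))
    mean_val = (data["eps"][val_idx].mean(axis=0), data["sigma"][val_idx].mean(axis=0))
    for i in val_idx:
        truth = (data["eps"][i], data["sigma"][i])
        pred = predict_volume(models, blocks, data["inputs"][i], stats, full_shape)
        val_mis.append(model_misfit(pred, truth))
        base_tr.append(model_misfit(mean_tr, truth))
        base_val.append(model_misfit(mean_val, truth))
    metrics = {
        "val_model_misfit_pct": float(np.mean(val_mis)),
        "baseline_trainmean_misfit_pct": float(np.mean(base_tr)),
        "baseline_valmean_misfit_pct": float(np.mean(base_val)),
        "final_train_loss": [h[-1] for h in hist],
        "n_params_per_block": models[0].n_params,
    }
    _mark_done(d, cfg, metrics)
    return metrics


def _reconstruct_training_volumes(cfg, models, blocks, stats, data, idx):
    """Stage-1 reconstructions of training phantoms at cycled noise levels
    (the U-Net's training inputs)."""
    full_shape = (cfg.grid_n,) * 3
    levels = list(cfg.noise_levels)
    X_slices, Y_slices = [], []
    for j, i in enumerate(idx):
        rec = ScatterRecord(e_scat=data["escat"][i], frequency_hz=cfg.frequency_hz)
        level = levels[j % len(levels)]
        noisy = add_noise(rec, level, seed=cfg.seed + _SEED_UNET + 31 * int(i))
        pre = predict_volume(models, blocks, noisy.input_vec, stats, full_shape)
        xs = slice_volume(stats.normalize_targets(pre[0], pre[1]))
        ys = slice_volume(
            stats.normalize_targets(data["eps"][i], data["sigma"][i])
        )
        X_slices.append(pad_slices(xs, 16)[0])
        Y_slices.append(pad_slices(ys, 16)[0])
    return np.concatenate(X_slices), np.concatenate(Y_slices)


def stage_unet(cfg: RunConfig, run_dir: Path, data_paths: dict,
               verbose: bool = False) -> dict:
    d = run_dir / "unet"
    if _stage_done(d, cfg):
        return json.loads((d / "done.json").read_text())
    models, blocks, stats = load_run(run_dir / "fcernn")
    data = load_dataset(data_paths["train"])
    tr_idx, val_idx = _train_val_split(cfg, data["inputs"].shape[0])
    X, Y = _reconstruct_training_volumes(cfg, models, blocks, stats, data, tr_idx)
    model = build_unet(UnetSpec(base_channels=cfg.unet_base_channels),
                       seed=cfg.seed + _SEED_UNET)
    hist = train_unet(
        model, X, Y,
        UnetTrainConfig(epochs=cfg.unet_epochs, batch_size=cfg.unet_batch,
                        lr=cfg.unet_lr),
        seed=cfg.seed + _SEED_UNET,
        verbose=verbose,
    )
    save_unet(d, model, hist, cfg)
    # validation MSE of the model vs. the identity mapping
    Xv, Yv = _reconstruct_training_volumes(cfg, models, blocks, stats, data, val_idx)
    pred = np.concatenate(
        [model.predict(Xv[s : s + 32]) for s in range(0, Xv.shape[0], 32)]
    )
    metrics = {
        "val_mse": float(np.mean((pred - Yv) ** 2)),
        "identity_val_mse": float(np.mean((Xv - Yv) ** 2)),
        "final_train_loss": hist[-1],
    }
    _mark_done(d, cfg, metrics)
    return metrics


def save_unet(d: Path, model: Unet, hist, cfg: RunConfig) -> None:
    d.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{idx}": p.data for idx, p in enumerate(model.params())}
    np.savez(d / "unet.npz", **arrays)
    meta = {
        "spec": asdict(model.spec),
        "trained_hw": list(model.trained_hw) if model.trained_hw else None,
        "config_hash": cfg.config_hash(),
        "history": [float(h) for h in hist],
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta))


def load_unet(d: Path) -> Unet:
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    model = build_unet(UnetSpec(**meta["spec"]))
    data = np.load(d / "unet.npz")
    for idx, p in enumerate(model.params()):
        p.data[...] = data[f"p{idx}"]
    if meta["trained_hw"]:
        model.trained_hw = tuple(meta["trained_hw"])
    return model


def stage_benchmark(cfg: RunConfig, run_dir: Path, data_paths: dict) -> dict:
    d = run_dir / "benchmark"
    if _stage_done(d, cfg):
        return json.loads((d / "done.json").read_text())
    d.mkdir(parents=True, exist_ok=True)
    models, blocks, stats = load_run(run_dir / "fcernn")
    unet_model = load_unet(run_dir / "unet")
    array = build_array(frequency_hz=cfg.frequency_hz)
    full_shape = (cfg.grid_n,) * 3
    all_reports = []
    payload: dict = {"cases": {}}
    for case_id, path_key in (("normal", "test_normal"), ("anomaly", "test_anomaly")):
        data = load_dataset(data_paths[path_key])
        samples = [
            {
                "record": ScatterRecord(e_scat=data["escat"][i],
                                        frequency_hz=cfg.frequency_hz),
                "eps": data["eps"][i],
                "sigma": data["sigma"][i],
            }
            for i in range(data["inputs"].shape[0])
        ]
        reports = run_benchmark(
            models, blocks, unet_model, stats, samples, array, full_shape,
            cfg.domain_side_m,
            noise_levels=cfg.noise_levels,
            seed=cfg.seed + _SEED_BENCH,
            case_id=case_id,
            with_data_misfit=cfg.with_data_misfit,
            forward_method=cfg.forward_method,
            eval_grid_factor=cfg.eval_grid_factor,
        )
        all_reports.extend(reports)
        payload["cases"][case_id] = [asdict(r) for r in reports]
        if case_id == "anomaly":
            det = []
            for i in range(len(samples)):
                prov = data["provenance"][i]
                a_raw = prov.get("anomalies", [])
                if not a_raw:
                    continue
                c, r, e, s = a_raw[-1]
                anomaly = AnomalySpec(center_m=tuple(c), radius_m=r, eps_r=e, sigma=s)
                rec0 = samples[i]["record"]
                noisy = add_noise(rec0, None, seed=0)
                pre = predict_volume(models, blocks, noisy.input_vec, stats, full_shape)
                enh = enhance_volume(unet_model, pre[0], pre[1], stats)
                det.append(
                    anomaly_detection_report(enh, (samples[i]["eps"], samples[i]["sigma"]),
                                             anomaly, cfg.domain_side_m)
                )
            payload["anomaly_detection"] = det
    benchmark_to_csv(all_reports, d / "benchmark.csv", config=asdict(cfg),
                     seeds={"root": cfg.seed, "benchmark": cfg.seed + _SEED_BENCH})
    _mark_done(d, cfg, payload)
    return payload


def run_pipeline(cfg: RunConfig, verbose: bool = False) -> dict:
    """Execute all stages in order (resuming completed ones) and return the
    collected metrics.  Any stage failure propagates with its artifacts
    left in place for inspection."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.save(run_dir / "config.yaml")
    t0 = time.time()
    timings = {}
    data_paths = stage_dataset(cfg, run_dir, verbose=verbose)
    timings["dataset_s"] = round(time.time() - t0, 1)
    t = time.time()
    fc_metrics = stage_fcernn(cfg, run_dir, data_paths, verbose=verbose)
    timings["fcernn_s"] = round(time.time() - t, 1)
    t = time.time()
    un_metrics = stage_unet(cfg, run_dir, data_paths, verbose=verbose)
    timings["unet_s"] = round(time.time() - t, 1)
    t = time.time()
    bench = stage_benchmark(cfg, run_dir, data_paths)
    timings["benchmark_s"] = round(time.time() - t, 1)
    timings["total_s"] = round(time.time() - t0, 1)
    result = {
        "run_dir": str(run_dir),
        "config_hash": cfg.config_hash(),
        "data_paths": data_paths,
        "fcernn": fc_metrics,
        "unet": un_metrics,
        "benchmark": bench,
        "timings": timings,
    }
    (run_dir / "metrics.json").write_text(json.dumps(result, indent=2, default=str))
    return result
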