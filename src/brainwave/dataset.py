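"""Paired (scattered field, property volume) dataset generation.

Chains the phantom strategy with the forward solver and writes HDF5
files with the layout::

    /meta                      attrs: config snapshot (JSON), root seed
    /samples/<k>/input         float64 (2M,)   aggregated input vector
    /samples/<k>/escat         complex128 (n_ant, n_ant-1, 3)
    /samples/<k>/eps           float32 (n, n, n)
    /samples/<k>/sigma         float32 (n, n, n)
    /samples/<k>/labels        uint8  (n, n, n)
    /samples/<k> attrs         provenance (scale factor, seeds, anomaly)

Generation is resumable (complete samples are skipped on re-run) and
deterministic given the root seed; a non-converging forward solve is
logged and the sample regenerated with a perturbed seed up to a retry cap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np

from .geometry import AntennaArray, build_array
from .phantom import BrainPhantom, build_base_phantom, sample_phantom
from .solver import SolverError, solve_scattered_field
from .tissues import default_tissue_table

log = logging.getLogger(__name__)

_RETRY_CAP = 3


@dataclass
class DatasetConfig:
    grid_n: int = 24
    domain_side_m: float = 0.24
    frequency_hz: float = 300e6
    anomaly_fraction: float = 0.5  # fraction of samples with an anomaly
    forced_anomaly_radii: tuple[float, ...] | None = None  # cycle per sample
    method: str = "born"
    solver_tol: float = 1e-6
    #: seed of the shared base anatomy; None derives it from the dataset
    #: seed.  Train and test splits must pass the same value so that only
    #: the strategy transformations (not the anatomy) are held out.
    base_seed: int | None = None


def _provenance_attrs(grp, phantom: BrainPhantom, sample_seed: int) -> None:
    prov = dict(phantom.provenance)
    grp.attrs["provenance"] = json.dumps(prov, default=str)
    grp.attrs["sample_seed"] = sample_seed
    grp.attrs["scale_factor"] = prov.get("scale_factor", 1.0)


def generate_dataset(
    n_samples: int,
    config: DatasetConfig,
    seed: int,
    out_path,
    array: AntennaArray | None = None,
    verbose: bool = False,
) -> Path:
    """Generate ``n_samples`` paired records into an HDF5 file.

    Re-running with the same arguments resumes (and reproduces byte-
    identical volumes for already-present samples' indices).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    array = array or build_array(frequency_hz=config.frequency_hz)
    table = default_tissue_table(config.frequency_hz)
    base_seed = config.base_seed if config.base_seed is not None else seed + 11
    base = build_base_phantom(
        table, config.grid_n, config.domain_side_m, seed=base_seed
    )
    with h5py.File(out_path, "a") as f:
        meta = f.require_group("meta")
        meta.attrs["config"] = json.dumps(asdict(config))
        meta.attrs["seed"] = seed
        samples = f.require_group("samples")
        for k in range(n_samples):
            name = f"{k:05d}"
            if name in samples and samples[name].attrs.get("complete", False):
                continue
            if name in samples:
                del samples[name]
            with_anomaly = (
                config.forced_anomaly_radii is not None
                or (k % max(1, round(1 / config.anomaly_fraction)) == 0
                    if 0 < config.anomaly_fraction <= 1 else False)
            )
            sample_seed = seed + 1000 + 17 * k
            rec = None
            for attempt in range(_RETRY_CAP):
                s = sample_seed + 1000003 * attempt
                if config.forced_anomaly_radii is not None:
                    # draw the full strategy, then pin the anomaly radius
                    # for this sample index (one phantom per menu radius)
                    from dataclasses import replace as dc_replace

                    from .phantom import (
                        deform_tissue_boundaries,
                        insert_anomaly,
                        sample_strategy_params,
                        scale_phantom,
                    )

                    params = sample_strategy_params(s, with_anomaly=True,
                                                    n_tissues=base.n_tissues)
                    radius = config.forced_anomaly_radii[
                        k % len(config.forced_anomaly_radii)
                    ]
                    phantom = scale_phantom(base, params.factor)
                    phantom = deform_tissue_boundaries(
                        phantom, params.sigma_disp_m, seed=s + 1, order=params.order
                    )
                    phantom = insert_anomaly(
                        phantom, dc_replace(params.anomaly, radius_m=radius)
                    )
                    phantom.provenance["sample_seed"] = s
                else:
                    phantom, params = sample_phantom(base, s, with_anomaly=with_anomaly)
                try:
                    rec = solve_scattered_field(
                        phantom, array, method=config.method, solver_tol=config.solver_tol
                    )
                    break
                except SolverError as e:
                    log.warning("sample %d attempt %d failed: %s", k, attempt, e)
            if rec is None:
                raise SolverError(
                    f"sample {k} failed after {_RETRY_CAP} attempts"
                )
            grp = samples.create_group(name)
            grp.create_dataset("input", data=rec.input_vec)
            grp.create_dataset("escat", data=rec.e_scat)
            grp.create_dataset("eps", data=phantom.eps_grid.astype(np.float32))
            grp.create_dataset("sigma", data=phantom.sigma_grid.astype(np.float32))
            grp.create_dataset("labels", data=phantom.label_grid.astype(np.uint8))
            _provenance_attrs(grp, phantom, sample_seed)
            grp.attrs["complete"] = True
            if verbose and k % 20 == 0:
                print(f"  sample {k}/{n_samples}")
    return out_path


def load_dataset(path) -> dict:
    """Load a generated dataset into memory.

    Returns a dict with ``inputs`` (S, 2M), ``escat`` (S, n_ant, n_ant-1, 3),
    ``eps``/``sigma`` (S, n, n, n), ``labels``, ``provenance`` (list of
    dicts) and ``config``.
    """
    with h5py.File(path, "r") as f:
        keys = sorted(f["samples"].keys())
        inputs, escat, eps, sigma, labels, prov = [], [], [], [], [], []
        for k in keys:
            g = f["samples"][k]
            inputs.append(g["input"][()])
            escat.append(g["escat"][()])
            eps.append(g["eps"][()])
            sigma.append(g["sigma"][()])
            labels.append(g["labels"][()])
            prov.append(json.loads(g.attrs.get("provenance", "{}")))
        config = json.loads(f["meta"].attrs["config"])
    return {
        "inputs": np.asarray(inputs),
        "escat": np.asarray(escat),
        "eps": np.asarray(eps, dtype=np.float64),
        "sigma": np.asarray(sigma, dtype=np.float64),
        "labels": np.asarray(labels),
        "provenance": prov,
        "config": config,
    }


def export_nifti(volume: np.ndarray, voxel_size_m: float, path) -> None:
    """Export a volume as NIfTI for visual inspection (requires nibabel)."""
    import nibabel as nib

    affine = np.diag([voxel_size_m * 1e3] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
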