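"""Procedural dielectric brain phantoms.

A phantom is a set of 16 nested, closed tissue surfaces voxelized onto a
centered cubic domain of interest (DOI).  Each surface is a radial function
``rho_i(theta, phi)`` stored on a (theta, phi) control grid and evaluated by
smooth spline interpolation; nesting (surface i strictly outside surface
i+1) is enforced at all times, which guarantees watertight, simply nested
tissue regions under every transformation.

The dataset-building strategy transforms a base phantom by
(1) random global scaling in {0.8, 0.9, 1.0, 1.1, 1.2} applied to *both*
geometry and electrical properties, (2) per-tissue boundary deformation by
i.i.d. normal control-point displacements applied in a random tissue order,
and (3) optional insertion of a spherical anomalous scatterer (lesion /
bleed / tumor stand-in) with radius drawn from {4, 7, 10} mm, relative
permittivity from {90, 120, 150} and conductivity from
{1.038, 1.384, 1.73} S/m.

Grids are indexed ``[ix, iy, iz]`` with voxel-centered sampling; linear
voxel indices, where needed, run x fastest (Fortran order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .tissues import TissueTable, default_tissue_table

# strategy menus
SCALE_FACTORS = (0.8, 0.9, 1.0, 1.1, 1.2)
ANOMALY_RADII_M = (0.004, 0.007, 0.010)
ANOMALY_EPS_R = (90.0, 120.0, 150.0)
ANOMALY_SIGMA = (1.038, 1.384, 1.73)

#: default standard deviation (m) of boundary control-point displacement
DEFAULT_SIGMA_DISP_M = 0.002

# base geometry: mean outer radius (m) and superellipsoid semi-axis ratios
_R_OUTER = 0.075
_AXES = (1.0, 0.85, 0.8)
_SE_POWER = 2.5
_F_OUTER, _F_INNER = 1.0, 0.15
_N_THETA, _N_PHI = 13, 24
_MIN_GAP_M = 1e-4  # minimal radial clearance preserved between neighbors


@dataclass
class AnomalySpec:
    """A spherical anomalous scatterer (lesion/bleeding/tumor stand-in)."""

    center_m: tuple[float, float, float]
    radius_m: float
    eps_r: float
    sigma: float


@dataclass
class StrategyParams:
    """One draw of the dataset-building strategy."""

    factor: float
    sigma_disp_m: float
    order: np.ndarray  # permutation of tissue indices
    anomaly: AnomalySpec | None


@dataclass
class BrainPhantom:
    """Labeled tissue volume with per-voxel electrical property grids.

    ``label_grid`` uses 0 for air, ``1..n_tissues`` for the nested tissues
    (outermost first) and ``n_tissues + 1`` for anomalous scatterers.
    """

    label_grid: np.ndarray  # (n, n, n) uint8
    eps_grid: np.ndarray  # (n, n, n) float64, >= 1
    sigma_grid: np.ndarray  # (n, n, n) float64, >= 0
    domain_side_m: float
    voxel_size_m: float
    table: TissueTable
    surfaces: np.ndarray  # (n_tissues, n_theta, n_phi) control radii, m
    tissue_eps: np.ndarray  # per-tissue eps_r after any scaling
    tissue_sigma: np.ndarray  # per-tissue sigma after any scaling
    anomalies: list[AnomalySpec] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def grid_n(self) -> int:
        return self.label_grid.shape[0]

    @property
    def n_tissues(self) -> int:
        return len(self.table)

    @property
    def anomaly_label(self) -> int:
        return self.n_tissues + 1


# ---------------------------------------------------------------------------
# surface machinery


def _control_angles() -> tuple[np.ndarray, np.ndarray]:
    theta = np.linspace(0.0, np.pi, _N_THETA)
    phi = np.linspace(0.0, 2.0 * np.pi, _N_PHI, endpoint=False)
    return theta, phi


def _pole_fix(grid: np.ndarray) -> np.ndarray:
    """Make the polar rows phi-independent (a radial map must be single
    valued at the poles)."""
    grid = grid.copy()
    grid[0, :] = grid[0, :].mean()
    grid[-1, :] = grid[-1, :].mean()
    return grid


def _superellipsoid_radius(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Radial profile of a unit superellipsoid, broadcast over a grid."""
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    nx = np.sin(tt) * np.cos(pp) / _AXES[0]
    ny = np.sin(tt) * np.sin(pp) / _AXES[1]
    nz = np.cos(tt) / _AXES[2]
    p = _SE_POWER
    return (np.abs(nx) ** p + np.abs(ny) ** p + np.abs(nz) ** p) ** (-1.0 / p)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Smooth random field on the control grid (coarse noise, bilinear
    upsampled) with unit peak scale."""
    coarse = rng.standard_normal((4, 6))
    ti = np.linspace(0, 3, shape[0])
    pi = np.linspace(0, 5, shape[1])
    t0 = np.clip(ti.astype(int), 0, 2)
    p0 = np.clip(pi.astype(int), 0, 4)
    ft = ti - t0
    fp = pi - p0
    a = coarse[np.ix_(t0, p0)]
    b = coarse[np.ix_(t0 + 1, p0)]
    c = coarse[np.ix_(t0, p0 + 1)]
    d = coarse[np.ix_(t0 + 1, p0 + 1)]
    f = (
        a * (1 - ft[:, None]) * (1 - fp[None, :])
        + b * ft[:, None] * (1 - fp[None, :])
        + c * (1 - ft[:, None]) * fp[None, :]
        + d * ft[:, None] * fp[None, :]
    )
    m = np.max(np.abs(f))
    return f / m if m > 0 else f


def _build_surfaces(n_tissues: int, rng: np.random.Generator) -> np.ndarray:
    theta, phi = _control_angles()
    base = _superellipsoid_radius(theta, phi)  # (T, P)
    # square-root spacing: shells thicken toward the center, where the
    # voxel lattice is sparsest, so every region survives coarse grids
    fractions = np.sqrt(np.linspace(_F_OUTER**2, _F_INNER**2, n_tissues))
    gap = (fractions[0] - fractions[1]) if n_tissues > 1 else 0.3
    surfaces = np.empty((n_tissues, _N_THETA, _N_PHI))
    for i, f in enumerate(fractions):
        # per-tissue smooth perturbation, small enough to preserve nesting
        pert = _smooth_noise(rng, (_N_THETA, _N_PHI)) * (0.35 * gap)
        surfaces[i] = _pole_fix(_R_OUTER * base * (f + pert))
    # enforce strict nesting outer -> inner
    for i in range(1, n_tissues):
        surfaces[i] = np.minimum(surfaces[i], surfaces[i - 1] - _MIN_GAP_M)
    return surfaces


def _surface_spline(grid: np.ndarray) -> RectBivariateSpline:
    theta, phi = _control_angles()
    # pad phi periodically so the spline wraps smoothly
    npad = 3
    phi_ext = np.concatenate(
        [phi[-npad:] - 2 * np.pi, phi, phi[:npad] + 2 * np.pi]
    )
    grid_ext = np.concatenate([grid[:, -npad:], grid, grid[:, :npad]], axis=1)
    return RectBivariateSpline(theta, phi_ext, grid_ext, kx=3, ky=3, s=0)


def voxel_centers(grid_n: int, domain_side_m: float) -> np.ndarray:
    """Voxel-center coordinates, shape (n, n, n, 3), DOI centered at 0."""
    h = domain_side_m / grid_n
    axis = (np.arange(grid_n) + 0.5) * h - domain_side_m / 2.0
    x, y, z = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.stack([x, y, z], axis=-1)


def _voxelize_labels(
    surfaces: np.ndarray, grid_n: int, domain_side_m: float
) -> np.ndarray:
    pts = voxel_centers(grid_n, domain_side_m).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    safe_r = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(pts[:, 2] / safe_r, -1.0, 1.0))
    phi = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
    count = np.zeros(pts.shape[0], dtype=np.uint8)
    for i in range(surfaces.shape[0]):
        rho = _surface_spline(surfaces[i]).ev(theta, phi)
        count += (r <= rho).astype(np.uint8)
    count[r == 0] = surfaces.shape[0]  # exact center is innermost
    return count.reshape(grid_n, grid_n, grid_n)


def _property_grids(
    label_grid: np.ndarray,
    tissue_eps: np.ndarray,
    tissue_sigma: np.ndarray,
    anomalies: list[AnomalySpec],
    grid_n: int,
    domain_side_m: float,
) -> tuple[np.ndarray, np.ndarray]:
    n_tissues = tissue_eps.size
    eps_lut = np.concatenate([[1.0], tissue_eps, [1.0]])
    sig_lut = np.concatenate([[0.0], tissue_sigma, [0.0]])
    eps = eps_lut[label_grid]
    sig = sig_lut[label_grid]
    if anomalies:
        pts = voxel_centers(grid_n, domain_side_m)
        for a in anomalies:
            mask = label_grid == n_tissues + 1
            d = np.linalg.norm(pts - np.asarray(a.center_m), axis=-1)
            inside = mask & (d <= a.radius_m + 1e-12)
            # a degenerate (sub-voxel) anomaly owns at least its center voxel
            if not inside.any():
                inside = mask
            eps[inside] = a.eps_r
            sig[inside] = a.sigma
    return eps, sig


def _revoxelize(p: BrainPhantom) -> BrainPhantom:
    labels = _voxelize_labels(p.surfaces, p.grid_n, p.domain_side_m)
    eps, sig = _property_grids(
        labels, p.tissue_eps, p.tissue_sigma, [], p.grid_n, p.domain_side_m
    )
    out = replace(p, label_grid=labels, eps_grid=eps, sigma_grid=sig, anomalies=[])
    for a in p.anomalies:
        out = insert_anomaly(out, a)
    return out


# ---------------------------------------------------------------------------
# operations


def build_base_phantom(
    table: TissueTable | None = None,
    grid_n: int = 64,
    domain_side_m: float = 0.24,
    seed: int = 0,
) -> BrainPhantom:
    """Construct the nested-superellipsoid base phantom.

    The base geometry is a procedural stand-in for an anatomical model:
    16 nested smooth closed surfaces (superellipsoids with a small seeded
    smooth perturbation), assigned tissues outer to inner from ``table``.
    Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If ``grid_n`` is too coarse to realize every tissue region; the
        message names the smallest empty tissue.
    """
    if table is None:
        table = default_tissue_table()
    if grid_n < 16:
        raise ValueError(f"grid_n must be >= 16, got {grid_n}")
    if domain_side_m <= 0:
        raise ValueError("domain_side_m must be positive")
    rng = np.random.default_rng(seed)
    surfaces = _build_surfaces(len(table), rng)
    labels = _voxelize_labels(surfaces, grid_n, domain_side_m)
    counts = np.bincount(labels.ravel(), minlength=len(table) + 2)
    empty = [i for i in range(1, len(table) + 1) if counts[i] == 0]
    if empty:
        # report the innermost (smallest-volume) empty tissue
        name = table.names[empty[-1] - 1]
        raise ValueError(
            f"grid_n={grid_n} too coarse: tissue {name!r} has no voxels; "
            "use a finer grid"
        )
    tissue_eps = np.asarray(table.eps_r, dtype=float)
    tissue_sigma = np.asarray(table.sigma, dtype=float)
    eps, sig = _property_grids(labels, tissue_eps, tissue_sigma, [], grid_n, domain_side_m)
    return BrainPhantom(
        label_grid=labels,
        eps_grid=eps,
        sigma_grid=sig,
        domain_side_m=domain_side_m,
        voxel_size_m=domain_side_m / grid_n,
        table=table,
        surfaces=surfaces,
        tissue_eps=tissue_eps,
        tissue_sigma=tissue_sigma,
        anomalies=[],
        provenance={"base_seed": seed, "scale_factor": 1.0, "anomalies": []},
    )


def scale_phantom(p: BrainPhantom, factor: float) -> BrainPhantom:
    """Scale geometry about the DOI center and electrical properties by the
    same ``factor`` (eps_r floored at 1, air untouched)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    surfaces = p.surfaces * factor
    if surfaces.max() > p.domain_side_m / 2.0:
        raise ValueError(
            f"scaled brain (max radius {surfaces.max():.3f} m) exceeds the "
            f"DOI half-side {p.domain_side_m / 2.0:.3f} m"
        )
    tissue_eps = np.maximum(1.0, p.tissue_eps * factor)
    tissue_sigma = p.tissue_sigma * factor
    anomalies = [
        AnomalySpec(
            center_m=tuple(np.asarray(a.center_m) * factor),
            radius_m=a.radius_m * factor,
            eps_r=max(1.0, a.eps_r * factor),
            sigma=a.sigma * factor,
        )
        for a in p.anomalies
    ]
    out = replace(
        p,
        surfaces=surfaces,
        tissue_eps=tissue_eps,
        tissue_sigma=tissue_sigma,
        anomalies=anomalies,
        provenance={**p.provenance, "scale_factor": p.provenance.get("scale_factor", 1.0) * factor},
    )
    return _revoxelize(out)


def deform_tissue_boundaries(
    p: BrainPhantom,
    sigma_disp_m: float = DEFAULT_SIGMA_DISP_M,
    seed: int = 0,
    order: np.ndarray | None = None,
) -> BrainPhantom:
    """Deform each tissue boundary by i.i.d. normal control-point
    displacements, processed in a (seeded) random tissue order.

    Each control point receives a displacement ``d ~ Normal(0, sigma^2 I3)``
    in x, y, z; its radial component moves the control radius, and the
    surface is smoothly re-interpolated.  Displacements that would cross a
    neighboring surface are clipped so nesting is preserved.
    """
    if sigma_disp_m < 0:
        raise ValueError("sigma_disp_m must be >= 0")
    rng = np.random.default_rng(seed)
    if order is None:
        order = rng.permutation(p.n_tissues)
    surfaces = p.surfaces.copy()
    theta, phi = _control_angles()
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    rhat = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    )
    n = p.n_tissues
    for i in order:
        d = rng.normal(0.0, sigma_disp_m, size=(_N_THETA, _N_PHI, 3))
        new = _pole_fix(surfaces[i] + np.sum(d * rhat, axis=-1))
        hi = surfaces[i - 1] - _MIN_GAP_M if i > 0 else np.full_like(new, p.domain_side_m / 2.0)
        lo = surfaces[i + 1] + _MIN_GAP_M if i < n - 1 else np.full_like(new, _MIN_GAP_M)
        if np.any(lo - hi > 1e-9):
            raise ValueError(
                f"deformation of tissue {p.table.names[i]!r} cannot preserve "
                "nesting: neighboring surfaces leave no admissible band"
            )
        # a band degenerate to float precision pins the surface in place
        mid = 0.5 * (lo + hi)
        surfaces[i] = np.clip(new, np.minimum(lo, mid), np.maximum(hi, mid))
    out = replace(
        p,
        surfaces=surfaces,
        provenance={**p.provenance, "deformation_seed": seed, "sigma_disp_m": sigma_disp_m},
    )
    return _revoxelize(out)


def insert_anomaly(p: BrainPhantom, a: AnomalySpec) -> BrainPhantom:
    """Relabel the voxels of a sphere to the anomaly class.

    Voxels whose *center* lies within ``radius_m`` of ``center_m`` are
    relabeled; a sphere smaller than half a voxel still claims the voxel
    containing its center.  The sphere must lie entirely inside the brain
    (intersecting air is an error).
    """
    pts = voxel_centers(p.grid_n, p.domain_side_m)
    d = np.linalg.norm(pts - np.asarray(a.center_m), axis=-1)
    inside = d <= a.radius_m + 1e-12
    if not inside.any():
        inside = d == d.min()  # center-voxel rule for sub-voxel spheres
    labels = p.label_grid
    touched = labels[inside]
    if np.any(touched == 0):
        raise ValueError("anomaly sphere intersects air; it must lie inside the brain")
    new_labels = labels.copy()
    new_labels[inside] = p.anomaly_label
    eps = p.eps_grid.copy()
    sig = p.sigma_grid.copy()
    eps[inside] = a.eps_r
    sig[inside] = a.sigma
    prov = dict(p.provenance)
    prov["anomalies"] = prov.get("anomalies", []) + [
        (tuple(a.center_m), a.radius_m, a.eps_r, a.sigma)
    ]
    return replace(
        p,
        label_grid=new_labels,
        eps_grid=eps,
        sigma_grid=sig,
        anomalies=p.anomalies + [a],
        provenance=prov,
    )


def sample_strategy_params(
    rng_seed: int,
    with_anomaly: bool = True,
    n_tissues: int = 16,
    sigma_disp_m: float = DEFAULT_SIGMA_DISP_M,
) -> StrategyParams:
    """Draw one set of dataset-strategy parameters.

    The scale factor is uniform over {0.8, 0.9, 1.0, 1.1, 1.2}; anomaly
    radius / eps_r / sigma are uniform over their three-value menus; the
    deformation order is a uniform permutation of the tissues.  The anomaly
    center is drawn uniformly in a centered ball of radius ``0.03 * factor``
    m, which keeps the sphere (radius <= 10 mm) strictly inside the deep
    brain for every admissible deformation.  Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    factor = float(rng.choice(SCALE_FACTORS))
    order = rng.permutation(n_tissues)
    anomaly = None
    if with_anomaly:
        radius = float(rng.choice(ANOMALY_RADII_M))
        eps_r = float(rng.choice(ANOMALY_EPS_R))
        sigma = float(rng.choice(ANOMALY_SIGMA))
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        rad = 0.03 * factor * rng.uniform() ** (1.0 / 3.0)
        anomaly = AnomalySpec(center_m=tuple(rad * v), radius_m=radius, eps_r=eps_r, sigma=sigma)
    return StrategyParams(
        factor=factor, sigma_disp_m=sigma_disp_m, order=order, anomaly=anomaly
    )


def sample_phantom(
    base: BrainPhantom, sample_seed: int, with_anomaly: bool = True
) -> tuple[BrainPhantom, StrategyParams]:
    """Apply one strategy draw (scale, deform, optional anomaly) to a base
    phantom and return the transformed phantom plus the draw."""
    params = sample_strategy_params(
        sample_seed, with_anomaly=with_anomaly, n_tissues=base.n_tissues
    )
    q = scale_phantom(base, params.factor)
    q = deform_tissue_boundaries(
        q, params.sigma_disp_m, seed=sample_seed + 1, order=params.order
    )
    if params.anomaly is not None:
        q = insert_anomaly(q, params.anomaly)
    q.provenance["sample_seed"] = sample_seed
    return q, params
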