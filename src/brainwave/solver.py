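"""Volume-integral-equation forward scattering solver.

The phantom's complex contrast ``chi(r) = eps_tilde_r(r) - 1`` scatters the
incident dipole fields.  Two modes are provided:

* ``born`` — single-scattering (first Born) approximation: the total field
  inside the scatterer is replaced by the incident field.  Linear in the
  contrast; fast enough for dataset generation.
* ``full`` — coupled-dipole discretization of the volume integral
  equation: each voxel is a polarizable cell with a quasi-static
  depolarization self-term (L = 1/3 for a cubic cell); off-diagonal
  interactions use the dyadic Green's function.  The linear system is
  solved iteratively with FFT-accelerated convolution matvecs (the
  interaction kernel is block-Toeplitz on the regular grid).

Both modes radiate the induced polarization to the receivers through the
same Green's kernel, fill all ordered (tx, rx) pairs in three Cartesian
components, and are the identical code path used for data-misfit
evaluation (optionally at a different grid to avoid the inverse crime).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.linalg import LinearOperator, bicgstab

from .em import complex_permittivity, greens_interaction
from .geometry import AntennaArray
from .measure import ScatterRecord, aggregate_inputs, receiver_indices
from .phantom import BrainPhantom, voxel_centers

_FULL_MODE_GRID_GUARD = 48

# cache of antenna<->voxel Green blocks keyed by geometry (one resident)
_G_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


class SolverError(RuntimeError):
    """Iterative solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def _antenna_voxel_green(array: AntennaArray, grid_n: int, side_m: float):
    """(G, E_inc) blocks between every antenna and every voxel center.

    G has shape (n_ant, N, 3, 3); E_inc = k0^2 G . axis has shape
    (n_ant, N, 3).  Voxels are enumerated in C order over [ix, iy, iz].
    Cached per geometry (array and grid are fixed across a dataset).
    """
    key = (
        grid_n,
        round(side_m, 12),
        round(array.frequency_hz, 6),
        array.positions_m.tobytes(),
        array.orientations.tobytes(),
    )
    if key in _G_CACHE:
        return _G_CACHE[key]
    pts = voxel_centers(grid_n, side_m).reshape(-1, 3)
    k0 = array.k0
    n_ant = array.n_antennas
    G = np.empty((n_ant, pts.shape[0], 3, 3), dtype=np.complex128)
    for a in range(n_ant):
        G[a] = greens_interaction(pts, array.positions_m[a], k0)
    einc = k0**2 * np.einsum("anij,aj->ani", G, array.orientations)
    _G_CACHE.clear()
    _G_CACHE[key] = (G, einc)
    return G, einc


def _interaction_kernel_fft(grid_n: int, h: float, k0: float, voxel_vol: float):
    """FFTs of the dyadic interaction kernel on the doubled (circulant-
    embedded) grid.  K(dr) = k0^2 V G(dr), K(0) = 0 (self-term analytic)."""
    n2 = 2 * grid_n
    idx = np.fft.fftfreq(n2, d=1.0 / n2).astype(int)  # offsets 0..n-1, -n..-1
    dx, dy, dz = np.meshgrid(idx, idx, idx, indexing="ij")
    dr = np.stack([dx, dy, dz], axis=-1).astype(float) * h
    R = np.linalg.norm(dr, axis=-1)
    mask = R > 0
    K = np.zeros((n2, n2, n2, 3, 3), dtype=np.complex128)
    K[mask] = k0**2 * voxel_vol * greens_interaction(dr[mask], np.zeros(3), k0)
    return np.fft.fftn(K, axes=(0, 1, 2))


def _apply_kernel(Khat: np.ndarray, u: np.ndarray, grid_n: int) -> np.ndarray:
    """Convolve a 3-vector voxel field u (n,n,n,3) with the dyadic kernel."""
    n2 = Khat.shape[0]
    U = np.zeros((n2, n2, n2, 3), dtype=np.complex128)
    U[:grid_n, :grid_n, :grid_n] = u
    Uhat = np.fft.fftn(U, axes=(0, 1, 2))
    Vhat = np.einsum("...ij,...j->...i", Khat, Uhat)
    v = np.fft.ifftn(Vhat, axes=(0, 1, 2))
    return v[:grid_n, :grid_n, :grid_n]


def solve_total_field(
    p: BrainPhantom,
    array: AntennaArray,
    einc: np.ndarray,
    chi_grid: np.ndarray,
    solver_tol: float = 1e-6,
    maxiter: int = 600,
) -> np.ndarray:
    """Coupled-dipole solve of (1 + chi/3) E - K*(chi E) = E_inc for every
    transmitter.

    ``einc``: (n_tx, N, 3) with voxels in C order; ``chi_grid``: (n,n,n)
    complex contrast.  Returns the total field, same shape as ``einc``.
    Raises :class:`SolverError` (carrying the final residual) if the
    iteration does not converge.
    """
    n = p.grid_n
    Khat = _interaction_kernel_fft(n, p.voxel_size_m, array.k0, p.voxel_size_m**3)
    diag = 1.0 + chi_grid / 3.0

    def matvec(x):
        E = x.reshape(n, n, n, 3)
        conv = _apply_kernel(Khat, chi_grid[..., None] * E, n)
        return (diag[..., None] * E - conv).reshape(-1)

    N3 = 3 * n**3
    A = LinearOperator((N3, N3), matvec=matvec, dtype=np.complex128)
    Etot = np.empty_like(einc)
    for t in range(einc.shape[0]):
        rhs = einc[t].reshape(-1)
        sol, info = bicgstab(A, rhs, x0=rhs.copy(), rtol=solver_tol, maxiter=maxiter)
        res = float(np.linalg.norm(A @ sol - rhs) / np.linalg.norm(rhs))
        if info != 0 or not np.isfinite(res) or res > solver_tol * 50:
            raise SolverError(
                f"coupled-dipole solve for transmitter {t} did not converge "
                f"(info={info}, residual={res:.3e}, tol={solver_tol:.1e})",
                residual=res,
            )
        Etot[t] = sol.reshape(-1, 3)
    return Etot


def solve_scattered_field(
    p: BrainPhantom,
    array: AntennaArray,
    method: str = "born",
    solver_tol: float = 1e-6,
    maxiter: int = 600,
    background_eps_r: float = 1.0,
    allow_large_grid: bool = False,
) -> ScatterRecord:
    """Compute scattered fields at all receivers for every transmitter.

    ``method='born'`` uses the single-scattering approximation (linear in
    the contrast); ``method='full'`` solves the coupled-dipole volume
    integral equation to ``solver_tol``.  The record holds all n x (n-1)
    ordered (tx, rx) pairs with x, y, z field components, plus the
    aggregated length-2M input vector.
    """
    if method not in ("born", "full"):
        raise ValueError(f"unknown method {method!r}")
    n = p.grid_n
    if method == "full" and n > _FULL_MODE_GRID_GUARD and not allow_large_grid:
        raise ValueError(
            f"full mode guarded to grids <= {_FULL_MODE_GRID_GUARD}^3 "
            f"(got {n}^3); pass allow_large_grid=True to override"
        )
    k0 = array.k0
    V = p.voxel_size_m**3
    G, einc = _antenna_voxel_green(array, n, p.domain_side_m)
    chi_grid = complex_permittivity(p.eps_grid, p.sigma_grid, array.omega) - background_eps_r
    chi_flat = chi_grid.reshape(-1)  # C order, matches G/einc rows

    if method == "born" or not np.any(chi_flat):
        Etot = einc
    else:
        Etot = solve_total_field(
            p, array, einc, chi_grid, solver_tol=solver_tol, maxiter=maxiter
        )

    # radiate the induced polarization to every antenna acting as receiver
    src = chi_flat[None, :, None] * Etot  # (n_tx, N, 3)
    n_ant = array.n_antennas
    Gm = (k0**2 * V) * G.transpose(0, 2, 1, 3).reshape(n_ant * 3, -1)  # (3 n_rx, 3N)
    E_rx = (Gm @ src.reshape(n_ant, -1).T).reshape(n_ant, 3, n_ant)  # (rx, comp, tx)
    E_full = E_rx.transpose(2, 0, 1)  # (tx, rx, comp)
    e_scat = np.empty((n_ant, n_ant - 1, 3), dtype=np.complex128)
    for t in range(n_ant):
        e_scat[t] = E_full[t, receiver_indices(n_ant, t)]
    rec = ScatterRecord(e_scat=e_scat, frequency_hz=array.frequency_hz)
    rec.input_vec = aggregate_inputs(rec)
    return rec


def dense_system(
    p: BrainPhantom, array: AntennaArray, background_eps_r: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the dense coupled-dipole matrix and incident-field RHS.

    Intended for small grids only (<= ~12^3).  Returns (A, b) with A of
    shape (3N, 3N) and b of shape (n_tx, 3N); the solution of A x = b[t]
    is the total field of transmitter t.  Shares the kernel definition
    with the FFT operator but assembles it by direct pairwise evaluation,
    which makes it a structurally independent reference path.
    """
    n = p.grid_n
    pts = voxel_centers(n, p.domain_side_m).reshape(-1, 3)
    N = pts.shape[0]
    k0 = array.k0
    V = p.voxel_size_m**3
    chi = (
        complex_permittivity(p.eps_grid, p.sigma_grid, array.omega) - background_eps_r
    ).reshape(-1)
    A = np.zeros((3 * N, 3 * N), dtype=np.complex128)
    for i in range(N):
        diff_mask = np.arange(N) != i
        Gi = greens_interaction(pts[i], pts[diff_mask], k0)  # (N-1, 3, 3)
        block = -(k0**2) * V * Gi * chi[diff_mask][:, None, None]
        A[3 * i : 3 * i + 3, :].reshape(3, N, 3)[:, diff_mask, :] = block.transpose(1, 0, 2)
        A[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += (1.0 + chi[i] / 3.0) * np.eye(3)
    _, einc = _antenna_voxel_green(array, n, p.domain_side_m)
    b = einc.reshape(array.n_antennas, -1)
    return A, b
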