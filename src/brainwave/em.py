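"""Free-space electromagnetic kernels: complex permittivity, the dyadic
Green's function and analytic point-dipole fields.

Time convention is ``exp(+j omega t)``, so outgoing waves carry
``exp(-j k R)`` and a lossy medium has a *negative* imaginary complex
relative permittivity.
"""

from __future__ import annotations

import numpy as np

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
MU0 = 1.25663706212e-6  # vacuum permeability, H/m
C0 = 299792458.0  # speed of light, m/s


def complex_permittivity(eps_r, sigma, omega: float):
    """Complex relative permittivity ``eps_r + sigma / (j omega eps0)``.

    Parameters
    ----------
    eps_r : array_like
        Relative permittivity, >= 1.
    sigma : array_like
        Conductivity in S/m, >= 0.
    omega : float
        Angular frequency in rad/s, > 0.

    Returns
    -------
    Complex relative permittivity with real part ``eps_r`` and imaginary
    part ``-sigma / (omega eps0)`` (exp(+j omega t) convention).
    """
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    eps_r = np.asarray(eps_r, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return eps_r - 1j * sigma / (omega * EPS0)


def scalar_green(r: np.ndarray, k0: float) -> np.ndarray:
    """Scalar free-space Green's function exp(-j k0 r) / (4 pi r)."""
    r = np.asarray(r, dtype=float)
    return np.exp(-1j * k0 * r) / (4.0 * np.pi * r)


def greens_interaction(r1, r2, k0: float) -> np.ndarray:
    """Free-space dyadic Green's function G(r1, r2) at wavenumber k0.

    ``G = (I + grad grad / k0^2) g`` with ``g = exp(-j k0 R)/(4 pi R)``,
    R = |r1 - r2|.  In closed form::

        G = g * [ (1 - j/(kR) - 1/(kR)^2) I
                  + (-1 + 3j/(kR) + 3/(kR)^2) RhatRhat ]

    The scattered field of a polarization density P is
    ``E_s(r) = k0^2 \\int G(r, r') chi(r') E(r') dr'``.

    Parameters are broadcast over leading axes; output shape is
    ``(..., 3, 3)``.  Coincident points raise ``ValueError`` (the singular
    self-term is handled separately by the solver).
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    dr = r1 - r2
    R = np.linalg.norm(dr, axis=-1)
    if np.any(R == 0):
        raise ValueError("greens_interaction is singular at coincident points")
    kR = k0 * R
    g = np.exp(-1j * kR) / (4.0 * np.pi * R)
    a = 1.0 - 1j / kR - 1.0 / kR**2
    b = -1.0 + 3j / kR + 3.0 / kR**2
    rhat = dr / R[..., None]
    eye = np.eye(3)
    outer = rhat[..., :, None] * rhat[..., None, :]
    return (g * a)[..., None, None] * eye + (g * b)[..., None, None] * outer


def dipole_field(src, axis, points, k0: float) -> np.ndarray:
    """Analytic E-field of an infinitesimal electric dipole at ``src``.

    The dipole axis is the unit vector ``axis``; amplitude is normalized so
    that ``E(r) = k0^2 G(r, src) . axis`` — the same kernel the scattering
    integral uses, which keeps incident and scattered fields mutually
    consistent and makes Lorentz reciprocity exact.  Includes all near-,
    intermediate- and far-field terms.

    Returns an array of shape ``(..., 3)`` over the observation ``points``.
    """
    points = np.asarray(points, dtype=float)
    src = np.asarray(src, dtype=float)
    axis = np.asarray(axis, dtype=float)
    G = greens_interaction(points, src, k0)
    return k0**2 * (G @ axis)
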