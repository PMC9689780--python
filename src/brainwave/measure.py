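"""Scattered-field measurement records, input aggregation and noise.

With 60 transceivers, each receiver hears the 59 other transmitters in
three Cartesian components: 3 x 60 x 59 = 10,620 raw complex measurements.
The network input aggregates these by summing, per receiver and component,
over all transmitters, giving M = 60 x 3 = 180 complex values stored as a
real vector of length 2M = 360 (first the 180 real parts, then the 180
imaginary parts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class ScatterRecord:
    """Complex scattered fields for all ordered (tx, rx) pairs.

    ``e_scat`` has shape (n, n-1, 3): entry ``[t, j]`` is the field at the
    j-th receiver of transmitter t's receiver list (all antennas except t,
    in increasing index order).  ``input_vec`` caches the aggregated 2M
    real input vector.
    """

    e_scat: np.ndarray  # (n, n-1, 3) complex
    frequency_hz: float
    noise_level_db: float | None = None
    input_vec: np.ndarray | None = None

    @property
    def n_antennas(self) -> int:
        return self.e_scat.shape[0]

    @property
    def n_measurements(self) -> int:
        return int(np.prod(self.e_scat.shape))


def receiver_indices(n: int, tx: int) -> np.ndarray:
    """Receiver antenna indices for transmitter ``tx`` (self excluded)."""
    return np.concatenate([np.arange(0, tx), np.arange(tx + 1, n)])


def full_matrix(rec: ScatterRecord) -> np.ndarray:
    """Expand e_scat to a dense (n, n, 3) array with zeros on the self
    pairs."""
    n = rec.n_antennas
    full = np.zeros((n, n, 3), dtype=complex)
    for t in range(n):
        full[t, receiver_indices(n, t)] = rec.e_scat[t]
    return full


def aggregate_inputs(rec: ScatterRecord) -> np.ndarray:
    """Sum fields over transmitters per (receiver, component) and return
    the length-2M real vector [Re..., Im...]."""
    if rec.e_scat.ndim != 3 or rec.e_scat.shape[2] != 3:
        raise ValueError("e_scat must have shape (n, n-1, 3)")
    if not np.all(np.isfinite(rec.e_scat)):
        raise ValueError("e_scat contains non-finite entries")
    s = full_matrix(rec).sum(axis=0)  # (n_rx, 3)
    flat = s.reshape(-1)  # rx-major, component minor
    return np.concatenate([flat.real, flat.imag])


def add_noise(rec: ScatterRecord, level_db: float | None, seed: int = 0) -> ScatterRecord:
    """Add complex circular white Gaussian noise at a relative power level.

    ``level_db`` is the noise-to-signal power ratio in dB over the whole
    measurement array: total noise power equals
    ``10**(level_db/10) * sum(|e_scat|^2)``.  ``None`` means no noise.
    The aggregated input vector is recomputed from the noisy fields.
    Deterministic given ``seed``.
    """
    if level_db is None:
        return replace(rec, input_vec=aggregate_inputs(rec))
    p_sig = float(np.sum(np.abs(rec.e_scat) ** 2))
    if p_sig == 0:
        raise ValueError("cannot add relative noise to an all-zero record")
    n_elem = rec.e_scat.size
    var = 10.0 ** (level_db / 10.0) * p_sig / n_elem  # per-element noise power
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((*rec.e_scat.shape, 2)) * np.sqrt(var / 2.0)
    noisy = rec.e_scat + noise[..., 0] + 1j * noise[..., 1]
    out = replace(rec, e_scat=noisy, noise_level_db=level_db)
    out.input_vec = aggregate_inputs(out)
    return out
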