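"""Tissue electrical-property tables for the 300 MHz imaging band.

The phantom generator assigns each nested tissue region a relative
permittivity ``eps_r`` and conductivity ``sigma`` (S/m).  The default table
below holds 16 brain-plausible values at 300 MHz (eps_r in [5, 80], sigma in
[0.1, 2.3] S/m), ordered from the outermost shell (skin) to the innermost
core.  It is a documented stand-in, overridable by configuration; no
frequency dispersion model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TissueTable:
    """Ordered tissue classes with electrical properties at one frequency.

    Entries are ordered outermost-to-innermost; the phantom generator nests
    region ``i+1`` strictly inside region ``i``.
    """

    entries: tuple[tuple[str, float, float], ...]  # (name, eps_r, sigma S/m)
    frequency_hz: float = 300e6

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("tissue names must be unique")
        for name, eps_r, sigma in self.entries:
            if eps_r < 1:
                raise ValueError(f"tissue {name!r}: eps_r must be >= 1, got {eps_r}")
            if sigma < 0:
                raise ValueError(f"tissue {name!r}: sigma must be >= 0, got {sigma}")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def eps_r(self) -> list[float]:
        return [e[1] for e in self.entries]

    @property
    def sigma(self) -> list[float]:
        return [e[2] for e in self.entries]


#: Default 16-tissue table at 300 MHz, outermost to innermost.
DEFAULT_TISSUES: tuple[tuple[str, float, float], ...] = (
    ("skin", 49.0, 0.64),
    ("fat", 5.5, 0.10),
    ("muscle", 58.0, 0.77),
    ("cortical_bone", 13.0, 0.12),
    ("bone_marrow", 5.8, 0.10),
    ("dura", 46.0, 0.83),
    ("csf", 72.0, 2.22),
    ("grey_matter", 60.0, 0.69),
    ("white_matter", 44.0, 0.41),
    ("cerebellum", 59.0, 0.97),
    ("brain_stem", 42.0, 0.45),
    ("thalamus", 57.0, 0.75),
    ("hippocampus", 58.0, 0.78),
    ("ventricle", 70.0, 2.10),
    ("corpus_callosum", 40.0, 0.38),
    ("blood_pool", 65.0, 1.32),
)


def default_tissue_table(frequency_hz: float = 300e6) -> TissueTable:
    """Return the default 16-tissue table at the given operating frequency."""
    return TissueTable(entries=DEFAULT_TISSUES, frequency_hz=frequency_hz)
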