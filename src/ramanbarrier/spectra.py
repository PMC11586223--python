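"""In-memory containers for Raman and impedance spectra.

A :class:`RamanSpectrum` is a single acquisition: an ascending wavenumber
grid (cm^-1), one intensity per channel, and provenance metadata (damage
class, membrane, spot).  An :class:`ImpedanceSpectrum` is a swept-frequency
complex impedance record (ohm*cm^2, area-normalised).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The four damage classes: intact epithelium, 2 h / 4 h calcium-chelator
#: (EGTA) treatment, and cell-free (blank) membrane.
CLASSES = ("T0", "T2", "T4", "BLANK")


@dataclass
class RamanSpectrum:
    """One single-point Raman acquisition.

    Parameters
    ----------
    wavenumbers
        Strictly increasing grid in cm^-1.
    intensities
        Detector counts / arbitrary units, same length as the grid.
    label
        Damage class, one of :data:`CLASSES`, or ``None`` for unlabelled data.
    membrane_id
        Biological sample (transwell membrane) the spot was acquired from.
        Blank-area acquisitions may carry no membrane id.
    spot_id
        Acquisition spot identifier within the membrane/time point.
    stages
        Names of preprocessing stages already applied, in order.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str | None = None
    membrane_id: str | None = None
    spot_id: str | None = None
    stages: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"grid/intensity length mismatch: "
                f"{self.wavenumbers.size} != {self.intensities.size}"
            )
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 channels")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASSES}")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def spectrum_id(self) -> str:
        """Stable identifier built from provenance metadata."""
        return f"{self.label or 'NA'}:{self.membrane_id or '-'}:{self.spot_id or '-'}"

    def with_intensities(self, intensities: np.ndarray, stage: str | None = None) -> "RamanSpectrum":
        """Copy with new intensities on the same grid, optionally recording a stage."""
        stages = self.stages + (stage,) if stage else self.stages
        return replace(self, intensities=np.asarray(intensities, dtype=float), stages=stages)

    def channel_index(self, wavenumber: float) -> int:
        """Index of the grid channel nearest ``wavenumber`` (must be in range)."""
        wn = self.wavenumbers
        if not (wn[0] <= wavenumber <= wn[-1]):
            raise ValueError(
                f"wavenumber {wavenumber} outside grid range [{wn[0]}, {wn[-1]}]"
            )
        return int(np.argmin(np.abs(wn - wavenumber)))


@dataclass
class ImpedanceSpectrum:
    """Complex impedance vs frequency, area-normalised (ohm*cm^2)."""

    frequencies: np.ndarray
    impedance: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if self.frequencies.size != self.impedance.size:
            raise ValueError("frequency/impedance length mismatch")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if not (np.all(np.isfinite(self.frequencies)) and np.all(np.isfinite(self.impedance))):
            raise ValueError("non-finite values in impedance spectrum")

    def __len__(self) -> int:
        return int(self.frequencies.size)
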