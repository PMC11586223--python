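"""Peak detection and molecular assignment for preprocessed spectra.

Finds the top-N local maxima of a normalised spectrum by prominence and
matches them against a reference band library.  A library entry spanning a
range (e.g. 852-858 cm^-1) matches by distance to the nearest point of the
range; ties between entries are broken toward the smaller centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .library import CELL_PEAKS, SUBSTRATE_PEAKS, PeakDef
from .spectra import RamanSpectrum

#: Minimum prominence (normalised units) for a maximum to count as a peak.
MIN_PROMINENCE = 0.01


@dataclass(frozen=True)
class Peak:
    """A detected spectral peak: apex position, height and prominence."""

    center: float
    height: float
    prominence: float


@dataclass(frozen=True)
class PeakLibrary:
    """Reference bands to assign detected peaks to.

    ``tolerance`` (cm^-1) is the maximum distance from a band's range for a
    match; beyond it a peak stays unassigned.
    """

    entries: tuple[PeakDef, ...] = field(
        default_factory=lambda: CELL_PEAKS + SUBSTRATE_PEAKS
    )
    tolerance: float = 5.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("library must be non-empty")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        centers = [e.center for e in self.entries]
        if len(set(centers)) != len(centers):
            raise ValueError("duplicate band centres in library")


def detect_top_peaks(s: RamanSpectrum, n_top: int = 20) -> list[Peak]:
    """Local maxima of a preprocessed spectrum, ranked by prominence.

    Returns at most ``n_top`` peaks with prominence >= ``MIN_PROMINENCE``,
    sorted by centre wavenumber.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    idx, props = find_peaks(s.intensities, prominence=MIN_PROMINENCE)
    if idx.size == 0:
        return []
    order = np.argsort(props["prominences"])[::-1][:n_top]
    chosen = sorted(order, key=lambda k: idx[k])
    return [
        Peak(
            center=float(s.wavenumbers[idx[k]]),
            height=float(s.intensities[idx[k]]),
            prominence=float(props["prominences"][k]),
        )
        for k in chosen
    ]


def assign_peaks(
    peaks: list[Peak], library: PeakLibrary | None = None
) -> list[tuple[Peak, str | None]]:
    """Match each peak to the nearest library band within tolerance.

    Distance to a range entry is measured to the nearest point of the range;
    exact-distance ties go to the entry with the smaller centre.  Peaks with
    no band within tolerance are returned with assignment ``None``.
    """
    library = library or PeakLibrary()
    entries = sorted(library.entries, key=lambda e: e.center)
    out: list[tuple[Peak, str | None]] = []
    for peak in peaks:
        best: PeakDef | None = None
        best_d = np.inf
        for entry in entries:
            d = entry.distance(peak.center)
            if d < best_d:  # strict: earlier (smaller-centre) entry wins ties
                best, best_d = entry, d
        if best is not None and best_d <= library.tolerance:
            out.append((peak, best.assignment))
        else:
            out.append((peak, None))
    return out
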