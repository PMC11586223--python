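"""Reference library of Raman band assignments for Caco-2 epithelial cells.

Each entry records the literature band position (a single wavenumber or a
narrow range, cm^-1), its molecular assignment, the cellular compartment the
band is characteristic of, and whether the band reports on tight-junction /
cell-adhesion structures (and hence fades as the junctions are disassembled
by calcium depletion).

The same entries drive the synthetic-spectrum generator (band positions and
relative intensities) and peak assignment, so planted peaks and recovered
assignments share one source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass

INTERCELLULAR = "intercellular"
INTRACELLULAR = "intracellular"
SUBSTRATE = "substrate"


@dataclass(frozen=True)
class PeakDef:
    """One Raman band: position, shape, intensity and biological role.

    ``low``/``high`` delimit the literature position (equal for single-valued
    bands); ``center`` is their midpoint and is where the generator plants
    the band.  ``tj_sensitive`` bands are attenuated by junction damage.
    """

    low: float
    high: float
    base_amplitude: float
    compartment: str
    tj_sensitive: bool
    assignment: str
    width: float = 6.0  # Gaussian sigma, cm^-1

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValueError("band range inverted")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if self.compartment not in (INTERCELLULAR, INTRACELLULAR, SUBSTRATE):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def distance(self, wavenumber: float) -> float:
        """Distance from ``wavenumber`` to the nearest point of the band range."""
        if wavenumber < self.low:
            return self.low - wavenumber
        if wavenumber > self.high:
            return wavenumber - self.high
        return 0.0


def _p(low, high, amp, compartment, tj, assignment):
    return PeakDef(low, high, amp, compartment, tj, assignment)


#: Band assignments for the 500-2000 cm^-1 fingerprint region.  Intercellular
#: (junction-area) bands are tight-junction sensitive; the 1035/1230/1298
#: protein/lipid bands are present at junction spots but persist through
#: damage.  Relative amplitudes encode the qualitative intensity pattern of
#: averaged Caco-2 spectra: phenylalanine 1003 and the E-cadherin-associated
#: 1080 band dominate their neighbourhoods.
CELL_PEAKS: tuple[PeakDef, ...] = (
    _p(621, 621, 0.40, INTRACELLULAR, False, "Phenylalanine"),
    _p(667, 669, 0.30, INTRACELLULAR, False, "Cystine (collagen type I), nucleic acids T and G"),
    _p(671, 671, 0.30, INTERCELLULAR, True, "Nucleic acids T and G"),
    _p(678, 678, 0.30, INTERCELLULAR, True, "Ring breathing modes in the DNA bases"),
    _p(729, 729, 0.35, INTRACELLULAR, False, "Nucleic acids A"),
    _p(742, 742, 0.35, INTRACELLULAR, False, "DNA, tryptophan"),
    _p(815, 815, 0.35, INTERCELLULAR, True, "Proline, hydroxyproline, tyrosine, PO2- stretch"),
    _p(852, 858, 0.60, INTERCELLULAR, True, "Proline, hydroxyproline, tyrosine"),
    _p(860, 860, 0.40, INTRACELLULAR, False, "Phosphate group"),
    _p(893, 893, 0.30, INTRACELLULAR, False, "Phosphodiester, deoxyribose"),
    _p(920, 920, 0.40, INTERCELLULAR, True, "Proline ring, glucose, lactic acid"),
    _p(928, 928, 0.35, INTRACELLULAR, False, "Proline and valine"),
    _p(937, 938, 0.50, INTERCELLULAR, True, "Proline, hydroxyproline"),
    _p(1003, 1003, 1.00, INTRACELLULAR, False, "Phenylalanine"),
    _p(1035, 1035, 0.30, INTERCELLULAR, False, "Collagen"),
    _p(1053, 1053, 0.45, INTERCELLULAR, True, "C-O stretching, C-N stretching (proteins)"),
    _p(1080, 1080, 1.00, INTERCELLULAR, True, "E-cadherin"),
    _p(1090, 1090, 0.35, INTERCELLULAR, True, "PO2- stretch"),
    _p(1230, 1230, 0.45, INTERCELLULAR, False, "Amide III"),
    _p(1298, 1298, 0.50, INTERCELLULAR, False, "Fatty acids, CH2 deformation"),
    _p(1614, 1614, 0.70, INTERCELLULAR, True, "Tyrosine"),
)

#: Generic bands of the blank polymer (PET) membrane substrate.  Positions are
#: kept clear of the junction bands; they are a synthetic stand-in, the study
#: system never characterises the blank membrane quantitatively.
SUBSTRATE_PEAKS: tuple[PeakDef, ...] = (
    _p(1130, 1130, 0.50, SUBSTRATE, False, "Substrate (polymer backbone)"),
    _p(1730, 1730, 0.80, SUBSTRATE, False, "Substrate (ester C=O)"),
)

#: Notable positions used throughout: phenylalanine ring-breathing mode and
#: the E-cadherin-associated band.
PHENYLALANINE_CM1 = 1003.0
ECADHERIN_CM1 = 1080.0
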