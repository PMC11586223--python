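"""Synthetic Raman datasets and impedance spectra with the statistical
structure of a barrier-damage study.

The generator emulates a study design in which single-point Raman spectra
are acquired at intercellular (tight-junction) spots on epithelial
monolayers grown on transwell membranes, before and after calcium-chelator
(EGTA) damage, plus spectra of blank membrane areas:

* junction-sensitive bands are attenuated as damage progresses
  (``damage_attenuation``: T0 > T2 > T4),
* at the 4 h time point the laser occasionally lands on a "hole" where cells
  have detached and the signal is dominated by the bare substrate
  (``hole_probability``), which makes heavily damaged spectra resemble blank
  ones,
* each membrane carries its own multiplicative gain and wavenumber
  calibration offset (batch effects), drawn once per membrane,
* spots within a membrane differ biologically: per-spot signal gain,
  per-band amplitude jitter and per-spot damage heterogeneity (chelator
  damage is spatially patchy; undamaged monolayers are uniform), so the
  2 h and 4 h populations overlap while the intact class stays tight,
* every spectrum gets a broad decaying fluorescence background, additive
  detector noise and occasional cosmic-ray spikes.

All randomness flows from one root seed through per-membrane substreams, so
regenerating with more spots leaves existing membranes' spectra unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .library import CELL_PEAKS, SUBSTRATE_PEAKS, INTERCELLULAR, INTRACELLULAR, PeakDef
from .spectra import CLASSES, ImpedanceSpectrum, RamanSpectrum
from .teer import CircuitParams, circuit_impedance

TREATED_CLASSES = ("T0", "T2", "T4")


@dataclass(frozen=True)
class StudyDesign:
    """Acquisition plan: membranes x spots x time points, plus blank areas.

    Defaults reproduce a 3-membrane, 20-spot, 3-time-point design with 40
    blank-area spectra (220 spectra total) on a 500-2000 cm^-1 grid at
    1 cm^-1 spacing.
    """

    n_membranes: int = 3
    n_spots_per_timepoint: int = 20
    timepoints: tuple[str, ...] = TREATED_CLASSES
    n_blank_spectra: int = 40
    grid: tuple[float, float, float] = (500.0, 2000.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_membranes < 1 or self.n_spots_per_timepoint < 1:
            raise ValueError("need at least one membrane and one spot")
        if self.n_blank_spectra < 0:
            raise ValueError("n_blank_spectra must be >= 0")
        lo, hi, step = self.grid
        if not (lo < hi and step > 0):
            raise ValueError("grid must satisfy min < max and step > 0")
        unknown = set(self.timepoints) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown timepoint labels {sorted(unknown)}")

    @property
    def total_spectra(self) -> int:
        return (
            self.n_membranes * self.n_spots_per_timepoint * len(self.timepoints)
            + self.n_blank_spectra
        )

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + 0.5 * step, step)


@dataclass(frozen=True)
class GeneratorParams:
    """Physical/instrumental knobs of the synthetic-spectrum model.

    ``damage_attenuation`` multiplies junction-sensitive band amplitudes per
    class and must be strictly decreasing T0 > T2 > T4 (blank membranes have
    no cell signal at all).  ``intracellular_bleed`` scales intracellular
    bands observed at intercellular spots (the laser spot samples some
    cytoplasm).  ``hole_probability`` is the per-spot chance at T4 that the
    acquisition lands on exposed substrate, in which case the cell fraction
    drops to ``hole_cell_fraction``.

    Three lognormal spreads model biological heterogeneity between
    acquisition spots (the per-spot standard deviation visible around
    averaged cell spectra): ``spot_amplitude_sd`` scales the whole cellular
    signal of a spot, ``band_amplitude_sd`` jitters each band independently,
    and ``damage_heterogeneity_sd`` spreads the per-spot damage *extent*
    (the attenuation is raised to a lognormal exponent) — chelator damage
    progresses as spatial hot spots, so the 2 h and 4 h spot populations
    partially overlap while undamaged spots are unaffected.
    """

    damage_attenuation: dict = field(
        default_factory=lambda: {"T0": 1.0, "T2": 0.5, "T4": 0.2}
    )
    hole_probability: float = 0.3
    hole_cell_fraction: float = 0.2
    intracellular_bleed: float = 0.3
    spot_amplitude_sd: float = 0.15
    band_amplitude_sd: float = 0.2
    damage_heterogeneity_sd: float = 0.35
    membrane_amplitude_sd: float = 0.15
    membrane_shift_sd: float = 1.0
    baseline_b0: float = 0.2
    baseline_b1: float = 2.0
    baseline_tau: float = 700.0
    noise_sd: float = 0.02
    cosmic_ray_rate: float = 0.1
    cosmic_ray_amplitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        att = self.damage_attenuation
        missing = [c for c in TREATED_CLASSES if c not in att]
        if missing:
            raise ValueError(f"damage_attenuation missing classes {missing}")
        if not (att["T0"] > att["T2"] > att["T4"]):
            raise ValueError("damage_attenuation must be strictly decreasing T0 > T2 > T4")
        if not (0.0 <= self.hole_probability <= 1.0):
            raise ValueError("hole_probability must be in [0, 1]")
        for name in ("spot_amplitude_sd", "band_amplitude_sd",
                     "damage_heterogeneity_sd", "membrane_amplitude_sd",
                     "membrane_shift_sd", "noise_sd", "cosmic_ray_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def clean(self) -> "GeneratorParams":
        """Copy with background, noise, spikes and batch effects switched off."""
        return GeneratorParams(
            damage_attenuation=dict(self.damage_attenuation),
            hole_probability=0.0,
            hole_cell_fraction=self.hole_cell_fraction,
            intracellular_bleed=self.intracellular_bleed,
            spot_amplitude_sd=0.0,
            band_amplitude_sd=0.0,
            damage_heterogeneity_sd=0.0,
            membrane_amplitude_sd=0.0,
            membrane_shift_sd=0.0,
            baseline_b0=0.0,
            baseline_b1=0.0,
            baseline_tau=self.baseline_tau,
            noise_sd=0.0,
            cosmic_ray_rate=0.0,
            cosmic_ray_amplitude=self.cosmic_ray_amplitude,
            seed=self.seed,
        )


def _gaussian(wn: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wn - center) / sigma) ** 2)


def cell_signal(
    wn: np.ndarray,
    label: str,
    params: GeneratorParams,
    shift: float = 0.0,
    peaks: tuple[PeakDef, ...] = CELL_PEAKS,
    damage_exponent: float = 1.0,
    band_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Cellular Raman signal at an intercellular spot (noise-free mean when
    the jitter arguments are left at their defaults).

    Junction-sensitive bands are scaled by
    ``damage_attenuation[label] ** damage_exponent``; the exponent is the
    per-spot damage-heterogeneity draw, so undamaged spots (attenuation 1)
    are unaffected while damaged classes spread.  Intracellular bands appear
    at the bleed fraction; ``band_factors`` multiplies each band
    individually.
    """
    if label not in TREATED_CLASSES:
        raise ValueError(f"no cell signal defined for label {label!r}")
    att = params.damage_attenuation[label] ** damage_exponent
    out = np.zeros_like(wn)
    for i, p in enumerate(peaks):
        amp = p.base_amplitude
        if band_factors is not None:
            amp *= band_factors[i]
        if p.compartment == INTRACELLULAR:
            amp *= params.intracellular_bleed
        elif p.compartment != INTERCELLULAR:
            continue
        if p.tj_sensitive:
            amp *= att
        out += amp * _gaussian(wn, p.center + shift, p.width)
    return out


def substrate_signal(wn: np.ndarray, shift: float = 0.0) -> np.ndarray:
    """Noise-free spectrum of the bare polymer membrane."""
    out = np.zeros_like(wn)
    for p in SUBSTRATE_PEAKS:
        out += p.base_amplitude * _gaussian(wn, p.center + shift, p.width)
    return out


def fluorescence_baseline(wn: np.ndarray, params: GeneratorParams) -> np.ndarray:
    """Broad decaying autofluorescence background: b0 + b1*exp(-(v-v0)/tau)."""
    return params.baseline_b0 + params.baseline_b1 * np.exp(
        -(wn - wn[0]) / params.baseline_tau
    )


def generate_spectrum(
    label: str,
    membrane_effect: tuple[float, float],
    params: GeneratorParams,
    rng: np.random.Generator,
    design: StudyDesign | None = None,
    membrane_id: str | None = None,
    spot_id: str | None = None,
) -> RamanSpectrum:
    """Simulate one acquisition of the given damage class.

    ``membrane_effect`` is the (gain, wavenumber shift) pair of the membrane
    the spot sits on.  The cell fraction is 1 for T0/T2, 0 for BLANK, and
    drops to ``hole_cell_fraction`` at T4 with probability
    ``hole_probability`` (laser on exposed substrate).
    """
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    design = design or StudyDesign()
    wn = design.wavenumbers()
    gain, shift = membrane_effect

    if label == "BLANK":
        f_cell = 0.0
    elif (
        label == "T4"
        and params.hole_probability > 0
        and rng.random() < params.hole_probability
    ):
        # hole sizes vary relative to the laser spot: residual cell signal
        # anywhere from none to hole_cell_fraction of a confluent spot
        f_cell = params.hole_cell_fraction * rng.random()
    else:
        f_cell = 1.0

    y = np.zeros_like(wn)
    if f_cell > 0:
        spot_gain = float(np.exp(rng.normal(0.0, params.spot_amplitude_sd)))
        damage_exp = float(np.exp(rng.normal(0.0, params.damage_heterogeneity_sd)))
        band_factors = np.exp(
            rng.normal(0.0, params.band_amplitude_sd, size=len(CELL_PEAKS))
        )
        y += gain * f_cell * spot_gain * cell_signal(
            wn, label, params, shift=shift,
            damage_exponent=damage_exp, band_factors=band_factors,
        )
    y += (1.0 - f_cell) * substrate_signal(wn, shift=shift)
    y += fluorescence_baseline(wn, params)
    if params.noise_sd > 0:
        y += rng.normal(0.0, params.noise_sd, size=wn.size)
    if params.cosmic_ray_rate > 0:
        n_spikes = rng.poisson(params.cosmic_ray_rate)
        if n_spikes:
            idx = rng.integers(0, wn.size, size=n_spikes)
            y[idx] += params.cosmic_ray_amplitude * np.max(y)
    return RamanSpectrum(
        wavenumbers=wn,
        intensities=y,
        label=label,
        membrane_id=membrane_id,
        spot_id=spot_id,
    )


def generate_dataset(
    design: StudyDesign | None = None,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> list[RamanSpectrum]:
    """Simulate a full study: all membranes, time points and blank areas.

    Returns exactly ``design.total_spectra`` spectra.  One seed substream
    per membrane (plus one for the blanks) keeps membranes independent:
    enlarging ``n_spots_per_timepoint`` never changes other membranes.
    """
    design = design or StudyDesign()
    params = params or GeneratorParams()
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    streams = root.spawn(design.n_membranes + 1)

    dataset: list[RamanSpectrum] = []
    for m in range(design.n_membranes):
        # child streams: one for the membrane effects, one per time point,
        # so adding spots or time points never perturbs existing draws
        children = streams[m].spawn(1 + len(design.timepoints))
        effect_rng = np.random.default_rng(children[0])
        gain = float(np.exp(effect_rng.normal(0.0, params.membrane_amplitude_sd)))
        shift = float(effect_rng.normal(0.0, params.membrane_shift_sd))
        membrane_id = f"M{m + 1}"
        for t, label in enumerate(design.timepoints):
            rng = np.random.default_rng(children[1 + t])
            for s in range(design.n_spots_per_timepoint):
                dataset.append(
                    generate_spectrum(
                        label, (gain, shift), params, rng,
                        design=design, membrane_id=membrane_id,
                        spot_id=f"{label}-{s + 1:02d}",
                    )
                )
    blank_rng = np.random.default_rng(streams[-1])
    for s in range(design.n_blank_spectra):
        dataset.append(
            generate_spectrum(
                "BLANK", (1.0, 0.0), params, blank_rng,
                design=design, membrane_id=None, spot_id=f"B-{s + 1:02d}",
            )
        )
    return dataset


DEFAULT_FREQUENCIES = np.logspace(0, 5, 50)  # 1 Hz - 100 kHz


def generate_impedance(
    circuit: CircuitParams,
    frequencies: np.ndarray | None = None,
    noise_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
    condition: str | None = None,
) -> ImpedanceSpectrum:
    """Impedance spectrum of a barrier equivalent circuit, with optional
    proportional complex Gaussian noise (``noise_fraction`` of |Z| per point).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    f = DEFAULT_FREQUENCIES if frequencies is None else np.asarray(frequencies, float)
    z = circuit_impedance(circuit, f)
    if noise_fraction > 0:
        rng = rng or np.random.default_rng()
        scale = noise_fraction * np.abs(z) / np.sqrt(2.0)
        z = z + scale * (rng.normal(size=f.size) + 1j * rng.normal(size=f.size))
    return ImpedanceSpectrum(frequencies=f, impedance=z, condition=condition)
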