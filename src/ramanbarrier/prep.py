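"""Spectral preprocessing chain for Raman acquisitions.

Four stages, applied in a fixed order:

i.   cosmic-ray (spike) removal — modified z-score of the second difference,
     flagged channels replaced by linear interpolation;
ii.  Savitzky-Golay smoothing (default window 51, order 2);
iii. asymmetric-least-squares (AsLS) baseline estimation and subtraction,
     removing the broad autofluorescence background;
iv.  normalisation to the global maximum.

AsLS solves, per iteration,

    min_z  sum_i w_i (y_i - z_i)^2 + lambda * sum (Delta^2 z)^2

with asymmetric weights w_i = p where y_i > z_i and (1 - p) otherwise, so
the smooth estimate hugs the lower envelope of the spectrum and leaves the
peaks above it.  The penalised system is symmetric pentadiagonal and is
solved with a banded Cholesky factorisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .spectra import RamanSpectrum


@dataclass(frozen=True)
class PrepConfig:
    """Tunables of the preprocessing chain.

    The Savitzky-Golay window is in grid points and must be odd; the AsLS
    smoothness weight ``asls_lambda`` (default 1e4) and asymmetry ``asls_p``
    control how stiff the baseline is and how strongly positive residuals
    (peaks) are down-weighted.
    """

    spike_z_threshold: float = 7.0
    sg_window: int = 51
    sg_order: int = 2
    asls_lambda: float = 1e4
    asls_p: float = 0.001
    asls_iterations: int = 10

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError(
                f"sg_window must be odd and > sg_order; got window={self.sg_window}, "
                f"order={self.sg_order} (nearest valid window: {self.sg_window + 1})"
            )
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be > 0")
        if not (0 < self.asls_p < 1):
            raise ValueError("asls_p must be in (0, 1)")
        if self.asls_iterations < 1:
            raise ValueError("asls_iterations must be >= 1")
        if self.spike_z_threshold <= 0:
            raise ValueError("spike_z_threshold must be > 0")


@dataclass
class SpikeReport:
    """Channels replaced by the despiking stage."""

    indices: list

    @property
    def n_spikes(self) -> int:
        return len(self.indices)


@dataclass
class BaselineResult:
    """AsLS output; ``corrected + baseline`` reproduces the input exactly."""

    baseline: np.ndarray
    corrected: np.ndarray
    iterations_used: int


def remove_cosmic_rays(
    s: RamanSpectrum, z_threshold: float = 7.0
) -> tuple[RamanSpectrum, SpikeReport]:
    """Replace cosmic-ray spikes by linear interpolation.

    A channel is a spike when the modified z-score (median/MAD) of the
    second difference centred on it exceeds ``z_threshold``.  The MAD is
    floored at a small fraction of the intensity range so that the smooth
    curvature of a noiseless spectrum is never mistaken for a spike — a
    cosmic ray must stand out both against the noise and in absolute terms.
    Spikes are replaced by interpolating the flanking non-spike channels;
    everything else is untouched.
    """
    y = s.intensities
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 channels to despike")
    d2 = np.diff(y, 2)  # d2[k] is centred on channel k+1
    med = np.median(d2)
    span = float(np.ptp(y))
    mad = max(np.median(np.abs(d2 - med)), 5e-3 * span)
    if mad == 0:  # perfectly constant spectrum
        z = np.zeros_like(d2)
    else:
        z = 0.6745 * (d2 - med) / mad
    flagged = np.where(np.abs(z) > z_threshold)[0] + 1
    if flagged.size == 0:
        return s.with_intensities(y, stage="despiked"), SpikeReport(indices=[])
    good = np.setdiff1d(np.arange(n), flagged)
    if good.size == 0:
        raise ValueError("every channel flagged as a spike: pathological input")
    cleaned = y.copy()
    cleaned[flagged] = np.interp(flagged, good, y[good])
    return s.with_intensities(cleaned, stage="despiked"), SpikeReport(
        indices=flagged.tolist()
    )


def smooth_savgol(s: RamanSpectrum, window: int = 51, order: int = 2) -> RamanSpectrum:
    """Savitzky-Golay local polynomial smoothing (mirror edge padding)."""
    if window % 2 == 0:
        raise ValueError(
            f"Savitzky-Golay window must be odd; got {window} "
            f"(use {window + 1} or {window - 1})"
        )
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    if window > len(s):
        raise ValueError(f"window {window} larger than spectrum ({len(s)} channels)")
    smoothed = savgol_filter(s.intensities, window, order, mode="mirror")
    return s.with_intensities(smoothed, stage="smoothed")


def _second_difference_penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper banded form (3, n) of lam * D2'D2 with D2 the (n-2, n) second
    difference operator."""
    diag = np.full(n, 6.0)
    diag[[0, -1]] = 1.0
    if n > 2:
        diag[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.ones(n - 2)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * off2
    ab[1, 1:] = lam * off1
    ab[2, :] = lam * diag
    return ab


def baseline_asls(
    s: RamanSpectrum,
    lam: float = 1e4,
    p: float = 0.001,
    n_iter: int = 10,
) -> BaselineResult:
    """Asymmetric-least-squares baseline estimate.

    Iterates the penalised weighted least-squares solve with weight updates
    (p above the baseline, 1-p below) for ``n_iter`` iterations or until the
    weights stop changing.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    y = s.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    n = y.size
    penalty = _second_difference_penalty_bands(n, lam)
    w = np.ones(n)
    z = y.copy()
    iterations_used = 0
    for _ in range(n_iter):
        ab = penalty.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        iterations_used += 1
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return BaselineResult(baseline=z, corrected=y - z, iterations_used=iterations_used)


def normalize_max(s: RamanSpectrum) -> RamanSpectrum:
    """Divide intensities by their global maximum (which becomes 1)."""
    peak = float(np.max(s.intensities))
    if peak <= 0:
        raise ValueError("maximum intensity must be positive to normalise")
    return s.with_intensities(s.intensities / peak, stage="normalized")


def preprocess(s: RamanSpectrum, config: PrepConfig | None = None) -> RamanSpectrum:
    """Full chain: despike -> smooth -> baseline-correct -> max-normalise."""
    config = config or PrepConfig()
    out, _report = remove_cosmic_rays(s, config.spike_z_threshold)
    window = min(config.sg_window, len(out) if len(out) % 2 else len(out) - 1)
    if window != config.sg_window:
        warnings.warn(
            f"Savitzky-Golay window reduced to {window} for a {len(out)}-channel spectrum"
        )
    out = smooth_savgol(out, window, config.sg_order)
    result = baseline_asls(out, config.asls_lambda, config.asls_p, config.asls_iterations)
    out = out.with_intensities(result.corrected, stage="baseline_corrected")
    return normalize_max(out)


def preprocess_dataset(
    dataset: list[RamanSpectrum], config: PrepConfig | None = None
) -> list[RamanSpectrum]:
    """Apply :func:`preprocess` to every spectrum of a dataset."""
    config = config or PrepConfig()
    return [preprocess(s, config) for s in dataset]
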