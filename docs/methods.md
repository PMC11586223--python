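# Methods

## The measurement being emulated

Single-point Raman spectra (500–2000 cm⁻¹, 1 cm⁻¹ grid) acquired at
intercellular spots of an epithelial monolayer on a transwell membrane, at
three damage states — intact (T0), 2 h and 4 h of calcium-chelator exposure
(T2, T4) — plus spectra of blank membrane areas. The default study design is
3 membranes × 20 spots × 3 time points + 40 blanks = 220 spectra. The
companion measurement is swept-frequency impedance (1 Hz–100 kHz) of the
same barrier, from which TEER is extracted by circuit fitting.

## Synthetic-data model

A spectrum is

```
I(ν) = g_m · f_cell · g_spot · Σ_p a_p b_p att(p, class)^e_spot · G(ν − s_m; c_p, σ_p)
     + (1 − f_cell) · substrate(ν − s_m) + baseline(ν) + ε(ν) + spikes
```

* **Bands.** Gaussian lines (σ = 6 cm⁻¹) at the positions of a curated
  assignment library for epithelial cells (21 cellular bands, 621–1614 cm⁻¹;
  range entries such as 852–858 are planted at their midpoint). Bands are
  tagged by compartment; intracellular bands appear at intercellular spots
  at a bleed factor of 0.3 (the laser volume samples some cytoplasm), which
  is why phenylalanine (1003, 621 cm⁻¹) features appear in junction-area
  data. Relative amplitudes encode the qualitative intensity pattern of
  averaged epithelial spectra; the E-cadherin-associated 1080 band (1.0) is
  dominant over its 1090 neighbour (0.35) so its apex survives band overlap
  within one grid step.
* **Damage.** Junction-sensitive bands (the ten intercellular bands) are
  attenuated per class: `att = 1.0 / 0.5 / 0.2` for T0/T2/T4. Chelator
  damage is spatially patchy ("hot spots"), so each spot raises the class
  attenuation to a lognormal exponent `e_spot = exp(N(0, 0.35))`: the intact
  class (att = 1) is unaffected, while the T2 and T4 spot populations
  spread and partially overlap — the cluster structure a classifier of real
  damage data has to cope with.
* **Holes.** At T4, with probability 0.3, the acquisition lands on a region
  where cells have detached: the cell fraction `f_cell` drops to
  `U(0, 0.2)` of confluence (hole sizes vary relative to the laser spot;
  some spots are fully bare) and the substrate spectrum dominates. This is
  what makes heavy damage confusable with blank membrane. Blanks have
  `f_cell = 0` exactly.
* **Batch effects.** Each membrane draws a gain `exp(N(0, 0.15))` and a
  wavenumber calibration offset `N(0, 1 cm⁻¹)` once; spots add a gain
  `exp(N(0, 0.15))` and independent per-band jitter `exp(N(0, 0.2))`.
* **Background and noise.** Fluorescence baseline
  `0.2 + 2.0·exp(−(ν−500)/700)` (broad, decaying, several times the band
  amplitudes — the raw spectra are background-dominated, as real cell
  spectra are); additive white noise σ = 0.02; cosmic-ray spikes at
  0.1/spectrum, amplitude 5× the spectrum maximum. The substrate (bare
  polymer membrane) is modelled as two generic bands at 1130 and
  1730 cm⁻¹ — deliberately clear of the junction bands, so damage
  monotonicity is a property of the cell signal rather than of substrate
  overlap.
* **Randomness.** One root seed; per-membrane substreams, and within a
  membrane one substream per time point, so enlarging the design never
  perturbs draws it shares with a smaller design.

`GeneratorParams.clean()` switches off background, noise, spikes and all
heterogeneity; it is the reference condition for exactness tests
(band positions, attenuation factors, monotone damage ordering).

**What the generator does not emulate:** wavelength-dependent detector
response, shot-noise scaling with intensity, spatial correlation between
neighbouring spots, focus drift within a time series, water/medium
background structure, and any real chemical variation beyond band-amplitude
jitter. Passing tests therefore demonstrate that the *pipeline* behaves
correctly on data with the study's statistical structure — not that the
classifier would reach these accuracies on real spectra.

## Preprocessing

Stages run in a fixed order (despike → smooth → baseline → normalise);
every stage preserves the wavenumber grid.

* **Despiking.** A channel is a spike when the modified z-score
  (0.6745·(x − median)/MAD) of the second difference centred on it exceeds
  7. The MAD is floored at 0.5% of the intensity range: without the floor
  the statistic diverges on smooth noiseless spectra (MAD → 0) and flags
  every band apex. Flagged channels are linearly interpolated from flanking
  clean channels. The operation is a fixed point on data it has cleaned.
* **Savitzky–Golay.** Window 51 points, order 2, mirror padding. A window
  of 50 is the nearest even equivalent and is rejected with guidance (SG
  windows must be odd). Exact on polynomials of degree ≤ 2 away from the
  edge half-windows. Note the window (51 points) is wide relative to the
  bands (σ = 6): each pass attenuates narrow bands, so the chain is only
  approximately idempotent (a second full pass moves a typical spectrum by
  ~3% RMS; the suite asserts < 5%).
* **AsLS baseline.** Minimises Σ wᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)² with asymmetric
  weights (p = 0.001 above the baseline, 1−p below), λ = 10⁴ ("smoothing
  factor 4" on the common log₁₀ slider convention), 10 iterations or until
  the weights stabilise. The normal equations are symmetric pentadiagonal
  and solved by banded Cholesky (`scipy.linalg.solveh_banded`); the test
  suite pins the output to a dense brute-force solve to 10⁻⁸ per channel.
  `corrected = input − baseline` by definition, so their sum restores the
  input to a rounding step.
* **Normalisation.** Division by the global maximum over the full grid (no
  exclusion windows); rejects non-positive maxima.

## Feature engineering and classification

* PCA on mean-centred, unscaled intensities (spectra are already
  max-normalised; channel scaling would inflate empty regions). Components
  ordered by variance with a deterministic sign (largest-|loading| element
  positive). Components are kept up to 99% cumulative explained variance.
* Candidate predictors: per kept component, the 30 channels of largest
  |loading|; union, deduplicated, ties toward the lower wavenumber. On
  generator data this set covers all ten planted junction-sensitive band
  centres within ±2 cm⁻¹.
* Ranking: one-vs-all linear SVMs (box constraint 10) on z-scored
  features; importance = Σ_classes |w|. On spectral data the heaviest
  weights concentrate on band *shoulders* rather than apexes (shoulders
  carry the largest class contrast after normalisation and under
  calibration shift) — the same phenomenon reported for real junction
  spectra, and the reason features are defined at channel level rather than
  re-detected apexes.
* Feature count: k grows along the ranking; for each k a stratified
  10-fold CV accuracy is computed with standardisation re-fit inside each
  fold; the smallest k within 0.005 of the curve maximum is chosen. The
  full curve is reported.
* Models (all standardise features): quadratic and cubic polynomial-kernel
  SVMs, one-vs-one, box constraint 1, kernel scale set per fit to the
  median pairwise Euclidean distance of the standardised training rows
  (kernel `((x·y)/s² + 1)^d`); and a wide neural network — one fully
  connected layer of 100 ReLU units, LBFGS (limited-memory quasi-Newton),
  iteration limit 1000, regularisation 0, softmax output.
* Split schemes. *Spectra-based*: per-class random 80/20
  (floor(0.2·n) to test). *Sample-based*: one whole membrane held out as
  test; blank spectra carry no membrane identity and always train — a
  deployed damage classifier is not asked about cell-free supports, so the
  blank row of the test confusion stays empty and blank is excluded from
  macro metrics.
* Evaluation: confusion over all four classes; accuracy = trace/total;
  specificity/precision/sensitivity/F1 computed one-vs-rest per class and
  macro-averaged over classes with ≥ 1 true instance; empty denominators
  contribute 0 and are flagged.
* Leakage policy: by default PCA, candidate extraction, ranking, the
  feature-count search and standardisation see training rows only; the
  suite asserts that corrupting test spectra changes neither the selected
  features nor the trained models. A `pooled_selection` flag reproduces the
  classical all-data feature selection for comparison; reports record which
  mode produced them. Standard k-fold (k−1 train / 1 test) is used
  throughout; fold assignment depends only on labels and seed, and k equal
  to the row count degenerates to leave-one-out.

## TEER circuit analysis

Topology: CPE in series with R_s in series with (R_TEER ‖ C_m) — the
standard transwell chopstick-electrode model, with the CPE capturing the
non-ideal electrode–medium interface. All parameters area-normalised;
defaults R_s = 20 Ω·cm², C_m = 1 µF/cm², Q = 10⁻⁵ S·s^α/cm², α = 0.8;
per-condition barrier resistances 700 / 328.9 / 197.9 Ω·cm² for
intact / 2 h / 4 h. The phase of this circuit is ≤ 0 at every frequency
(all elements capacitive or resistive), which the suite checks across
random parameter draws.

Fitting minimises the modulus-weighted complex residual
Σ|Z_obs − Z_model|²/|Z_obs|² (unweighted optional) with
`scipy.optimize.least_squares` over log-scaled parameters (α linear) within
physical bounds; initialisation from the spectrum's asymptotes (R_s from
the high-frequency magnitude, R_TEER from the plateau gap, C_m from the
knee frequency). Noiseless round trips recover all five parameters to
better than 0.1%; at 1% proportional noise the median R_TEER error stays
below 5% (20-draw Monte Carlo), and the intact > 2 h > 4 h ordering
survives ≥ 5% noise.

## Problem sizes and runtime choices

Unit and acceptance tests use the full 220-spectrum design where the
quantity under test is bookkeeping or a single pipeline run, and a reduced
design (3 membranes × 10 spots + 20 blanks on a 2 cm⁻¹ grid, fixed
13-feature models) for the 20-seed split-scheme comparison, chosen so the
whole suite runs in well under a minute of compute per property while the
directional contrasts (sample-based ≤ spectra-based accuracy; dominant
T4→blank confusion) remain stable. The full default experiment — complete
plateau search over ~270 candidates and all three model families — runs in
under a minute on one CPU.

## Known limitations

* The SG window/bandwidth mismatch above means absolute band heights after
  preprocessing are systematically attenuated; classification is
  unaffected (all spectra share the distortion), but the pipeline should
  not be used for quantitative band-intensity ratios without narrowing the
  window.
* The plateau rule at tolerance 0.005 tends to select large feature counts
  when the CV curve creeps slowly; the curve is always reported so users
  can apply stricter parsimony.
* Sample-based results with only three membranes have high variance across
  the choice of held-out membrane; the analysis scripts rotate the holdout
  and report all three.
* The impedance fitter assumes the stated topology; it does not select
  among circuits.
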