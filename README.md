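# ramanbarrier

Label-free classification of epithelial-barrier damage from single-point
Raman microspectra, with a companion equivalent-circuit analysis of
trans-epithelial electrical resistance (TEER) impedance spectra.

## The problem

Intestinal epithelial monolayers (e.g. Caco-2 cells on transwell membranes)
seal themselves with tight junctions. Calcium chelation (EGTA) disassembles
those junctions, the barrier leaks, and the damage state of the epithelium —
intact, mildly damaged (2 h exposure), heavily damaged (4 h), or bare
membrane — is normally read out invasively (electrodes, immunostaining).
Raman microspectroscopy of the intercellular junction regions offers a
contactless alternative: junction-associated bands (E-cadherin near
1080 cm⁻¹, protein/proline bands at 852–858 and 937 cm⁻¹, …) fade as the
junctions disassemble, and a supervised classifier over selected spectral
channels can call the damage state of a single acquisition.

This package implements that workflow end to end for researchers working on
organ-on-chip and barrier models:

* **`synth`** — a generative model of the study: Gaussian bands from a
  curated assignment library, class-dependent attenuation of
  junction-sensitive bands, per-membrane batch effects (gain + wavenumber
  shift), per-spot biological heterogeneity, fluorescence background,
  detector noise, cosmic-ray spikes, and "hole" spots at heavy damage where
  the laser samples exposed substrate. Also simulates impedance spectra of
  the barrier circuit.
* **`prep`** — the preprocessing chain: cosmic-ray removal (modified
  z-score on the second difference), Savitzky–Golay smoothing (window 51,
  order 2), asymmetric-least-squares baseline correction
  (λ = 10⁴, p = 0.001), max-normalisation.
* **`peaks`** — top-N peak detection by prominence and nearest-band
  assignment against the library.
* **`chemometrics`** — PCA over preprocessed spectra; components kept to
  99% cumulative explained variance; the 30 heaviest-|loading| channels per
  component pooled as candidate predictors; features ranked by summed
  absolute weights of one-vs-all linear SVMs (box constraint 10); feature
  count chosen where 10-fold CV accuracy plateaus.
* **`classify`** — spectrum-level 80/20 splits vs whole-membrane
  ("sample-based") holdout; quadratic/cubic-kernel SVMs (one-vs-one, box
  constraint 1, automatic kernel scale) and a wide neural network
  (1 × 100 ReLU, LBFGS, no regularisation); confusion matrices and
  macro-averaged metrics.
* **`teer`** — closed-form impedance of the barrier circuit

  Z(f) = 1/(Q·(j2πf)^α) + R_s + R_TEER / (1 + j2πf·R_TEER·C_m)

  (CPE electrode interface in series with the medium resistance and the
  parallel R‖C barrier) and complex nonlinear least-squares extraction of
  R_TEER, the barrier resistance in Ω·cm².

The numbered scripts under `analysis/` run the study: simulate, preprocess
and fingerprint, classify under both split schemes, and fit TEER.

## Worked example

```bash
python analysis/03_classify_spectra_split.py
```

simulates the default study (220 spectra: 60 each at T0/T2h/T4h from three
membranes, 40 blank-membrane spectra), preprocesses it, selects features on
the training portion only, and trains the three model families. Output
(seed 1):

```
176 train / 44 test spectra; 274 candidate predictors from 13 principal
components; plateau at 213 features
model  cv_accuracy  train_accuracy  test_accuracy  specificity  precision  sensitivity    f1
 qSVM        0.886           0.909          0.932        0.979      0.932        0.938 0.925
 cSVM        0.884           0.932          0.909        0.971      0.907        0.917 0.904
  WNN        0.896           1.000          0.886        0.964      0.886        0.896 0.883
```

Random 80/20 splitting mixes membranes between train and test, so these
accuracies are flattering. The deployment-realistic protocol holds out a
whole membrane:

```bash
python analysis/04_classify_sample_split.py
```

```
mean validation accuracy per model: {'WNN': 0.881, 'cSVM': 0.889, 'qSVM': 0.871}
mean never-seen-membrane test accuracy per model: {'WNN': 0.839, 'cSVM': 0.861, 'qSVM': 0.822}
largest off-diagonal mass: true T4 predicted as BLANK (21 spectra)
```

Test accuracy drops relative to spectrum-level splitting, and the dominant
confusion is heavily damaged epithelium called as bare membrane: at 4 h the
monolayer has holes where cells detached, and an acquisition on a hole
carries little junction fingerprint. Both effects are structural, not
incidental — the generator plants them and the test suite asserts them as
directional properties.

The TEER companion analysis:

```bash
python analysis/05_fit_teer.py
```

```
condition  true_r_teer_ohm_cm2  fitted_r_teer_ohm_cm2
   intact                700.0                  693.3
 EGTA 2 h                328.9                  329.9
 EGTA 4 h                197.9                  196.0
```

recovers the collapsing barrier resistance from impedance spectra with 2%
measurement noise (noiseless spectra are recovered to better than 0.1%).

A thin CLI wraps the same library: `ramanbarrier simulate|preprocess|peaks|
teer-fit|run` (see `ramanbarrier --help`; `run` accepts a YAML config such
as `configs/example.yaml`).

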