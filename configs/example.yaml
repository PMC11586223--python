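# Experiment configuration for `ramanbarrier run --config configs/example.yaml`.
# Sections `design`, `generator` and `prep` map onto StudyDesign,
# GeneratorParams and PrepConfig; top-level keys onto ExperimentConfig.
# Any omitted key keeps its documented default.

design:
  n_membranes: 3
  n_spots_per_timepoint: 20
  n_blank_spectra: 40
  grid: [500, 2000, 1]

generator:
  noise_sd: 0.02
  hole_probability: 0.3
  membrane_amplitude_sd: 0.15
  membrane_shift_sd: 1.0

prep:
  sg_window: 51
  sg_order: 2
  asls_lambda: 10000.0
  asls_p: 0.001

scheme: sample_based        # spectra_based | sample_based
held_out_membrane: M3
variance_threshold: 0.99
n_per_pc: 30
ranking_box_constraint: 10
plateau_tolerance: 0.005
cv_folds: 10
seed: 1
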