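kinetics:
  model_kind: one_phase
  k: 0.23104906018664842
  f_fast: 0.39
  k_fast: 0.7535
  k_slow: 0.0
  shutoff_age: .inf
optics:
  yield_ratio: 2.6
  quench: 0.2
  acidic_fraction:
    0.0: 0.05
    2.0: 0.35
  af_gfp: 30.0
  af_rfp: 12.0
  af_ratio: 0.15
preset:
  neuron_class: DA9
  n_puncta: 15
  punctum_amount_mu: 800.0
  punctum_amount_sigma: 0.5
  punctum_radius_um: 0.35
  axon_length_um: 40.0
  growth:
    0.0: 1.0
    2.0: 2.2
  count_growth:
    0.0: 1.0
    2.0: 1.4
design:
  pulse_age: 2.0
  chase_times:
  - 2.0
  - 3.0
  - 4.0
  - 5.0
  - 6.0
  - 7.0
  n_animals_per_timepoint: 15
  include_controls: true
  pulse_delay_h: 0.0
  recomb_efficiency: 1.0
noise:
  animal_cv: 0.15
  punctum_cv: 0.2
  brightness_cv: 0.4
  acidic_kappa: 30.0
  read_sigma: 2.0
  photon_gain: 1.0
pixel_size_um: 0.108
z_step_um: 0.4
seed: 0
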