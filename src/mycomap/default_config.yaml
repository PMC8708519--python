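# Default design and preset library.
#
# Targets are the per-variant mean frequency / intensity / arbuscules /
# vesicles (percent) each preset aims for; gap_rate and the shape knob
# (persistence for longitudinal, spot_rate for radial) were produced by
# mycomap.simulate.calibrate_preset against those targets (seed 12345,
# n_pilot 600) and frozen here.  Regenerate with:
#   calibrate_preset(strategy, targets, n_pilot=600, seed=12345)
design:
  combinations:
  - A0-B1
  - A1-B2
  - A1-B3
  - A1-B4
  - A1-B5
  - A2-B2
  - A2-B3
  - A2-B4
  - A2-B5
  plants_per_combination: 5
  fragments_per_plant_control: 6
  fragments_per_plant: 9
  fields_per_fragment: 15
presets:
  A0-B1:
    strategy: longitudinal
    target_frequency: 13.34
    target_intensity: 6.08
    arbuscule_share: 0.17105263157894737
    vesicle_share: 0.02631578947368421
    gap_rate: 0.85190625
    spot_rate: 3.0
    persistence: 0.95
    field_cv: 0.35
    seed: 12345
  A1-B2:
    strategy: longitudinal
    target_frequency: 19.65
    target_intensity: 9.05
    arbuscule_share: 0.19779005524861878
    vesicle_share: 0.0011049723756906076
    gap_rate: 0.7810423519736842
    spot_rate: 3.0
    persistence: 0.95
    field_cv: 0.35
    seed: 12345
  A1-B3:
    strategy: longitudinal
    target_frequency: 29.82
    target_intensity: 13.5
    arbuscule_share: 0.21703703703703706
    vesicle_share: 0.020740740740740744
    gap_rate: 0.6551500822368421
    spot_rate: 3.0
    persistence: 0.95
    field_cv: 0.35
    seed: 12345
  A1-B4:
    strategy: longitudinal
    target_frequency: 44.57
    target_intensity: 19.23
    arbuscule_share: 0.1908476339053562
    vesicle_share: 0.0010400416016640665
    gap_rate: 0.4486381578947368
    spot_rate: 3.0
    persistence: 0.95
    field_cv: 0.35
    seed: 12345
  A1-B5:
    strategy: longitudinal
    target_frequency: 50.17
    target_intensity: 20.25
    arbuscule_share: 0.05037037037037037
    vesicle_share: 0.003950617283950617
    gap_rate: 0.3442434210526316
    spot_rate: 3.0
    persistence: 0.95
    field_cv: 0.35
    seed: 12345
  A2-B2:
    strategy: radial
    target_frequency: 22.98
    target_intensity: 10.72
    arbuscule_share: 0.314365671641791
    vesicle_share: 0.010261194029850746
    gap_rate: 0.7693322368421054
    spot_rate: 7.0
    persistence: 0.85
    field_cv: 0.35
    seed: 12345
  A2-B3:
    strategy: radial
    target_frequency: 37.94
    target_intensity: 16.72
    arbuscule_share: 0.15251196172248804
    vesicle_share: 0.006578947368421053
    gap_rate: 0.5665000000000001
    spot_rate: 6.0
    persistence: 0.85
    field_cv: 0.35
    seed: 12345
  A2-B4:
    strategy: radial
    target_frequency: 32.56
    target_intensity: 15.0
    arbuscule_share: 0.162
    vesicle_share: 0.006666666666666667
    gap_rate: 0.644736842105263
    spot_rate: 6.0
    persistence: 0.85
    field_cv: 0.35
    seed: 12345
  A2-B5:
    strategy: radial
    target_frequency: 37.33
    target_intensity: 14.8
    arbuscule_share: 0.0060810810810810806
    vesicle_share: 0.004054054054054053
    gap_rate: 0.5803947368421053
    spot_rate: 6.0
    persistence: 0.85
    field_cv: 0.35
    seed: 12345
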