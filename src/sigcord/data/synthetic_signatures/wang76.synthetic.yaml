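name: WANG76
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: up_minus_down
components:
- probe_id: WANG76_001_at
  set_label: up
- probe_id: WANG76_002_at
  set_label: up
- probe_id: WANG76_003_at
  set_label: up
- probe_id: WANG76_004_at
  set_label: up
- probe_id: WANG76_005_at
  set_label: up
- probe_id: WANG76_006_at
  set_label: up
- probe_id: WANG76_007_at
  set_label: up
- probe_id: WANG76_008_at
  set_label: up
- probe_id: WANG76_009_at
  set_label: up
- probe_id: WANG76_010_at
  set_label: up
- probe_id: WANG76_011_at
  set_label: up
- probe_id: WANG76_012_at
  set_label: up
- probe_id: WANG76_013_at
  set_label: up
- probe_id: WANG76_014_at
  set_label: up
- probe_id: WANG76_015_at
  set_label: up
- probe_id: WANG76_016_at
  set_label: up
- probe_id: WANG76_017_at
  set_label: up
- probe_id: WANG76_018_at
  set_label: up
- probe_id: WANG76_019_at
  set_label: up
- probe_id: WANG76_020_at
  set_label: up
- probe_id: WANG76_021_at
  set_label: up
- probe_id: WANG76_022_at
  set_label: up
- probe_id: WANG76_023_at
  set_label: up
- probe_id: WANG76_024_at
  set_label: up
- probe_id: WANG76_025_at
  set_label: up
- probe_id: WANG76_026_at
  set_label: up
- probe_id: WANG76_027_at
  set_label: up
- probe_id: WANG76_028_at
  set_label: up
- probe_id: WANG76_029_at
  set_label: up
- probe_id: WANG76_030_at
  set_label: up
- probe_id: WANG76_031_at
  set_label: up
- probe_id: WANG76_032_at
  set_label: up
- probe_id: WANG76_033_at
  set_label: up
- probe_id: WANG76_034_at
  set_label: up
- probe_id: WANG76_035_at
  set_label: up
- probe_id: WANG76_036_at
  set_label: up
- probe_id: WANG76_037_at
  set_label: up
- probe_id: WANG76_038_at
  set_label: up
- probe_id: WANG76_039_at
  set_label: up
- probe_id: WANG76_040_at
  set_label: up
- probe_id: WANG76_041_at
  set_label: up
- probe_id: WANG76_042_at
  set_label: up
- probe_id: WANG76_043_at
  set_label: up
- probe_id: WANG76_044_at
  set_label: up
- probe_id: WANG76_045_at
  set_label: up
- probe_id: WANG76_046_at
  set_label: up
- probe_id: WANG76_047_at
  set_label: up
- probe_id: WANG76_048_at
  set_label: up
- probe_id: WANG76_049_at
  set_label: up
- probe_id: WANG76_050_at
  set_label: up
- probe_id: WANG76_051_at
  set_label: up
- probe_id: WANG76_052_at
  set_label: up
- probe_id: WANG76_053_at
  set_label: up
- probe_id: WANG76_054_at
  set_label: up
- probe_id: WANG76_055_at
  set_label: up
- probe_id: WANG76_056_at
  set_label: up
- probe_id: WANG76_057_at
  set_label: up
- probe_id: WANG76_058_at
  set_label: down
- probe_id: WANG76_059_at
  set_label: down
- probe_id: WANG76_060_at
  set_label: down
- probe_id: WANG76_061_at
  set_label: down
- probe_id: WANG76_062_at
  set_label: down
- probe_id: WANG76_063_at
  set_label: down
- probe_id: WANG76_064_at
  set_label: down
- probe_id: WANG76_065_at
  set_label: down
- probe_id: WANG76_066_at
  set_label: down
- probe_id: WANG76_067_at
  set_label: down
- probe_id: WANG76_068_at
  set_label: down
- probe_id: WANG76_069_at
  set_label: down
- probe_id: WANG76_070_at
  set_label: down
- probe_id: WANG76_071_at
  set_label: down
- probe_id: WANG76_072_at
  set_label: down
- probe_id: WANG76_073_at
  set_label: down
- probe_id: WANG76_074_at
  set_label: down
- probe_id: WANG76_075_at
  set_label: down
- probe_id: WANG76_076_at
  set_label: down
threshold_rule:
  kind: quantile
  q: 0.48
poor_direction: high
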