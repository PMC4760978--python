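name: GGI
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: up_minus_down
components:
- probe_id: GGI_001_at
  set_label: up
- probe_id: GGI_002_at
  set_label: up
- probe_id: GGI_003_at
  set_label: up
- probe_id: GGI_004_at
  set_label: up
- probe_id: GGI_005_at
  set_label: up
- probe_id: GGI_006_at
  set_label: up
- probe_id: GGI_007_at
  set_label: up
- probe_id: GGI_008_at
  set_label: up
- probe_id: GGI_009_at
  set_label: up
- probe_id: GGI_010_at
  set_label: up
- probe_id: GGI_011_at
  set_label: up
- probe_id: GGI_012_at
  set_label: up
- probe_id: GGI_013_at
  set_label: up
- probe_id: GGI_014_at
  set_label: up
- probe_id: GGI_015_at
  set_label: up
- probe_id: GGI_016_at
  set_label: up
- probe_id: GGI_017_at
  set_label: up
- probe_id: GGI_018_at
  set_label: up
- probe_id: GGI_019_at
  set_label: up
- probe_id: GGI_020_at
  set_label: up
- probe_id: GGI_021_at
  set_label: up
- probe_id: GGI_022_at
  set_label: up
- probe_id: GGI_023_at
  set_label: up
- probe_id: GGI_024_at
  set_label: up
- probe_id: GGI_025_at
  set_label: up
- probe_id: GGI_026_at
  set_label: up
- probe_id: GGI_027_at
  set_label: up
- probe_id: GGI_028_at
  set_label: up
- probe_id: GGI_029_at
  set_label: up
- probe_id: GGI_030_at
  set_label: up
- probe_id: GGI_031_at
  set_label: up
- probe_id: GGI_032_at
  set_label: up
- probe_id: GGI_033_at
  set_label: up
- probe_id: GGI_034_at
  set_label: up
- probe_id: GGI_035_at
  set_label: up
- probe_id: GGI_036_at
  set_label: up
- probe_id: GGI_037_at
  set_label: up
- probe_id: GGI_038_at
  set_label: up
- probe_id: GGI_039_at
  set_label: up
- probe_id: GGI_040_at
  set_label: up
- probe_id: GGI_041_at
  set_label: up
- probe_id: GGI_042_at
  set_label: up
- probe_id: GGI_043_at
  set_label: up
- probe_id: GGI_044_at
  set_label: up
- probe_id: GGI_045_at
  set_label: up
- probe_id: GGI_046_at
  set_label: up
- probe_id: GGI_047_at
  set_label: up
- probe_id: GGI_048_at
  set_label: up
- probe_id: GGI_049_at
  set_label: up
- probe_id: GGI_050_at
  set_label: up
- probe_id: GGI_051_at
  set_label: up
- probe_id: GGI_052_at
  set_label: up
- probe_id: GGI_053_at
  set_label: up
- probe_id: GGI_054_at
  set_label: up
- probe_id: GGI_055_at
  set_label: up
- probe_id: GGI_056_at
  set_label: up
- probe_id: GGI_057_at
  set_label: up
- probe_id: GGI_058_at
  set_label: up
- probe_id: GGI_059_at
  set_label: up
- probe_id: GGI_060_at
  set_label: up
- probe_id: GGI_061_at
  set_label: up
- probe_id: GGI_062_at
  set_label: up
- probe_id: GGI_063_at
  set_label: up
- probe_id: GGI_064_at
  set_label: up
- probe_id: GGI_065_at
  set_label: up
- probe_id: GGI_066_at
  set_label: up
- probe_id: GGI_067_at
  set_label: up
- probe_id: GGI_068_at
  set_label: up
- probe_id: GGI_069_at
  set_label: up
- probe_id: GGI_070_at
  set_label: up
- probe_id: GGI_071_at
  set_label: up
- probe_id: GGI_072_at
  set_label: up
- probe_id: GGI_073_at
  set_label: up
- probe_id: GGI_074_at
  set_label: down
- probe_id: GGI_075_at
  set_label: down
- probe_id: GGI_076_at
  set_label: down
- probe_id: GGI_077_at
  set_label: down
- probe_id: GGI_078_at
  set_label: down
- probe_id: GGI_079_at
  set_label: down
- probe_id: GGI_080_at
  set_label: down
- probe_id: GGI_081_at
  set_label: down
- probe_id: GGI_082_at
  set_label: down
- probe_id: GGI_083_at
  set_label: down
- probe_id: GGI_084_at
  set_label: down
- probe_id: GGI_085_at
  set_label: down
- probe_id: GGI_086_at
  set_label: down
- probe_id: GGI_087_at
  set_label: down
- probe_id: GGI_088_at
  set_label: down
- probe_id: GGI_089_at
  set_label: down
- probe_id: GGI_090_at
  set_label: down
- probe_id: GGI_091_at
  set_label: down
- probe_id: GGI_092_at
  set_label: down
- probe_id: GGI_093_at
  set_label: down
- probe_id: GGI_094_at
  set_label: down
- probe_id: GGI_095_at
  set_label: down
- probe_id: GGI_096_at
  set_label: down
- probe_id: GGI_097_at
  set_label: down
threshold_rule:
  kind: quantile
  q: 0.65
poor_direction: high
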