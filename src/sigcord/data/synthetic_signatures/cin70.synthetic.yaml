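name: CIN70
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: mean
components:
- probe_id: CIN70_001_at
- probe_id: CIN70_002_at
- probe_id: CIN70_003_at
- probe_id: CIN70_004_at
- probe_id: CIN70_005_at
- probe_id: CIN70_006_at
- probe_id: CIN70_007_at
- probe_id: CIN70_008_at
- probe_id: CIN70_009_at
- probe_id: CIN70_010_at
- probe_id: CIN70_011_at
- probe_id: CIN70_012_at
- probe_id: CIN70_013_at
- probe_id: CIN70_014_at
- probe_id: CIN70_015_at
- probe_id: CIN70_016_at
- probe_id: CIN70_017_at
- probe_id: CIN70_018_at
- probe_id: CIN70_019_at
- probe_id: CIN70_020_at
- probe_id: CIN70_021_at
- probe_id: CIN70_022_at
- probe_id: CIN70_023_at
- probe_id: CIN70_024_at
- probe_id: CIN70_025_at
- probe_id: CIN70_026_at
- probe_id: CIN70_027_at
- probe_id: CIN70_028_at
- probe_id: CIN70_029_at
- probe_id: CIN70_030_at
- probe_id: CIN70_031_at
- probe_id: CIN70_032_at
- probe_id: CIN70_033_at
- probe_id: CIN70_034_at
- probe_id: CIN70_035_at
- probe_id: CIN70_036_at
- probe_id: CIN70_037_at
- probe_id: CIN70_038_at
- probe_id: CIN70_039_at
- probe_id: CIN70_040_at
- probe_id: CIN70_041_at
- probe_id: CIN70_042_at
- probe_id: CIN70_043_at
- probe_id: CIN70_044_at
- probe_id: CIN70_045_at
- probe_id: CIN70_046_at
- probe_id: CIN70_047_at
- probe_id: CIN70_048_at
- probe_id: CIN70_049_at
- probe_id: CIN70_050_at
- probe_id: CIN70_051_at
- probe_id: CIN70_052_at
- probe_id: CIN70_053_at
- probe_id: CIN70_054_at
- probe_id: CIN70_055_at
- probe_id: CIN70_056_at
- probe_id: CIN70_057_at
- probe_id: CIN70_058_at
- probe_id: CIN70_059_at
- probe_id: CIN70_060_at
- probe_id: CIN70_061_at
- probe_id: CIN70_062_at
- probe_id: CIN70_063_at
- probe_id: CIN70_064_at
- probe_id: CIN70_065_at
- probe_id: CIN70_066_at
- probe_id: CIN70_067_at
- probe_id: CIN70_068_at
- probe_id: CIN70_069_at
- probe_id: CIN70_070_at
threshold_rule:
  kind: quantile
  q: 0.61
poor_direction: high
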