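name: T52
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: weighted_sum
components:
- probe_id: T52_001_at
  weight: 1.0
- probe_id: T52_002_at
  weight: 1.0
- probe_id: T52_003_at
  weight: 1.0
- probe_id: T52_004_at
  weight: 1.0
- probe_id: T52_005_at
  weight: 1.0
- probe_id: T52_006_at
  weight: 1.0
- probe_id: T52_007_at
  weight: 1.0
- probe_id: T52_008_at
  weight: 1.0
- probe_id: T52_009_at
  weight: 1.0
- probe_id: T52_010_at
  weight: 1.0
- probe_id: T52_011_at
  weight: 1.0
- probe_id: T52_012_at
  weight: 1.0
- probe_id: T52_013_at
  weight: 1.0
- probe_id: T52_014_at
  weight: 1.0
- probe_id: T52_015_at
  weight: 1.0
- probe_id: T52_016_at
  weight: 1.0
- probe_id: T52_017_at
  weight: 1.0
- probe_id: T52_018_at
  weight: 1.0
- probe_id: T52_019_at
  weight: 1.0
- probe_id: T52_020_at
  weight: 1.0
- probe_id: T52_021_at
  weight: 1.0
- probe_id: T52_022_at
  weight: 1.0
- probe_id: T52_023_at
  weight: 1.0
- probe_id: T52_024_at
  weight: 1.0
- probe_id: T52_025_at
  weight: 1.0
- probe_id: T52_026_at
  weight: 1.0
- probe_id: T52_027_at
  weight: 1.0
- probe_id: T52_028_at
  weight: 1.0
- probe_id: T52_029_at
  weight: 1.0
- probe_id: T52_030_at
  weight: 1.0
- probe_id: T52_031_at
  weight: 1.0
- probe_id: T52_032_at
  weight: 1.0
- probe_id: T52_033_at
  weight: 1.0
- probe_id: T52_034_at
  weight: 1.0
- probe_id: T52_035_at
  weight: 1.0
- probe_id: T52_036_at
  weight: 1.0
- probe_id: T52_037_at
  weight: 1.0
- probe_id: T52_038_at
  weight: 1.0
- probe_id: T52_039_at
  weight: 1.0
- probe_id: T52_040_at
  weight: -1.0
- probe_id: T52_041_at
  weight: -1.0
- probe_id: T52_042_at
  weight: -1.0
- probe_id: T52_043_at
  weight: -1.0
- probe_id: T52_044_at
  weight: -1.0
- probe_id: T52_045_at
  weight: -1.0
- probe_id: T52_046_at
  weight: -1.0
- probe_id: T52_047_at
  weight: -1.0
- probe_id: T52_048_at
  weight: -1.0
- probe_id: T52_049_at
  weight: -1.0
- probe_id: T52_050_at
  weight: -1.0
- probe_id: T52_051_at
  weight: -1.0
- probe_id: T52_052_at
  weight: -1.0
threshold_rule:
  kind: quantile
  q: 0.62
poor_direction: high
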