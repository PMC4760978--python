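name: IGS
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: mean
components:
- probe_id: IGS_001_at
- probe_id: IGS_002_at
- probe_id: IGS_003_at
- probe_id: IGS_004_at
- probe_id: IGS_005_at
- probe_id: IGS_006_at
- probe_id: IGS_007_at
- probe_id: IGS_008_at
- probe_id: IGS_009_at
- probe_id: IGS_010_at
- probe_id: IGS_011_at
- probe_id: IGS_012_at
- probe_id: IGS_013_at
- probe_id: IGS_014_at
- probe_id: IGS_015_at
- probe_id: IGS_016_at
- probe_id: IGS_017_at
- probe_id: IGS_018_at
- probe_id: IGS_019_at
- probe_id: IGS_020_at
- probe_id: IGS_021_at
- probe_id: IGS_022_at
- probe_id: IGS_023_at
- probe_id: IGS_024_at
- probe_id: IGS_025_at
- probe_id: IGS_026_at
- probe_id: IGS_027_at
- probe_id: IGS_028_at
- probe_id: IGS_029_at
- probe_id: IGS_030_at
- probe_id: IGS_031_at
- probe_id: IGS_032_at
- probe_id: IGS_033_at
- probe_id: IGS_034_at
- probe_id: IGS_035_at
- probe_id: IGS_036_at
- probe_id: IGS_037_at
- probe_id: IGS_038_at
- probe_id: IGS_039_at
- probe_id: IGS_040_at
- probe_id: IGS_041_at
- probe_id: IGS_042_at
- probe_id: IGS_043_at
- probe_id: IGS_044_at
- probe_id: IGS_045_at
- probe_id: IGS_046_at
- probe_id: IGS_047_at
- probe_id: IGS_048_at
- probe_id: IGS_049_at
- probe_id: IGS_050_at
- probe_id: IGS_051_at
- probe_id: IGS_052_at
- probe_id: IGS_053_at
- probe_id: IGS_054_at
- probe_id: IGS_055_at
- probe_id: IGS_056_at
- probe_id: IGS_057_at
- probe_id: IGS_058_at
- probe_id: IGS_059_at
- probe_id: IGS_060_at
threshold_rule:
  kind: quantile
  q: 0.62
poor_direction: high
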