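name: CSR
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: centroid_correlation
components:
- probe_id: CSR_001_at
- probe_id: CSR_002_at
- probe_id: CSR_003_at
- probe_id: CSR_004_at
- probe_id: CSR_005_at
- probe_id: CSR_006_at
- probe_id: CSR_007_at
- probe_id: CSR_008_at
- probe_id: CSR_009_at
- probe_id: CSR_010_at
- probe_id: CSR_011_at
- probe_id: CSR_012_at
- probe_id: CSR_013_at
- probe_id: CSR_014_at
- probe_id: CSR_015_at
- probe_id: CSR_016_at
- probe_id: CSR_017_at
- probe_id: CSR_018_at
- probe_id: CSR_019_at
- probe_id: CSR_020_at
- probe_id: CSR_021_at
- probe_id: CSR_022_at
- probe_id: CSR_023_at
- probe_id: CSR_024_at
- probe_id: CSR_025_at
- probe_id: CSR_026_at
- probe_id: CSR_027_at
- probe_id: CSR_028_at
- probe_id: CSR_029_at
- probe_id: CSR_030_at
- probe_id: CSR_031_at
- probe_id: CSR_032_at
- probe_id: CSR_033_at
- probe_id: CSR_034_at
- probe_id: CSR_035_at
- probe_id: CSR_036_at
- probe_id: CSR_037_at
- probe_id: CSR_038_at
- probe_id: CSR_039_at
- probe_id: CSR_040_at
- probe_id: CSR_041_at
- probe_id: CSR_042_at
- probe_id: CSR_043_at
- probe_id: CSR_044_at
- probe_id: CSR_045_at
- probe_id: CSR_046_at
- probe_id: CSR_047_at
- probe_id: CSR_048_at
- probe_id: CSR_049_at
- probe_id: CSR_050_at
threshold_rule:
  kind: quantile
  q: 0.33
poor_direction: high
centroids:
  poor:
    CSR_001_at: 2.5
    CSR_002_at: 2.5
    CSR_003_at: 2.5
    CSR_004_at: 2.5
    CSR_005_at: 2.5
    CSR_006_at: 2.5
    CSR_007_at: 2.5
    CSR_008_at: 2.5
    CSR_009_at: 2.5
    CSR_010_at: 2.5
    CSR_011_at: 2.5
    CSR_012_at: 2.5
    CSR_013_at: 2.5
    CSR_014_at: 2.5
    CSR_015_at: 2.5
    CSR_016_at: 2.5
    CSR_017_at: 2.5
    CSR_018_at: 2.5
    CSR_019_at: 2.5
    CSR_020_at: 2.5
    CSR_021_at: 2.5
    CSR_022_at: 2.5
    CSR_023_at: 2.5
    CSR_024_at: 2.5
    CSR_025_at: 2.5
    CSR_026_at: 2.5
    CSR_027_at: 2.5
    CSR_028_at: 2.5
    CSR_029_at: 2.5
    CSR_030_at: 2.5
    CSR_031_at: 2.5
    CSR_032_at: 2.5
    CSR_033_at: 2.5
    CSR_034_at: 2.5
    CSR_035_at: 2.5
    CSR_036_at: 2.5
    CSR_037_at: 2.5
    CSR_038_at: 2.5
    CSR_039_at: 1.5
    CSR_040_at: 1.5
    CSR_041_at: 1.5
    CSR_042_at: 1.5
    CSR_043_at: 1.5
    CSR_044_at: 1.5
    CSR_045_at: 1.5
    CSR_046_at: 1.5
    CSR_047_at: 1.5
    CSR_048_at: 1.5
    CSR_049_at: 1.5
    CSR_050_at: 1.5
  good:
    CSR_001_at: 1.5
    CSR_002_at: 1.5
    CSR_003_at: 1.5
    CSR_004_at: 1.5
    CSR_005_at: 1.5
    CSR_006_at: 1.5
    CSR_007_at: 1.5
    CSR_008_at: 1.5
    CSR_009_at: 1.5
    CSR_010_at: 1.5
    CSR_011_at: 1.5
    CSR_012_at: 1.5
    CSR_013_at: 1.5
    CSR_014_at: 1.5
    CSR_015_at: 1.5
    CSR_016_at: 1.5
    CSR_017_at: 1.5
    CSR_018_at: 1.5
    CSR_019_at: 1.5
    CSR_020_at: 1.5
    CSR_021_at: 1.5
    CSR_022_at: 1.5
    CSR_023_at: 1.5
    CSR_024_at: 1.5
    CSR_025_at: 1.5
    CSR_026_at: 1.5
    CSR_027_at: 1.5
    CSR_028_at: 1.5
    CSR_029_at: 1.5
    CSR_030_at: 1.5
    CSR_031_at: 1.5
    CSR_032_at: 1.5
    CSR_033_at: 1.5
    CSR_034_at: 1.5
    CSR_035_at: 1.5
    CSR_036_at: 1.5
    CSR_037_at: 1.5
    CSR_038_at: 1.5
    CSR_039_at: 2.5
    CSR_040_at: 2.5
    CSR_041_at: 2.5
    CSR_042_at: 2.5
    CSR_043_at: 2.5
    CSR_044_at: 2.5
    CSR_045_at: 2.5
    CSR_046_at: 2.5
    CSR_047_at: 2.5
    CSR_048_at: 2.5
    CSR_049_at: 2.5
    CSR_050_at: 2.5
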