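name: T17
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: weighted_sum
components:
- probe_id: T17_001_at
  weight: 1.0
- probe_id: T17_002_at
  weight: 1.0
- probe_id: T17_003_at
  weight: 1.0
- probe_id: T17_004_at
  weight: 1.0
- probe_id: T17_005_at
  weight: 1.0
- probe_id: T17_006_at
  weight: 1.0
- probe_id: T17_007_at
  weight: 1.0
- probe_id: T17_008_at
  weight: 1.0
- probe_id: T17_009_at
  weight: 1.0
- probe_id: T17_010_at
  weight: 1.0
- probe_id: T17_011_at
  weight: 1.0
- probe_id: T17_012_at
  weight: 1.0
- probe_id: T17_013_at
  weight: 1.0
- probe_id: T17_014_at
  weight: -1.0
- probe_id: T17_015_at
  weight: -1.0
- probe_id: T17_016_at
  weight: -1.0
- probe_id: T17_017_at
  weight: -1.0
threshold_rule:
  kind: quantile
  q: 0.59
poor_direction: high
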