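name: CIN25
synthetic: true
note: 'Synthetic reconstruction: probe ids follow the package''s synthetic-cohort
  naming, not the published gene list.'
aggregation: mean
components:
- probe_id: CIN25_001_at
- probe_id: CIN25_002_at
- probe_id: CIN25_003_at
- probe_id: CIN25_004_at
- probe_id: CIN25_005_at
- probe_id: CIN25_006_at
- probe_id: CIN25_007_at
- probe_id: CIN25_008_at
- probe_id: CIN25_009_at
- probe_id: CIN25_010_at
- probe_id: CIN25_011_at
- probe_id: CIN25_012_at
- probe_id: CIN25_013_at
- probe_id: CIN25_014_at
- probe_id: CIN25_015_at
- probe_id: CIN25_016_at
- probe_id: CIN25_017_at
- probe_id: CIN25_018_at
- probe_id: CIN25_019_at
- probe_id: CIN25_020_at
- probe_id: CIN25_021_at
- probe_id: CIN25_022_at
- probe_id: CIN25_023_at
- probe_id: CIN25_024_at
- probe_id: CIN25_025_at
threshold_rule:
  kind: quantile
  q: 0.61
poor_direction: high
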