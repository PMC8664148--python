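{
  "name": "axb-proposed-published",
  "description": "Published algorithm-adapted (AXB-equivalent) SBRT lung guideline limits: volume-independent limits plus volume-specific thresholds for PTVs of 13.2-50 cc. Volume-row columns: ptv_cc, ci_none, ci_minor_upper, r50_none, r50_minor_upper, d2cm_none, d2cm_minor_upper.",
  "volume_rows": [
    [13.2, 1.12, 1.41, 4.66, 5.75, 49.0, 57.0],
    [22.0, 1.12, 1.41, 4.46, 5.45, 53.0, 62.0],
    [34.0, 1.12, 1.41, 4.26, 5.25, 57.0, 67.0],
    [50.0, 1.12, 1.41, 3.96, 4.96, 61.0, 76.0]
  ],
  "d95_target_pct": 98.2,
  "v100_target_pct": 91.4,
  "v90_min_pct": 98.8,
  "v105_max_pct": 12.9,
  "rx_over_dmax_range": [0.59, 0.89],
  "oar": {"chestwall_v30gy_max_cc": 30.0, "lung_v20gy_max_pct": 10.0}
}
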