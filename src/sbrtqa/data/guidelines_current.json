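{
  "name": "rtog-nrg-current",
  "description": "RTOG 0813/0915 and NRG-BR001 volume-specific SBRT lung deviation thresholds plus volume-independent limits. Volume-row columns: ptv_cc, ci_none, ci_minor_upper, r50_none, r50_minor_upper, d2cm_none, d2cm_minor_upper. Thresholds between tabulated PTV volumes are linearly interpolated.",
  "volume_rows": [
    [1.8, 1.2, 1.5, 6.0, 7.5, 50.0, 57.0],
    [3.8, 1.2, 1.5, 6.0, 6.5, 50.0, 57.0],
    [7.4, 1.2, 1.5, 5.0, 6.0, 50.0, 58.0],
    [13.2, 1.2, 1.5, 5.0, 5.8, 50.0, 58.0],
    [22.0, 1.2, 1.5, 5.0, 5.5, 54.0, 63.0],
    [34.0, 1.2, 1.5, 4.0, 5.3, 58.0, 68.0],
    [50.0, 1.2, 1.5, 4.0, 5.0, 62.0, 77.0],
    [70.0, 1.2, 1.5, 4.0, 4.8, 66.0, 86.0],
    [95.0, 1.2, 1.5, 3.0, 4.4, 70.0, 89.0],
    [126.0, 1.2, 1.5, 3.0, 4.0, 73.0, 91.0],
    [163.0, 1.2, 1.5, 3.0, 3.7, 77.0, 94.0]
  ],
  "d95_target_pct": 100.0,
  "v100_target_pct": 95.0,
  "v90_min_pct": 99.0,
  "v105_max_pct": 15.0,
  "rx_over_dmax_range": [0.6, 0.9],
  "oar": {"chestwall_v30gy_max_cc": 30.0, "lung_v20gy_max_pct": 10.0}
}
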