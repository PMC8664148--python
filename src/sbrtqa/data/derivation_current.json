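{
  "name": "derivation-current",
  "description": "Current volume-specific limits used as the basis for cohort-ratio rescaling, restricted to the supported PTV volume range. The R50 variation column follows the RTOG-0915-style graded values (4.7/4.5/4.3/4.0), which differ from the integerized none-thresholds of the classification table at 13.2 and 22 cc. Columns: ptv_cc, ci_none, ci_minor_upper, r50_none, r50_minor_upper, d2cm_none, d2cm_minor_upper.",
  "volume_rows": [
    [13.2, 1.2, 1.5, 4.7, 5.8, 50.0, 58.0],
    [22.0, 1.2, 1.5, 4.5, 5.5, 54.0, 63.0],
    [34.0, 1.2, 1.5, 4.3, 5.3, 58.0, 68.0],
    [50.0, 1.2, 1.5, 4.0, 5.0, 62.0, 77.0]
  ]
}
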