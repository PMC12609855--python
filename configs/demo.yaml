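# Demo study replica: synthetic validation cohort (n=1099) scored with the
# shipped non-HDL-C model, outcomes simulated with planted miscalibration
# (intercept drift -0.07, slope drift 0.71) so the pipeline has something
# real to detect and correct.
endpoint: nonhdl
drift_intercept: -0.07
drift_slope: 0.71
seed: 7
benchmark_B: 500
outdir: lipidval_report
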