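{
 "beta0": -2.5172152407946666,
 "beta": 1.111482237663428,
 "residual_sd": 0.2046007931416735,
 "n_points": 86,
 "note": "synthetic default: fitted on strexpand's own read simulator (16xAGC/NxAGC locus, N uniform 0-500, 150 bp PE reads, insert 500+/-50 bp, 30x coverage, seed 0, n=100). Refit with `strexpand calibrate` for other sequencing conditions."
}
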