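{
 "gamma_v": 0.367,
 "b": 0.056,
 "b0": 0.14,
 "b1": 0.0,
 "b2": 0.057,
 "b3": -0.047,
 "A_v": 0.35,
 "gamma_a": 0.414,
 "d": -0.442,
 "d0": 0.178,
 "d1": 0.14469,
 "d2": 0.0,
 "d3": 0.0,
 "A_a": 0.32,
 "tau_expr": 0.0,
 "fs_kind": "identity",
 "lambda_a": 0.5,
 "lambda_v": 0.5,
 "p0": 0.199,
 "alpha": 0.438,
 "tau_p": 0.0
}
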