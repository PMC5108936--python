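{
 "pos": {"intercept": -0.4203, "slope": 0.9462},
 "neg": {"intercept": 0.2194, "slope": -0.9777}
}
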