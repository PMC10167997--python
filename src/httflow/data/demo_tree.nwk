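((((BM:2.65,BD:2.65):5.35,IV:8.0):12.0,IC:20.0):15.0,LT:35.0);
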