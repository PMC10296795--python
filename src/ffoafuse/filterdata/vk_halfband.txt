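-3.125000000000000000e-02 0.000000000000000000e+00 2.812500000000000000e-01 5.000000000000000000e-01 2.812500000000000000e-01 0.000000000000000000e+00 -3.125000000000000000e-02
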