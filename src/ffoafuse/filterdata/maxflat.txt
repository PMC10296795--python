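9.765625000000000000e-04 -0.000000000000000000e+00 -8.789062500000000000e-03 -1.562500000000000000e-02 -8.789062500000000000e-03 -0.000000000000000000e+00 9.765625000000000000e-04
-0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 -0.000000000000000000e+00
-8.789062500000000000e-03 0.000000000000000000e+00 7.910156250000000000e-02 1.406250000000000000e-01 7.910156250000000000e-02 0.000000000000000000e+00 -8.789062500000000000e-03
-1.562500000000000000e-02 0.000000000000000000e+00 1.406250000000000000e-01 2.500000000000000000e-01 1.406250000000000000e-01 0.000000000000000000e+00 -1.562500000000000000e-02
-8.789062500000000000e-03 0.000000000000000000e+00 7.910156250000000000e-02 1.406250000000000000e-01 7.910156250000000000e-02 0.000000000000000000e+00 -8.789062500000000000e-03
-0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 0.000000000000000000e+00 -0.000000000000000000e+00
9.765625000000000000e-04 -0.000000000000000000e+00 -8.789062500000000000e-03 -1.562500000000000000e-02 -8.789062500000000000e-03 -0.000000000000000000e+00 9.765625000000000000e-04
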