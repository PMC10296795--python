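3.906250000000000000e-03 1.562500000000000000e-02 2.343750000000000000e-02 1.562500000000000000e-02 3.906250000000000000e-03
1.562500000000000000e-02 6.250000000000000000e-02 9.375000000000000000e-02 6.250000000000000000e-02 1.562500000000000000e-02
2.343750000000000000e-02 9.375000000000000000e-02 1.406250000000000000e-01 9.375000000000000000e-02 2.343750000000000000e-02
1.562500000000000000e-02 6.250000000000000000e-02 9.375000000000000000e-02 6.250000000000000000e-02 1.562500000000000000e-02
3.906250000000000000e-03 1.562500000000000000e-02 2.343750000000000000e-02 1.562500000000000000e-02 3.906250000000000000e-03
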