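wavelength_nm,n,k
400.0,2.490000,0.000000
1100.0,2.490000,0.000000
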