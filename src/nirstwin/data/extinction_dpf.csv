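wavelength_nm,eps_o2hb_mM_cm,eps_hhb_mM_cm,eps_oxcco_diff_mM_cm,dpf
774,0.650,1.360,1.590,6.35
817,0.880,0.730,2.260,6.22
865,1.090,0.750,2.120,5.93
892,1.210,0.820,1.620,5.78
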