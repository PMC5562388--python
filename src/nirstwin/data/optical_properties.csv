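medium,wavelength_nm,mua_mm,musp_mm
human_forehead,680,0.0109,0.8235
human_forehead,850,0.0115,0.7210
silicone_phantom,680,0.0104,1.1093
silicone_phantom,850,0.0099,0.9514
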