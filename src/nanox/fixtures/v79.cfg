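# V79 (Chinese-hamster lung fibroblast) standard parameters
name = v79
RVs_um = 4.9
LVs_um = 1.0
z0_Gy = 22789
sigma_Gy = 8117
h = 225841
betar_Gy2 = 0.0259
SF2 = 0.65
eta = 0.8
TRCE_s = 1e-11
penumbra_alpha_rescale = true
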