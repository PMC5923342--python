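# CHO-K1 (Chinese-hamster ovary) standard parameters; betar carries the
# published x2 correction factor (0.0200 x 2)
name = cho_k1
RVs_um = 5.9
LVs_um = 1.0
z0_Gy = 14507
sigma_Gy = 2781
h = 104810
betar_Gy2 = 0.0400
SF2 = 0.58
eta = 0.8
TRCE_s = 1e-11
penumbra_alpha_rescale = true
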