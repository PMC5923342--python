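# HSG (human salivary-gland tumor) standard parameters
name = hsg
RVs_um = 7.0
LVs_um = 1.0
z0_Gy = 15654
sigma_Gy = 549
h = 179439
betar_Gy2 = 0.0615
SF2 = 0.42
eta = 0.8
TRCE_s = 1e-11
# act with alphar/eta on restricted specific energy in the penumbra so the
# reference LQ response is reproduced at every dose, not only at 2 Gy
penumbra_alpha_rescale = true
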