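# standard and varied reference-radiation quadratic coefficients (Gy^-2)
# with the printed relative difference (percent)
cell,betar_standard,betar_varied,rel_diff_pct_printed
hsg,0.0615,0.0565,8.5
v79,0.0259,0.0480,85.3
cho_k1,0.0400,0.0350,12.5
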