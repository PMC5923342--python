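# published ELF parameters fitted on the standard vs minimal datasets and
# the printed relative variation (percent).  convention_consistent marks
# whether the printed variation matches |minimal-standard|/standard*100;
# the hsg sigma row matches neither denominator convention.
cell,parameter,standard,minimal,rel_var_pct_printed,convention_consistent
hsg,z0,15654,14858,5,1
hsg,sigma,549,1063,50,0
hsg,h,179439,165283,8,1
v79,z0,22789,24481,7,1
v79,sigma,8117,10135,25,1
v79,h,225841,223597,1,1
cho_k1,z0,14507,14191,2,1
cho_k1,sigma,2781,44,98,1
cho_k1,h,104810,107548,3,1
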