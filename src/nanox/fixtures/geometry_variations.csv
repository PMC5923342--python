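# sensitive-volume variations per cell line: radius at fixed length,
# length at fixed radius, and shape at constant volume (lengths printed
# rounded to 0.1 um)
cell,variation,R_um,L_um
hsg,standard,7.0,1.0
hsg,radius_1,5.9,1.0
hsg,radius_2,4.9,1.0
hsg,length,7.0,7.0
hsg,shape_constant_volume,4.9,2.1
v79,standard,4.9,1.0
v79,radius_1,5.9,1.0
v79,radius_2,7.0,1.0
v79,length,4.9,4.9
v79,shape_constant_volume,7.0,0.5
cho_k1,standard,5.9,1.0
cho_k1,radius_1,4.9,1.0
cho_k1,radius_2,7.0,1.0
cho_k1,length,5.9,5.9
cho_k1,shape_constant_volume,7.0,0.7
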