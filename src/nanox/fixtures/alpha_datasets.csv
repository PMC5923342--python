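# standard and minimal alpha(LET) measurement sets per cell line
# (particle type and energy in MeV per nucleon; photons are the reference)
cell,dataset,particle,energy_MeV_u
hsg,standard,photon,1.25
hsg,standard,helium,2.9
hsg,standard,helium,5.6
hsg,standard,helium,8.4
hsg,standard,carbon,2.3
hsg,standard,carbon,8.5
hsg,standard,carbon,21.4
hsg,standard,carbon,39.1
hsg,standard,carbon,82.6
hsg,standard,neon,17.2
hsg,standard,neon,43.6
hsg,standard,neon,84.4
hsg,standard,neon,96.4
hsg,minimal,photon,1.25
hsg,minimal,carbon,8.5
hsg,minimal,carbon,39.1
v79,standard,photon,1.25
v79,standard,proton,2.6
v79,standard,proton,7.7
v79,standard,helium,2.9
v79,standard,helium,9.2
v79,standard,carbon,12
v79,standard,carbon,28.4
v79,standard,carbon,67.6
v79,standard,carbon,190
v79,standard,neon,23
v79,standard,neon,47.8
v79,standard,neon,105
v79,standard,argon,17.3
v79,standard,argon,46.5
v79,standard,argon,170
v79,minimal,photon,1.25
v79,minimal,carbon,12
v79,minimal,carbon,28.4
cho_k1,standard,photon,1.25
cho_k1,standard,carbon,2.4
cho_k1,standard,carbon,4.8
cho_k1,standard,carbon,11
cho_k1,standard,carbon,35
cho_k1,standard,neon,1.7
cho_k1,standard,neon,11
cho_k1,standard,neon,28.7
cho_k1,standard,neon,58
cho_k1,standard,oxygen,11
cho_k1,standard,oxygen,141.5
cho_k1,standard,oxygen,360
cho_k1,minimal,photon,1.25
cho_k1,minimal,carbon,11
cho_k1,minimal,carbon,35
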