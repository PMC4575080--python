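# Random-coil 13C/1H chemical shifts (ppm, DSS-referenced) for the 20
# canonical residues, from the standard random-coil compilation used by
# secondary-structure-propensity scoring (Wishart et al. 1995 lineage).
# Glycine has no CB.
aa,CA,CB,HA
A,52.5,19.1,4.32
C,58.2,28.0,4.55
D,54.2,41.1,4.64
E,56.6,29.9,4.35
F,57.7,39.6,4.62
G,45.1,,3.96
H,55.0,29.0,4.73
I,61.1,38.8,4.17
K,56.2,33.1,4.32
L,55.1,42.4,4.34
M,55.4,32.9,4.48
N,53.1,38.9,4.74
P,63.3,32.1,4.42
Q,55.7,29.4,4.34
R,56.0,30.9,4.34
S,58.3,63.8,4.47
T,61.8,69.8,4.35
V,62.2,32.9,4.12
W,57.5,29.6,4.66
Y,57.9,38.8,4.55
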