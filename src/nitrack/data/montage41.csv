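channel,region
Fp1,frontal
Fp2,frontal
AF7,frontal
AF3,frontal
AFz,frontal
AF4,frontal
AF8,frontal
F7,frontal
F5,frontal
F3,frontal
F1,frontal
Fz,frontal
F2,frontal
F4,frontal
F6,frontal
F8,frontal
FT7,temporal
FT8,temporal
T7,temporal
T8,temporal
TP7,temporal
TP8,temporal
TP9,temporal
TP10,temporal
P7,parietal
P5,parietal
P3,parietal
P1,parietal
Pz,parietal
P2,parietal
P4,parietal
P6,parietal
P8,parietal
PO7,occipital
PO3,occipital
POz,occipital
PO4,occipital
PO8,occipital
O1,occipital
Oz,occipital
O2,occipital
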