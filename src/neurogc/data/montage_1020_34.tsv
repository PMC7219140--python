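electrode	region
Fp1	prefrontal
Fp2	prefrontal
F7	frontal
F3	frontal
Fz	frontal
F4	frontal
F8	frontal
C3	central
Cz	central
C4	central
FT9	frontal-central
FT7	frontal-central
FC3	frontal-central
FCz	frontal-central
FC4	frontal-central
FT8	frontal-central
FT10	frontal-central
T3	temporal
T4	temporal
T5	temporal
T6	temporal
TP7	temporal-parietal
TP8	temporal-parietal
P3	parietal
Pz	parietal
P4	parietal
CP3	central-parietal
CPz	central-parietal
CP4	central-parietal
PO1	parietal-occipital
PO2	parietal-occipital
O1	occipital
O2	occipital
Oz	occipital
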