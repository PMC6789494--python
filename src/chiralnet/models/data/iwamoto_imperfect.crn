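# Iwamoto's enzymatic model under imperfect conditions: the perfect-case
# reactions plus stereoselective side channels (suffix 'a') that let each
# enantiomer react across sides, producing the cross complexes YL/YD.
# Rate constants are distinct labels here; the stability-restoring
# equalities (k2=k2a=k4=k4a, ...) are applied by merging label classes.
# Name map: E_L -> EL, Z_L -> ZL, Y_L -> YL, etc.
species A L D EL ED P ZL ZD YL YD Q
constant P ZL ZD YL YD Q
pair L:D
pair EL:ED
pair ZL:ZD
pair YL:YD
dual k2~k4
dual k3~k5
dual k6~k8
dual k7~k9
dual k10~k12
dual k11~k13
dual k2a~k4a
dual k3a~k5a
dual k6a~k8a
dual k7a~k9a
dual k10a~k12a
dual k11a~k13a
P <-> A | k0, k1
A + L <-> 2 L | k2, k3
A + L <-> L + D | k2a, k3a
A + D <-> 2 D | k4, k5
A + D <-> D + L | k4a, k5a
L + EL <-> ZL | k6, k7
L + ED <-> YD | k6a, k7a
D + ED <-> ZD | k8, k9
D + EL <-> YL | k8a, k9a
ZL <-> EL + Q | k10, k11
YL <-> EL + Q | k10a, k11a
ZD <-> ED + Q | k12, k13
YD <-> ED + Q | k12a, k13a
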