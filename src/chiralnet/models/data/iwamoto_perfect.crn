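# Iwamoto's enzymatic model under perfect stereoselectivity: reversible
# autocatalysis of L and D from the feed A plus Michaelis-Menten-type
# enzyme cycles. Only A, L, D, EL and ED are dynamic; the feed precursor
# P, the complexes ZL/ZD and the product Q are pool species.
# Name map: E_L -> EL, E_D -> ED, Z_L -> ZL, Z_D -> ZD.
species A L D EL ED P ZL ZD Q
constant P ZL ZD Q
pair L:D
pair EL:ED
pair ZL:ZD
dual k2~k4
dual k3~k5
dual k6~k8
dual k7~k9
dual k10~k12
dual k11~k13
P <-> A | k0, k1
A + L <-> 2 L | k2, k3
A + D <-> 2 D | k4, k5
L + EL <-> ZL | k6, k7
D + ED <-> ZD | k8, k9
ZL <-> EL + Q | k10, k11
ZD <-> ED + Q | k12, k13
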