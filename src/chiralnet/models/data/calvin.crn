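# Calvin's abstract autocatalysis/racemization mechanism: a pseudochiral
# network of order 2 with no symmetry-breaking states (the stability
# analysis proves its racemic steady states are never unstable in the
# mirror-asymmetric direction).
species L1 D1 L2 D2
pair L1:D1
pair L2:D2
dual k0~k1
dual k2~k3
dual k4~k5
dual k6~k7
dual k8~k9
L1 + L2 -> 2 L2 | k0
D1 + D2 -> 2 D2 | k1
2 L2 -> L1 + L2 | k2
2 D2 -> D1 + D2 | k3
L1 -> D1 | k4
D1 -> L1 | k5
L1 -> L2 | k6
D1 -> D2 | k7
L2 -> L1 | k8
D2 -> D1 | k9
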