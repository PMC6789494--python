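# Open-flow replicator model (Hochberg/Ribo): two cross-coupled
# autocatalytic template pairs per enantiomer side, first-order outflows
# of the four replicators, and inflow/outflow of the achiral feed A.
# Name map: ^1R_D -> R1D, ^1R_L -> R1L, ^2R_D -> R2D, ^2R_L -> R2L.
species R1L R1D R2L R2D A
pair R1L:R1D
pair R2L:R2D
dual k0~k2
dual k1~k3
dual k4~k6
dual k5~k7
dual k8~k10
dual k9~k11
A + R1D + R2D <-> 2 R1D + R2D | k0, k1
A + R1L + R2L <-> 2 R1L + R2L | k2, k3
A + R2D + R1D <-> 2 R2D + R1D | k4, k5
A + R2L + R1L <-> 2 R2L + R1L | k6, k7
R1D -> | k8
R2D -> | k9
R1L -> | k10
R2L -> | k11
-> A | k12
A -> | k13
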