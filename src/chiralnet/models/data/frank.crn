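# Frank's minimal autocatalytic model of absolute asymmetric synthesis.
# The achiral feedstock A is held constant (pool-chemical approximation);
# the product P is inert and also excluded from the dynamics.
species L D A P
constant A P
pair L:D
dual k1~k2
L + A -> 2 L | k1
D + A -> 2 D | k2
L + D -> P | k3
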