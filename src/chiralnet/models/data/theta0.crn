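# Toy two-species network used to illustrate the convex-coordinate change
# of variables: one steady-state equation, a two-ray current cone.
species I A
3 I -> 3 A | k1
2 I + A -> 3 I | k2
I + A -> 2 A | k3
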