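# Built-in modification registry: name -> {target residue, monoisotopic delta (Da)}.
# 'water' is registered as an abstract neutral-loss species (any residue).
carbamidomethyl:
  target: C
  delta: 57.021464
farnesyl:
  target: C
  delta: 204.187801
o_methyl:
  target: C
  delta: 14.015650
water:
  target: "*"
  delta: 18.0105646863
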