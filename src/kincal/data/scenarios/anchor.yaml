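# Anchor-point scenario: the plateau pedigree shifted 135 years older, so the
# earliest death (A2, 800 cal BC) lands on the steep approach before the
# plateau and anchors the whole model.
name: anchor
gen1_yob: -835
yob_gap: 20
err: 25
n_generations: 5
aad_table:
  A1: 45
  A2: 35
  B1: 36
  B2: 40
  C1: 38
  C2: 42
  D1: 40
  D2: 44
  E1: 60
  E2: 48
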