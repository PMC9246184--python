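# Simulated pedigree on the plateau regime: A1's death at 655 cal BC falls in
# a down-wiggle (trough) of the plateau, producing a wide, inverted range.
name: plateau
gen1_yob: -700
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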