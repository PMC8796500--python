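# SYNTHETIC EQ-5D-3L value set for testing the scoring path.
# Invented additive decrements -- NOT a published national tariff.
# score(code) = 1 - sum of decrements over dimensions at level 2/3.
# Worst state "33333" scores 1 - 1.20 = -0.20.
# dimension	level	decrement
MO	2	0.07
MO	3	0.30
SC	2	0.06
SC	3	0.25
UA	2	0.05
UA	3	0.20
PD	2	0.08
PD	3	0.25
AD	2	0.06
AD	3	0.20
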