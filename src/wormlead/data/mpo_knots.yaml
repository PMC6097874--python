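# CNS MPO desirability knots (published parameterisation of the six-attribute
# desirability sum). Monotone attributes list [full, zero]; tpsa is a hump
# [lo0, lo1, hi1, hi0]. Scores of >= 4 (of 6) are conventionally "high".
clogp: [3.0, 5.0]
clogd: [2.0, 4.0]
mw: [360.0, 500.0]
tpsa: [20.0, 40.0, 90.0, 120.0]
hbd: [0.5, 3.5]
pka_basic: [8.0, 10.0]
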