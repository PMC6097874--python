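# Transparent surrogate for worm bioaccumulation propensity: a logistic
# transform of a linear combination of simple descriptors. The coefficients
# are a versioned modelling choice of this package (the cited worm
# structure-accumulation model's internals are not public); they are scaled
# so the succinimide-class screening compounds score in a narrow band.
sam_surrogate_v1:
  intercept: 0.5
  clogp: 0.25
  mw_per_100: -0.4
  tpsa_per_100: -0.5
  hbd: -0.1
  rotatable_bonds: -0.05
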