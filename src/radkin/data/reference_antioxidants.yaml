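# Published overall rate constants (M^-1 s^-1) of common antioxidants toward
# the hydroperoxyl radical, per medium, used only for ranking comparisons.
water:
  ascorbic acid: 9.97e7
  caftaric acid: 9.09e8
  cannabidiol: 9.09e6
  carnosic acid: 4.73e6
  BHT: 2.51e5
  Trolox: 1.13e5
pentyl ethanoate:
  Trolox: 1.00e5
  BHT: 1.70e4
  carnosic acid: 5.70e3
  cannabidiol: 2.60e3
  caftaric acid: 1.82e3
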