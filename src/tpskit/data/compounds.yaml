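# GC-MS compound lexicon: class assignment, putative-identification flag, and
# a fixed reference retention time (min) per compound.  Retention times are
# synthetic but ordered plausibly for a 60 m TG-5SILMS-style column ramp
# (monoterpenes elute before sesquiterpenes; oxygenated compounds later than
# their hydrocarbon parents); only the ordering matters to the pipeline.
# putative: identified by spectral-library match only, no authentic standard.
compounds:
  isobutylbenzene: {class: internal_standard, rt_min: 10.20, putative: false}

  # monoterpene hydrocarbons
  α-pinene: {class: monoterpene, rt_min: 11.52, putative: false}
  camphene: {class: monoterpene, rt_min: 12.10, putative: false}
  sabinene: {class: monoterpene, rt_min: 12.84, putative: false}
  β-pinene: {class: monoterpene, rt_min: 13.05, putative: false}
  β-myrcene: {class: monoterpene, rt_min: 13.42, putative: false}
  α-phellandrene: {class: monoterpene, rt_min: 14.01, putative: false}
  delta-3-carene: {class: monoterpene, rt_min: 14.23, putative: false, synonyms: [d-carene, δ-3-carene]}
  α-terpinene: {class: monoterpene, rt_min: 14.55, putative: false}
  limonene: {class: monoterpene, rt_min: 15.02, putative: false}
  β-phellandrene: {class: monoterpene, rt_min: 15.21, putative: true}
  (Z)-β-ocimene: {class: monoterpene, rt_min: 15.63, putative: false}
  (E)-β-ocimene: {class: monoterpene, rt_min: 16.02, putative: false}
  γ-terpinene: {class: monoterpene, rt_min: 16.48, putative: false, synonyms: [y-terpinene, g-terpinene]}
  α-ocimene: {class: monoterpene, rt_min: 16.81, putative: false}
  terpinolene: {class: monoterpene, rt_min: 17.50, putative: false}
  allo-ocimene: {class: monoterpene, rt_min: 17.93, putative: true}

  # oxygenated monoterpenes
  linalool: {class: monoterpene, rt_min: 18.24, putative: false}
  fenchol: {class: monoterpene, rt_min: 19.18, putative: true}
  β-terpineol: {class: monoterpene, rt_min: 20.47, putative: true}
  α-terpineol: {class: monoterpene, rt_min: 21.33, putative: false}
  geraniol: {class: monoterpene, rt_min: 23.10, putative: false}

  # chromatographic peaks that are neither mono- nor sesquiterpenes; excluded
  # from percent-of-total quantification
  pinene hydrate: {class: non_terpene, rt_min: 18.80, putative: true}
  geranyl methyl ether: {class: non_terpene, rt_min: 21.90, putative: true}

  # sesquiterpenes
  δ-elemene: {class: sesquiterpene, rt_min: 26.21, putative: true}
  β-elemene: {class: sesquiterpene, rt_min: 27.48, putative: true}
  epi-β-caryophyllene: {class: sesquiterpene, rt_min: 28.17, putative: true}
  β-caryophyllene: {class: sesquiterpene, rt_min: 28.62, putative: false}
  γ-elemene: {class: sesquiterpene, rt_min: 29.04, putative: true}
  humulene: {class: sesquiterpene, rt_min: 29.81, putative: false, synonyms: [α-humulene]}
  alloaromadendrene: {class: sesquiterpene, rt_min: 30.22, putative: true}
  germacrene D: {class: sesquiterpene, rt_min: 30.85, putative: true}
  germacrene B: {class: sesquiterpene, rt_min: 31.58, putative: true}
  nerolidol: {class: sesquiterpene, rt_min: 32.20, putative: false}
  # hedycaryol thermally degrades in the GC inlet and is detected as elemol
  elemol: {class: sesquiterpene, rt_min: 32.84, putative: true, alias_of: hedycaryol}
  hedycaryol: {class: sesquiterpene, rt_min: 32.84, putative: true}
  globulol: {class: sesquiterpene, rt_min: 33.47, putative: true}
  guaiol: {class: sesquiterpene, rt_min: 33.92, putative: false}
  γ-eudesmol: {class: sesquiterpene, rt_min: 34.41, putative: true}
  α-eudesmol: {class: sesquiterpene, rt_min: 34.88, putative: true}
  farnesol: {class: sesquiterpene, rt_min: 35.60, putative: true}
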