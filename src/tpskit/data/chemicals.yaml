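# Crystallisation-chemical lexicon: canonical names, default mother-liquor
# role, and free-text synonyms (matched case-insensitively, hyphens and
# whitespace collapsed).  Ammonium sulfate is dual-use: it is a salt additive
# at low concentration and the precipitant at high concentration; the parser
# reassigns it to "precipitant" at or above the molarity threshold below.
ammonium_sulfate_precipitant_threshold_M: 0.8

chemicals:
  # buffers
  Bis-Tris: {role: buffer, synonyms: [bistris, "bis tris", "bis-tris methane"]}
  Tris: {role: buffer, synonyms: [tris-hcl, "tris hcl", "tris base"]}
  HEPES: {role: buffer, synonyms: []}
  MES: {role: buffer, synonyms: []}
  CAPS: {role: buffer, synonyms: []}
  CHES: {role: buffer, synonyms: []}
  Tricine: {role: buffer, synonyms: []}
  imidazole: {role: buffer, synonyms: []}
  sodium acetate: {role: buffer, synonyms: [naoac, "na acetate"]}
  sodium citrate: {role: buffer, synonyms: [tri-sodium citrate, trisodium citrate]}
  sodium cacodylate: {role: buffer, synonyms: [na cacodylate]}
  Bis-Tris propane: {role: buffer, synonyms: [btp]}

  # salts
  MgCl2: {role: salt, synonyms: [magnesium chloride, magnesium chloride hexahydrate]}
  NaCl: {role: salt, synonyms: [sodium chloride]}
  KCl: {role: salt, synonyms: [potassium chloride]}
  CaCl2: {role: salt, synonyms: [calcium chloride]}
  LiCl: {role: salt, synonyms: [lithium chloride]}
  MgSO4: {role: salt, synonyms: [magnesium sulfate, magnesium sulphate]}
  MnCl2: {role: salt, synonyms: [manganese chloride, manganese(ii) chloride]}
  sodium formate: {role: salt, synonyms: [na formate]}
  ammonium acetate: {role: salt, synonyms: [nh4 acetate]}
  lithium sulfate: {role: salt, synonyms: [li2so4, lithium sulphate]}
  sodium malonate: {role: salt, synonyms: [na malonate]}
  ammonium sulfate: {role: salt, synonyms: [ammonium sulphate, (nh4)2so4, "nh4 2so4"]}

  # precipitants
  PEG-3350: {role: precipitant, synonyms: [peg 3350, polyethylene glycol 3350, peg3350]}
  PEG-8000: {role: precipitant, synonyms: [peg 8000, polyethylene glycol 8000, peg8000]}
  PEG-4000: {role: precipitant, synonyms: [peg 4000, polyethylene glycol 4000, peg4000]}
  PEG-6000: {role: precipitant, synonyms: [peg 6000, polyethylene glycol 6000, peg6000]}
  PEG-400: {role: precipitant, synonyms: [peg 400, polyethylene glycol 400, peg400]}
  PEG-MME-2000: {role: precipitant, synonyms: [peg mme 2000, peg monomethyl ether 2000, polyethylene glycol monomethyl ether 2000]}
  MPD: {role: precipitant, synonyms: [2-methyl-2 4-pentanediol, 2-methyl-2-4-pentanediol]}
  isopropanol: {role: precipitant, synonyms: [2-propanol, iso-propanol]}
  glycerol: {role: precipitant, synonyms: [glycerin]}
  ethanol: {role: precipitant, synonyms: []}
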