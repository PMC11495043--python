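# Location-label normalization table (versioned).
# Subcellular-location predictors emit different labels for diderm vs monoderm
# (and archaeal) profiles; every known raw spelling maps to the closed
# vocabulary. Matching is case-insensitive after collapsing spaces/underscores.
version: 1
labels:
  extracellular: EXTRACELLULAR
  outermembrane: OUTER_MEMBRANE
  outer membrane: OUTER_MEMBRANE
  cellwall: CELL_WALL
  cell wall: CELL_WALL
  periplasmic: PERIPLASMIC
  periplasmicspace: PERIPLASMIC
  cytoplasmicmembrane: CYTOPLASMIC_MEMBRANE
  cytoplasmic membrane: CYTOPLASMIC_MEMBRANE
  plasmamembrane: CYTOPLASMIC_MEMBRANE
  cytoplasmic: CYTOPLASMIC
  cytoplasm: CYTOPLASMIC
  unknown: UNKNOWN
  unknown (multiple localizations): UNKNOWN
  unknown (this protein may have multiple localization sites): UNKNOWN
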