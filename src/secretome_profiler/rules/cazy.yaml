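# CAZyme acceptance: exclusions with probable biosynthetic function.
# Whole GT (glycosyltransferase) families are excluded by prefix; the
# class-label list excludes murein/peptidoglycan remodelling enzymes.
version: 1
excluded_prefixes:
  - GT
excluded_class_labels:
  - Glycoside transferases
  - Soluble_lytic_murein_transglycosylase
  - Peptidoglycan-N-acetylmuramic_acid_deacetylase_PdaC
  - Peptidoglycan_hydrolase_FlgJ
  - Membrane-bound_lytic_murein_transglycosylase_A
  - Membrane-bound_lytic_murein_transglycosylase_D
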