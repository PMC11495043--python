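# Domain rule set: nucleases (iterative seed-expansion accept list).
# Candidates from the homology search are kept only if they carry at least one
# of these conserved-domain names; matching is exact on the normalized name.
version: 1
class_label: NUCLEASE
accept_domains:
  - endonuclease
  - SNase
  - NUC1
  - SNC
  - HNHC
  - 5_nucleotid_C/MPP_superfamily
  - nadN superfamily
  - PRK09419 superfamily
reject_domains: []
annotation_include_keywords: []
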