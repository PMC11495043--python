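# Domain rule set: periplasmic nucleotidases (iterative seed-expansion accept list).
version: 1
class_label: NUCLEOTIDASE
accept_domains:
  - MPP_superfamily superfamily
  - 5_nucleotid_C
  - ushA
  - MPP_UshA_N_like
  - nadN superfamily
  - PRK09419 superfamily
reject_domains: []
annotation_include_keywords: []
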