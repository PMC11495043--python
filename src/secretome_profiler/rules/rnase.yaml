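# Domain rule set: RNases (iterative seed-expansion accept list).
version: 1
class_label: RNASE
accept_domains:
  - microbial_RNases superfamily
  - RNase_H_like superfamily
  - RNase_HI_prokaryote_like
  - rnhA
  - RNase_Sa
  - Ribonuclease
reject_domains: []
annotation_include_keywords: []
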