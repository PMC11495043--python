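# Cytochrome classification evidence for proteins carrying CxxCH motifs.
version: 1
cytochrome_domains:
  - Cytochrom
  - nanowire_3heme
  - decahem
  - PSCyt1 superfamily
  - octaheme_Shew superfamily
  - MXAN_0977_Heme2 superfamily
heat_shock_keyword: heat shock protein
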