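# Domain rule set: lipases (single-pass seed search + gene-caller keywords).
# Candidates come from a seed-database hit OR a gene-caller descriptor keyword;
# they are accepted only with a lipase functional domain, and any candidate
# carrying a PhoD domain (alkaline phosphatase D, not a lipase) is rejected
# regardless of other evidence.
version: 1
class_label: LIPASE
accept_domains:
  - EstA
  - Lipase_3
  - SGNH_hydrolase superfamily
  - Abhydrolase
  - GDPD_ScGlpQ1_like
  - ALP_like
  - nSMase
  - PC_PLC
  - PLA1
  - Triacylglycerol_lipase_like
  - OMPLA superfamily
reject_domains:
  - PhoD
annotation_include_keywords:
  - Multifunctional_esterase
  - lipase
  - Glycerophosphodiester_phosphodiesterase
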