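# secretome-profiler

Per-genome profiling of the *predicted secretome* — the proteins a microbial
genome exports beyond its cytoplasm — for cohorts of metagenome-assembled
genomes (MAGs), as used to map nutrient-acquisition and electron-transfer
niches in mixed microbial communities such as activated sludge.

The package consumes flat-file outputs of standard upstream predictors
(subcellular-location calls, signal-peptide calls from up to three detectors,
conserved-domain hits, functional annotations with COG categories, CAZyme
overview tables, peptidase-database hits, 12-column tabular similarity hits,
orthogroup membership, relative abundances) and integrates them into:

* **Compartment assignments** per protein — extracellular (EC),
  outer-membrane (OM), cell-wall (CW), periplasmic (PP), cytoplasmic-membrane
  (CM), cytoplasmic (CY) or unknown (UNK), with the *extra-cytoplasmic* union
  EC ∪ OM ∪ CW ∪ PP, and the **UNK+SP** category: unknown-location proteins
  that nonetheless carry a signal peptide and are therefore likely secreted.
  Compartment validity is checked against each MAG's cell-envelope
  architecture (OM/PP exist only in diderms, a profiled CW only in monoderms).
* **Catabolic enzyme classes** — CAZymes (GH/CBM/CE/PL, accepted with ≥ 2 of
  3 detection methods, biosynthetic families excluded), nutrient-acquiring
  peptidases (best database hit at e ≤ 10⁻²⁰, COG category E only, glutathione
  hydrolases excluded), lipases (seed-database hit at e ≤ 10⁻⁵ or gene-caller
  keyword, plus a lipase domain, PhoD carriers rejected), and nucleases,
  RNases and nucleotidases found by **iterative seed expansion**: search the
  proteome against a seed database at e ≤ 10⁻¹⁰, keep hits carrying an
  accept-listed domain, add them to the database and repeat to a fixed point.
* **Heme-binding proteins** — every CxxCH motif (heme-c attachment site) is
  counted, overlaps included; ≥ 4 sites defines a multi-heme protein, and
  cytochromes are classified from gene names, respiration-related
  descriptors, cytochrome-type domains, or the deliberate collection of
  multi-heme "heat shock protein" mis-annotations.
* **Per-MAG niche profiles and cohort statistics** — count vectors per
  genome; "especially high" flags for counts above mean + 2·SD (sample SD,
  strict >); "abundant" labels for mean relative abundance > 0.1 %; the
  Pearson correlation between UNK+SP and extra-cytoplasmic counts per MAG;
  orthogroup count matrices ranked by summed counts; and heatmap-style
  clustering (rows centered and unit-variance scaled, correlation distance
  d = 1 − r, average linkage) with Newick export.

A built-in affine-gap Smith–Waterman engine with Karlin–Altschul statistics
(E = K·m·n·e^(−λS), BLOSUM62/11/1, λ = 0.267, K = 0.041) is interchangeable
with externally supplied similarity tables throughout.

Because real cohorts require external genome databases and predictor runs,
the package ships a first-class **synthetic-data generator** that emits every
input dialect with planted, machine-readable ground truth (exact CxxCH
counts, homology chains, rule-boundary decoys), so every stage is testable
end to end from nothing but a seed.

## Worked example

```bash
python examples/01_profile_cohort.py
```

```
 mag_id  EC  OM  CW  PP  UNK  UNK_SP  EXTRA_CYTOPLASMIC  abundant
MAG0001   2   1   0   2   76      22                  5      True
MAG0002   3   4   0   3   76      25                 10     False
MAG0003   4   0   3   0   68      28                  7     False
MAG0004   2   0   2   0   86      18                  4      True
MAG0005   2   0   0   0   76      18                  2      True

% extracellular proteins with a signal peptide: 92.3
% unknown-location proteins with a signal peptide: 29.1
Pearson r (UNK+SP vs extra-cytoplasmic counts): 0.793 (p = 0.11)

planted-truth recovery: min precision 1.00, min recall 1.00 over 18 classes
```

Each row is one genome's secretome profile: e.g. MAG0002 exports ten proteins
via known compartments and carries 25 more likely-secreted UNK+SP proteins.
The recovery line re-derives every planted label from the pipeline output —
on a noise-free cohort all 18 classes (7 compartments, UNK+SP, 9 enzyme
classes, multi-heme cytochromes) are recovered perfectly. The other examples
demonstrate heme scanning, the alignment engine, the enzyme rules and
orthogroup clustering; a thin CLI (`secretome-profiler run|generate|
scan-heme|search|flag|cluster-og`) wraps the same functions for shell use.

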