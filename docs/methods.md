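# Methods

## Scope and model

The package treats secretome profiling as an *integration* problem: the
sequence-level predictors (subcellular location, signal peptides, domains,
CAZyme/peptidase family assignment, orthogroup inference) are consumed as
tabular inputs in their common dialects, and the package's own contribution
is everything downstream — the integration rules, the enzyme-classification
procedures, the CxxCH scanner, the iterative homology expansion, the per-MAG
aggregation and the cohort statistics. Nothing re-derives localisation or
family membership from sequence.

## Compartment integration

Each protein has exactly one location call; its compartment is taken verbatim
after label normalisation (an explicit, versioned vocabulary table maps
predictor dialects — `Cellwall`, `Outer Membrane`, `Unknown (multiple
localizations)`, … — onto seven canonical categories). Signal-peptide
evidence is layered on top:

* `unk_sp` is true iff the category is UNKNOWN **and the primary detector**
  calls a signal peptide. The tri-method screen exists for predicted
  extracellular proteins; its vote count travels separately as `sp_support`
  (0–3) and never changes the category.
* Extra-cytoplasmic = EC ∪ OM ∪ CW ∪ PP; the four categories are disjoint so
  the union size is their sum.
* Envelope constraints are integrity checks, not reassignments: OM/PP in a
  monoderm MAG (or CW in a diderm) is an error naming MAG and protein.
  Archaeal envelopes are treated as monoderm for validity because archaeal
  location profiles have no OM/PP classes.

Location scores are accepted as given (no re-thresholding beyond the
predictor's own defaults).

## Enzyme classification

Thresholds live in one `PipelineConfig` (defaults: CAZyme ≥ 2 methods,
peptidase e ≤ 10⁻²⁰, expansion e ≤ 10⁻¹⁰, lipase e ≤ 10⁻⁵, multi-heme ≥ 4
sites, flag multiplier 2, abundance cutoff 0.1 %, top-100 orthogroups, ≤ 10
expansion rounds). Domain accept/reject lists and keyword lists are data, not
code: they ship as versioned YAML under `secretome_profiler/rules/` and match
exactly on whitespace-normalised names (a trailing `" superfamily"` is part
of the name as printed by domain-search tools).

Decisions taken where the procedure left room:

* **E-value cutoffs** compare with a 1 % relative tolerance
  (`evalue ≤ cutoff·1.01`): tool tables print e-values with few significant
  digits, and a hit that passed the upstream tool's own `≤ cutoff` filter
  should not be re-rejected for representation jitter. One order of magnitude
  above the cutoff still fails cleanly.
* **Peptidases**: the best (minimum) e-value per protein decides; the COG
  condition is *exactly* {E} by default ("mapped to other categories" read
  strictly — an E+M protein is excluded), with a config switch
  (`peptidase_strict_cog=False`) relaxing to contains-E. The glutathione-
  hydrolase exclusion is a case-insensitive descriptor substring.
* **Iterative expansion**: rounds are synchronous (a round's candidate set is
  fixed against the database as of the round start); accepted proteins join
  the database for the next round; domain-negative candidates are discarded
  permanently and never re-tested, which both matches the discard rule and
  makes the result the domain-filtered BFS closure of the hit graph — the
  oracle the tests check against. Iteration runs to convergence with a cap of
  10 rounds; non-convergence is a logged warning with a partial result, and
  every call records its acceptance round.
* **CAZymes**: subtype by family prefix; GT families and the murein/
  peptidoglycan-remodelling labels are excluded as biosynthetic. AA
  (auxiliary-activity) families parse validly but are outside the four
  reported secreted-CAZyme subtypes and are dropped.
* **Lipases**: candidacy via seed hit *or* gene-caller keyword
  (case-insensitive substring); acceptance needs an accept-listed domain; a
  PhoD domain rejects regardless of other evidence.

## Heme scanning and cytochrome rules

The scanner reports every 1-based position i with `s[i]=C, s[i+3]=C,
s[i+4]=H`. Overlapping motifs are counted individually — the biological
reading of distinct attachment sites, and the only deterministic choice.
Anchors must be literal C/H (the ambiguity letter X never matches an anchor);
the two wildcard positions accept anything. Multi-heme means
≥ `multiheme_min_sites` (4) motifs.

Cytochrome classification is restricted to the secreted context
(extra-cytoplasmic + UNK+SP); the whole-proteome scan (`heme_scan_scope=
"all"`, the pipeline default) additionally records motif counts for PP/CM
proteins so the per-MAG heme vector (multi-heme EC+OM+CW, multi-heme UNK+SP,
PP ≥ 1 site, CM ≥ 1 site) is complete. The "respiration-related descriptor"
rule is open-ended in practice; it is realised as a configurable keyword list
defaulting to {cytochrome, respiration, respiratory, denitrification, nitrate
reductase, oxidase, reductase} — an interpretation, flagged as such.

## Cohort statistics

* Flags: count > mean + 2·SD with the **sample** SD (n−1; the estimator was
  an open choice) and a strict inequality, as is the abundance label
  (> 0.1 %).
* UNK+SP vs extra-cytoplasmic association: Pearson product–moment r with a
  two-sided t-test p (n−2 df). Zero variance raises rather than returning
  NaN.
* Orthogroup ranking: descending row sums over the MAG subset, ties broken
  by OG id ascending, truncated to the top 100.
* Clustering follows the heatmap recipe: rows centered and scaled to unit
  variance (sample SD), distance d = 1 − Pearson r, average linkage (UPGMA)
  on rows and on columns of the scaled matrix. Pearson was assumed where
  "correlation distance" was ambiguous. Merge ties break deterministically
  (lowest index pair). Newick branch lengths are ultrametric halves of the
  merge heights, so leaf-to-leaf path lengths equal merge distances; heights
  are non-decreasing by construction. Constant rows/columns are errors naming
  the offender (the pipeline drops constant rows before clustering, since
  they carry no correlation signal).

## Similarity engine

Affine-gap Smith–Waterman (a gap of length k costs `gap_open +
k·gap_extend`, defaults −11/−1 on BLOSUM62) with deterministic traceback
(diagonal, then gap-in-subject, then gap-in-query). Ambiguity letters absent
from the matrix score as the matrix minimum. E-values use fixed gapped
Karlin–Altschul constants λ = 0.267, K = 0.041 with m = query length and
n = total database residues (database sizes for e-value computation were
unstated upstream, so the actual supplied database size is used). An external
tool's exact e-values are not reproducible by design; synthetic evidence
therefore places planted e-values ≥ 2 orders of magnitude away from every
cutoff so classifications are robust to the statistics. The search prefilter
skips a pair only when a perfect-match alignment of the shorter sequence
could not reach the cutoff — provably hit-set-preserving.

## Synthetic cohorts: what they emulate, and what they do not

Defaults are 20 MAGs × 500 proteins (desk-scale) with category proportions
anchored to the category breakdown reported for large activated-sludge MAG
cohorts (≈ 1.9 % EC, 1.6 % OM, 1.6 % PP,
0.4 % CW in monoderms, 19.9 % CM, ≈ 36 % unknown of which roughly a third
carry signal peptides, 81 % SP probability among EC). Per-class counts are
binomial draws, with a per-MAG secretion-propensity factor (uniform 0.5–1.5)
scaling the secreted and UNK+SP fractions jointly — this emulates the
between-lineage variation in export investment and is what makes the UNK+SP
vs extra-cytoplasmic correlation positive, as observed in real cohorts.

Ground truth is planted constructively: background sequences use the 18
residues excluding C and H, so planted CxxCH counts are exact and nothing
else in the cohort contains a motif; homology chains are realised as hit
rows (or, in `similarity_mode="sequence"`, as point-mutated copies of the
seeds, exercising the aligner end to end); boundary decoys (single-method
CAZymes, GT families, E+M and glutathione peptidases, PhoD lipases,
domain-negative expansion blockers, multi-heme non-cytochromes) are planted
as negatives. Signal peptides are planted as table rows, not realistic
N-terminal sequences (the detectors are out of scope); `sp_prefix=True`
prepends a stylised signal-like prefix for realism only.

Passing tests on these cohorts therefore demonstrates that the *rules* are
implemented exactly and recover planted truth perfectly; they do not
demonstrate robustness to predictor noise, compositional bias, or realistic
score distributions, none of which the generator models beyond threshold
placement.

## Numerical and determinism notes

Everything randomised flows from a single integer seed (numpy
`default_rng`); identical config + seed yields byte-identical FASTA, tables,
catalogs, profiles and Newick files. Output rows are sorted by (MAG,
protein); run manifests record a config hash and the seed. Degenerate inputs
are contract errors, not silent NaNs: empty seed databases, empty similarity
databases, < 2 MAGs for flagging, < 3 MAGs or zero variance for correlation,
constant rows for clustering.

## Known limitations

Cohort-scale flag statistics are computed cohort-wide (per-subset flagging is
available by filtering profiles first). The engine is exact and therefore
quadratic per pair; it is meant for seed databases and small proteomes, not
for replacing a production aligner on millions of pairs. Guild labels
(PAO/GAO, nitrifiers, filaments) are user-supplied annotations, never
inferred.
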