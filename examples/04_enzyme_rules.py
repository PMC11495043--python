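"""The four catabolic-enzyme classification procedures on tiny inputs.

Shows which evidence is accepted and which is filtered away: CAZyme calls
need >= 2 detection methods and a non-biosynthetic family; nutrient
peptidases need a strong peptidase-database hit (e <= 1e-20) mapped to COG
category E only; lipases need a seed hit or gene-caller keyword plus a lipase
domain (and no PhoD); nucleases grow from a seed database by iterative
homology expansion in which domain-negative candidates block propagation.
"""
from secretome_profiler import (
    CazyCall,
    FunctionalAnnotation,
    MeropsHit,
    ProteinRecord,
    SimilarityHit,
    classify_lipases,
    classify_peptidases,
    filter_cazymes,
    iterative_expansion,
    load_ruleset,
)

TWO = frozenset({"HMM", "HOTPEP"})
cazy = filter_cazymes([
    CazyCall("amylase", "GH13", TWO, "Glycoside hydrolase family 13"),
    CazyCall("weak", "GH13", frozenset({"HMM"}), "only one method"),
    CazyCall("biosynthetic", "GT2", TWO, "Glycoside transferases"),
])
print("CAZymes kept:", [(c.protein_id, c.enzyme_class.value) for c in cazy])

pept = classify_peptidases(
    [MeropsHit("m4_like", "M4", 1e-30), MeropsHit("housekeeping", "C26", 1e-30)],
    [
        FunctionalAnnotation("m4_like", "og_mapper", "Thermolysin-like peptidase", frozenset("E")),
        FunctionalAnnotation("housekeeping", "og_mapper", "Murein peptidase", frozenset("M")),
    ],
)
print("nutrient peptidases:", [c.protein_id for c in pept])

rules = load_ruleset("lipase")
def seed_hit(q, e): return SimilarityHit(q, "LIPASE_SEED_01", 90, 80, 4, 1, 1, 80, 1, 80, e, 200)
from secretome_profiler import DomainHit
lip = classify_lipases(
    [seed_hit("estA_like", 1e-8), seed_hit("phosphatase", 1e-8)], [],
    [DomainHit("estA_like", "EstA", 1e-9),
     DomainHit("phosphatase", "EstA", 1e-9), DomainHit("phosphatase", "PhoD", 1e-9)],
    rules,
)
print("lipases (PhoD carrier rejected):", [c.protein_id for c in lip])

nuc_rules = load_ruleset("nuclease")
accept = sorted(nuc_rules.accept_domains)[0]
seeds = [ProteinRecord("SEED1", "SEEDDB", "MKTA")]
proteome = [ProteinRecord(p, "magA", "MKTA") for p in ("roundone", "roundtwo", "blocked")]
hits = [
    SimilarityHit("roundone", "SEED1", 90, 80, 4, 1, 1, 80, 1, 80, 1e-30, 200),
    SimilarityHit("roundtwo", "roundone", 90, 80, 4, 1, 1, 80, 1, 80, 1e-30, 200),
    SimilarityHit("blocked", "SEED1", 90, 80, 4, 1, 1, 80, 1, 80, 1e-30, 200),
]
domains = {"roundone": {accept}, "roundtwo": {accept}}  # "blocked" has no nuclease domain
out = iterative_expansion(seeds, proteome, hits, nuc_rules, domains)
print("nuclease expansion:",
      [(c.protein_id, f"round {c.evidence['iteration']}") for c in out])
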