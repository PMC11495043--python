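"""Enzyme classification rules: CAZyme acceptance, nutrient-peptidase
filtering, lipase rules, and the iterative homology expansion vs a BFS
closure oracle."""
from __future__ import annotations

import random

import pytest

from secretome_profiler import (
    CazyCall,
    DomainHit,
    EnzymeClass,
    FormatError,
    FunctionalAnnotation,
    MeropsHit,
    PipelineConfig,
    ProteinRecord,
    SimilarityHit,
    UsageError,
    classify_lipases,
    classify_peptidases,
    filter_cazymes,
    iterative_expansion,
    load_ruleset,
)
from conftest import bfs_closure

ALL3 = frozenset({"HMM", "HOTPEP", "DIAMOND_METHOD"})
TWO = frozenset({"HMM", "HOTPEP"})
ONE = frozenset({"HMM"})


def hit(q, s, e=1e-30):
    return SimilarityHit(q, s, 90.0, 100, 5, 1, 1, 100, 1, 100, e, 300.0)


def ann(pid, cogs, desc="Peptidase M4", source="og_mapper"):
    return FunctionalAnnotation(pid, source, desc, frozenset(cogs))


class TestCazymes:
    @pytest.mark.parametrize(
        "call, expected_class",
        [
            (CazyCall("p", "GH13", TWO, "Glycoside hydrolase family 13"), EnzymeClass.CAZY_GH),
            (CazyCall("p", "CBM48", ALL3, "binding module"), EnzymeClass.CAZY_CBM),
            (CazyCall("p", "CE1", TWO, "esterase"), EnzymeClass.CAZY_CE),
            (CazyCall("p", "PL9", TWO, "lyase"), EnzymeClass.CAZY_PL),
        ],
    )
    def test_accepted_subtypes(self, call, expected_class):
        (out,) = filter_cazymes([call])
        assert out.enzyme_class == expected_class

    @pytest.mark.parametrize(
        "call",
        [
            CazyCall("p", "GH13", ONE, "hydrolase"),  # below the 2-method rule
            CazyCall("p", "GT2", ALL3, "Glycoside transferases"),  # biosynthetic family
            CazyCall("p", "GH23", TWO, "Soluble_lytic_murein_transglycosylase"),
            CazyCall("p", "GH23", TWO, "Membrane-bound_lytic_murein_transglycosylase_A"),
            CazyCall("p", "AA9", ALL3, "lytic polysaccharide monooxygenase"),
        ],
    )
    def test_rejected_calls(self, call):
        assert filter_cazymes([call]) == []

    def test_bad_family_grammar(self):
        with pytest.raises(FormatError, match="XYZ9"):
            filter_cazymes([CazyCall("p", "XYZ9", TWO, "")])

    def test_no_duplicate_protein_class_pairs(self):
        calls = [CazyCall("p", "GH13", TWO, "a"), CazyCall("p", "GH5", ALL3, "b")]
        assert len(filter_cazymes(calls)) == 1


class TestPeptidases:
    def test_nutrient_peptidase_accepted(self):
        out = classify_peptidases([MeropsHit("p", "M4", 1e-25)], [ann("p", "E")])
        assert [c.enzyme_class for c in out] == [EnzymeClass.PEPTIDASE_NUTRIENT]

    @pytest.mark.parametrize(
        "hit_e, cogs, desc, expected",
        [
            (1e-25, "M", "Peptidase", False),       # mapped to another category
            (1e-25, "EM", "Peptidase", False),      # E plus another category (strict)
            (1e-15, "E", "Peptidase", False),       # above the e-value cutoff
            (1e-25, "E", "Glutathione Hydrolase proenzyme", False),  # housekeeping
            (1e-25, "E", "Peptidase M4", True),
        ],
    )
    def test_filters(self, hit_e, cogs, desc, expected):
        out = classify_peptidases([MeropsHit("p", "M4", hit_e)], [ann("p", cogs, desc)])
        assert bool(out) is expected

    def test_relaxed_cog_mode_accepts_mixed_categories(self):
        cfg = PipelineConfig(peptidase_strict_cog=False)
        out = classify_peptidases([MeropsHit("p", "M4", 1e-25)], [ann("p", "EM")], cfg)
        assert len(out) == 1

    def test_best_evalue_wins_over_weak_extra_hits(self):
        hits = [MeropsHit("p", "M4", 1e-5), MeropsHit("p", "S8", 1e-30)]
        out = classify_peptidases(hits, [ann("p", "E")])
        assert out and out[0].evidence["best_evalue"] == 1e-30

    def test_missing_annotation_excluded_not_fatal(self):
        assert classify_peptidases([MeropsHit("p", "M4", 1e-25)], []) == []

    @pytest.mark.parametrize(
        "evalue, accepted",
        [(1e-20, True), (1.01e-20, True), (1e-19, False)],
    )
    def test_cutoff_boundary(self, evalue, accepted):
        """The cutoff is <= 1e-20 with tolerance for printed-precision jitter:
        a value equal to the threshold passes, one order of magnitude above
        does not."""
        out = classify_peptidases([MeropsHit("p", "M4", evalue)], [ann("p", "E")])
        assert bool(out) is accepted


class TestLipases:
    RULES = load_ruleset("lipase")

    def test_seed_hit_plus_domain(self):
        out = classify_lipases([hit("p", "LIPASE_SEED_01", 1e-7)], [],
                               [DomainHit("p", "Lipase_3", 1e-8)], self.RULES)
        assert [c.enzyme_class for c in out] == [EnzymeClass.LIPASE]

    def test_gene_caller_keyword_route(self):
        out = classify_lipases(
            [], [ann("p", "", "Multifunctional_esterase", source="gene_caller")],
            [DomainHit("p", "Abhydrolase", 1e-8)], self.RULES,
        )
        assert len(out) == 1 and out[0].evidence["keyword"] == "multifunctional_esterase"

    def test_phod_rejects_despite_other_evidence(self):
        out = classify_lipases(
            [hit("p", "LIPASE_SEED_01", 1e-7)], [],
            [DomainHit("p", "Lipase_3", 1e-8), DomainHit("p", "PhoD", 1e-9)], self.RULES,
        )
        assert out == []

    def test_candidate_without_accept_domain_rejected(self):
        out = classify_lipases([hit("p", "LIPASE_SEED_01", 1e-7)], [],
                               [DomainHit("p", "DUF1", 1e-8)], self.RULES)
        assert out == []

    def test_seed_hit_above_cutoff_not_a_candidate(self):
        out = classify_lipases([hit("p", "LIPASE_SEED_01", 1e-3)], [],
                               [DomainHit("p", "Lipase_3", 1e-8)], self.RULES)
        assert out == []


def _proteome(ids):
    return [ProteinRecord(i, "m", "MKTA") for i in ids]


SEEDS = [ProteinRecord("SEED1", "SEEDDB", "MKTA")]
NUC = load_ruleset("nuclease")
ACCEPT_DOMAIN = sorted(NUC.accept_domains)[0]


class TestIterativeExpansion:
    def test_chain_accepted_round_by_round(self):
        hits = [hit("A", "SEED1"), hit("B", "A")]
        domains = {"A": {ACCEPT_DOMAIN}, "B": {ACCEPT_DOMAIN}}
        out = iterative_expansion(SEEDS, _proteome("AB"), hits, NUC, domains)
        rounds = {c.protein_id: c.evidence["iteration"] for c in out}
        assert rounds == {"A": 1, "B": 2}

    def test_domain_negative_candidate_blocks_propagation(self):
        hits = [hit("A", "SEED1"), hit("B", "A")]
        domains = {"B": {ACCEPT_DOMAIN}}  # A lacks an accept domain
        out = iterative_expansion(SEEDS, _proteome("AB"), hits, NUC, domains)
        assert out == []

    def test_no_hits_converges_immediately(self):
        out = iterative_expansion(SEEDS, _proteome("AB"), [], NUC, {})
        assert out == []

    def test_hits_above_cutoff_ignored(self):
        hits = [hit("A", "SEED1", e=1e-5)]
        out = iterative_expansion(SEEDS, _proteome("A"), hits, NUC, {"A": {ACCEPT_DOMAIN}})
        assert out == []

    def test_empty_seed_rejected(self):
        with pytest.raises(UsageError, match="seed"):
            iterative_expansion([], _proteome("A"), [], NUC, {})

    def test_iteration_cap_returns_partial_result(self):
        ids = [f"N{i}" for i in range(6)]
        hits = [hit(ids[0], "SEED1")] + [hit(ids[i], ids[i - 1]) for i in range(1, 6)]
        domains = {i: {ACCEPT_DOMAIN} for i in ids}
        cfg = PipelineConfig(max_expansion_iterations=3)
        out = iterative_expansion(SEEDS, _proteome(ids), hits, NUC, domains, cfg)
        assert {c.protein_id for c in out} == set(ids[:3])
        assert all(not c.evidence["converged"] for c in out)

    def test_equals_bfs_closure_on_random_graphs(self):
        """Chains, stars and domain-negative blockers: the expansion equals the
        independently computed domain-filtered BFS closure, rounds included."""
        rng = random.Random(17)
        for _ in range(40):
            n = rng.randint(2, 24)
            ids = [f"P{i}" for i in range(n)]
            edges = []
            for i, pid in enumerate(ids):
                targets = ["SEED1"] + ids[:i]
                for t in rng.sample(targets, k=min(len(targets), rng.randint(1, 2))):
                    edges.append((pid, t))
            accept_ids = {pid for pid in ids if rng.random() < 0.6}
            hits = [hit(q, s) for q, s in edges]
            domains = {pid: {ACCEPT_DOMAIN} for pid in accept_ids}
            out = iterative_expansion(SEEDS, _proteome(ids), hits, NUC, domains)
            got = {c.protein_id: c.evidence["iteration"] for c in out}
            assert got == bfs_closure({"SEED1"}, edges, accept_ids, set(ids))

    def test_monotone_rounds(self, small_cohort):
        d, cohort = small_cohort
        from secretome_profiler import read_fasta, read_table

        proteome = read_fasta(d / "proteins.fasta")
        hits = read_table("similarity", d / "similarity" / "nuclease.tsv")
        domains = read_table("domain", d / "domains.tsv")
        seeds = read_fasta(d / "seeds" / "nuclease_seeds.fasta")
        out = iterative_expansion(seeds, proteome, hits, NUC, domains)
        truth = {p for p, t in cohort.manifest.proteins.items()
                 if "NUCLEASE" in t["enzyme_classes"]}
        assert {c.protein_id for c in out} == truth
        rounds = [c.evidence["iteration"] for c in out]
        assert all(1 <= r <= PipelineConfig().max_expansion_iterations for r in rounds)
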