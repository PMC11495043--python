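"""Generator contracts: determinism, planted-motif exactness, envelope
feasibility, manifest self-consistency, recovery evaluation."""
from __future__ import annotations

import hashlib
import os

import pandas as pd
import pytest

from secretome_profiler import (
    CohortConfig,
    ConfigError,
    IntegrityError,
    TruthManifest,
    evaluate_recovery,
    generate_cohort,
    read_fasta,
    read_table,
    run_pipeline,
)
from conftest import sliding_window_motifs


def _tree_hash(root) -> str:
    h = hashlib.sha256()
    for dirpath, dirs, files in sorted(os.walk(root)):
        dirs.sort()
        for name in sorted(files):
            path = os.path.join(dirpath, name)
            h.update(os.path.relpath(path, root).encode())
            h.update(open(path, "rb").read())
    return h.hexdigest()


class TestGenerator:
    def test_same_seed_gives_byte_identical_cohorts(self, tmp_path):
        cfg = CohortConfig(n_mags=2, proteins_per_mag=10, seed=7)
        hashes = []
        for sub in ("a", "b"):
            generate_cohort(cfg, tmp_path / sub)
            hashes.append(_tree_hash(tmp_path / sub))
        assert hashes[0] == hashes[1]

    def test_different_seed_changes_output(self, tmp_path):
        generate_cohort(CohortConfig(n_mags=2, proteins_per_mag=30, seed=1), tmp_path / "a")
        generate_cohort(CohortConfig(n_mags=2, proteins_per_mag=30, seed=2), tmp_path / "b")
        assert _tree_hash(tmp_path / "a") != _tree_hash(tmp_path / "b")

    def test_planted_motif_counts_are_exact(self, small_cohort):
        """Brute-force recount: every emitted sequence carries exactly the
        manifest's number of CxxCH motifs (zero for background proteins)."""
        d, cohort = small_cohort
        records = {r.protein_id: r.sequence for r in read_fasta(d / "proteins.fasta")}
        assert set(records) == set(cohort.manifest.proteins)
        for pid, truth in cohort.manifest.proteins.items():
            assert len(sliding_window_motifs(records[pid])) == truth["n_heme_motifs"]

    def test_monoderm_cohort_with_om_fraction_rejected(self):
        with pytest.raises(ConfigError, match="diderm"):
            CohortConfig(n_mags=4, envelope_mix=0.0)

    def test_all_diderm_cohort_with_cw_fraction_rejected(self):
        with pytest.raises(ConfigError, match="monoderm"):
            CohortConfig(n_mags=4, envelope_mix=1.0)

    def test_envelope_respects_planting(self, small_cohort):
        d, cohort = small_cohort
        envelopes = {e.mag_id: e.envelope.value for e in read_table("envelope", d / "envelopes.tsv")}
        for truth in cohort.manifest.proteins.values():
            if truth["compartment"] in ("OUTER_MEMBRANE", "PERIPLASMIC"):
                assert envelopes[truth["mag_id"]] == "DIDERM"
            if truth["compartment"] == "CELL_WALL":
                assert envelopes[truth["mag_id"]] == "MONODERM"

    def test_manifest_counts_match_generated_tables(self, small_cohort):
        """Self-consistency: planted class members can be recounted from the
        emitted evidence files."""
        d, cohort = small_cohort
        truth = cohort.manifest.proteins
        merops = read_table("merops", d / "merops.tsv")
        planted_pept = {p for p, t in truth.items() if "PEPTIDASE_NUTRIENT" in t["enzyme_classes"]}
        assert planted_pept <= {h.protein_id for h in merops}
        domains = read_table("domain", d / "domains.tsv")
        by_protein = {}
        for h in domains:
            by_protein.setdefault(h.protein_id, set()).add(h.domain_name)
        from secretome_profiler import load_ruleset

        for cls in ("NUCLEASE", "RNASE", "NUCLEOTIDASE"):
            accept = load_ruleset(cls.lower()).accept_domains
            for p, t in truth.items():
                if cls in t["enzyme_classes"]:
                    assert by_protein[p] & accept

    def test_background_sequences_avoid_c_and_h(self, small_cohort):
        d, cohort = small_cohort
        for rec in read_fasta(d / "proteins.fasta"):
            if cohort.manifest.proteins[rec.protein_id]["n_heme_motifs"] == 0:
                assert "C" not in rec.sequence and "H" not in rec.sequence

    def test_fraction_validation(self):
        with pytest.raises(ConfigError, match="fractions"):
            fractions = {
                "extracellular": 0.7, "outer_membrane": 0.2, "cell_wall": 0.0,
                "periplasmic": 0.2, "cm": 0.2, "cytoplasmic": 0.2,
                "unknown_with_sp": 0.1, "cazyme_by_subtype": {},
                "peptidase_nutrient": 0, "peptidase_housekeeping": 0, "lipase": 0,
                "nuclease": 0, "rnase": 0, "nucleotidase": 0,
                "multiheme_cytochrome": 0,
            }
            CohortConfig(planted_fractions=fractions)


class TestRecovery:
    def test_noise_free_cohort_recovers_perfectly(self, small_cohort, small_result):
        _, cohort = small_cohort
        table = evaluate_recovery(cohort.manifest, small_result.catalog)
        assert (table["precision"] == 1.0).all() and (table["recall"] == 1.0).all()

    def test_planned_miss_lowers_recall(self, tmp_path):
        cfg = CohortConfig(n_mags=3, proteins_per_mag=200, seed=5,
                           peptidase_planned_misses=1)
        cohort = generate_cohort(cfg, tmp_path)
        result = run_pipeline(tmp_path)
        (missed,) = [p for p, t in cohort.manifest.proteins.items() if t["planned_miss"]]
        row = result.catalog.set_index("protein_id").loc[missed]
        assert not row["peptidase_nutrient"]
        table = evaluate_recovery(cohort.manifest, result.catalog).set_index("class")
        pept = table.loc["PEPTIDASE_NUTRIENT"]
        assert pept["fn"] == 1 and pept["recall"] < 1.0 and pept["precision"] == 1.0

    def test_empty_cohort_gives_empty_table(self):
        table = evaluate_recovery(TruthManifest(proteins={}), pd.DataFrame())
        assert len(table) == 0

    def test_id_mismatch_rejected(self, small_cohort, small_result):
        _, cohort = small_cohort
        truncated = small_result.catalog.iloc[:-1]
        with pytest.raises(IntegrityError, match="mismatch"):
            evaluate_recovery(cohort.manifest, truncated)
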