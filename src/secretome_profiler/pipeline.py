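"""End-to-end orchestration: cohort directory in, catalog + profiles out.

The expected directory layout is the one :func:`secretome_profiler.synthetic.
generate_cohort` writes (and which mirrors the flat-file outputs of the
emulated upstream tools):

    proteins.fasta            MAGID|PROTEINID headers
    locations.tsv             protein_id  raw_location_label  score
    signal_peptides.tsv       protein_id  method  Y/N  SEC|TAT|NONE
    domains.tsv               protein_id  domain_name  evalue
    annotations.tsv           protein_id  gene_caller|og_mapper  COGs  descriptor
    cazy.tsv                  protein_id  family  methods  class_label
    merops.tsv                protein_id  family  evalue
    orthogroups.tsv           og_id  protein_id
    abundance.tsv             mag_id  mean_relative_abundance (%)
    envelopes.tsv             mag_id  DIDERM|MONODERM|ARCHAEAL
    seeds/<class>_seeds.fasta seed databases (nuclease, rnase, nucleotidase, lipase)
    similarity/<class>.tsv    externally computed hits (optional with use_engine)

With ``use_engine=True`` the similarity tables are ignored and the built-in
Smith–Waterman engine searches the proteome against the seed databases
directly.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import compartments, enzymes, heme, io_formats, profiling, similarity
from .config import PipelineConfig
from .errors import FormatError
from .records import EnzymeClass, Location
from .rulesets import load_ruleset

logger = logging.getLogger(__name__)

_EXPANSION_CLASSES = ("nuclease", "rnase", "nucleotidase")

#: compartment context in which secreted-heme profiling happens
_SECRETED_SCAN = "secreted"
_WHOLE_PROTEOME_SCAN = "all"


@dataclass
class PipelineResult:
    catalog: pd.DataFrame
    profiles: pd.DataFrame
    summary: profiling.CohortSummary
    og_matrix: pd.DataFrame


def _read_optional(kind: str, path) -> list:
    if not os.path.exists(path):
        return []
    return io_formats.read_table(kind, path)


def run_pipeline(cohort_dir, config: PipelineConfig | None = None,
                 use_engine: bool = False,
                 heme_scan_scope: str = _WHOLE_PROTEOME_SCAN) -> PipelineResult:
    """Run every stage over a cohort directory and assemble the outputs.

    ``heme_scan_scope`` — "secreted" profiles CxxCH content only for
    extra-cytoplasmic and UNK+SP proteins (the secreted-heme report); "all"
    additionally records motif counts for periplasmic/membrane proteins so the
    per-MAG heme count vector is complete. Cytochrome classification is always
    restricted to the secreted set.
    """
    config = config or PipelineConfig()
    d = os.fspath(cohort_dir)
    p = lambda *parts: os.path.join(d, *parts)

    proteins = io_formats.read_fasta(p("proteins.fasta"))
    protein_to_mag = {r.protein_id: r.mag_id for r in proteins}
    by_id = {r.protein_id: r for r in proteins}

    location_calls = io_formats.read_table("location", p("locations.tsv"))
    sp_calls = _read_optional("signal_peptide", p("signal_peptides.tsv"))
    domain_hits = _read_optional("domain", p("domains.tsv"))
    annotations = _read_optional("annotation", p("annotations.tsv"))
    cazy_calls = _read_optional("cazy", p("cazy.tsv"))
    merops_hits = _read_optional("merops", p("merops.tsv"))
    og_rows = _read_optional("orthogroup", p("orthogroups.tsv"))
    abundance = _read_optional("abundance", p("abundance.tsv"))
    envelope_rows = io_formats.read_table("envelope", p("envelopes.tsv"))
    envelopes = {e.mag_id: e for e in envelope_rows}

    for kind, rows in (("location", location_calls), ("signal_peptide", sp_calls),
                       ("domain", domain_hits), ("annotation", annotations),
                       ("cazy", cazy_calls), ("merops", merops_hits)):
        orphans = io_formats.unknown_ids(rows, set(protein_to_mag))
        if orphans:
            logger.warning("%s table references %d unknown protein ids (e.g. %s)",
                           kind, len(orphans), orphans[:3])

    # --- compartments ------------------------------------------------------
    assignments = compartments.assign_all(location_calls, sp_calls, envelopes, protein_to_mag)
    by_protein = {a.protein_id: a for a in assignments}

    # --- enzyme classes ----------------------------------------------------
    calls: dict[str, list] = {}
    calls["cazy"] = enzymes.filter_cazymes(cazy_calls, config)
    calls["peptidase"] = enzymes.classify_peptidases(merops_hits, annotations, config)
    dom_idx = enzymes.domain_index(domain_hits)

    lipase_rules = load_ruleset("lipase")
    if use_engine:
        lipase_seeds = io_formats.read_fasta(p("seeds", "lipase_seeds.fasta"))
        lipase_hits = similarity.search(proteins, lipase_seeds, config.lipase_evalue_cutoff)
    else:
        lipase_hits = _read_optional("similarity", p("similarity", "lipase.tsv"))
    calls["lipase"] = enzymes.classify_lipases(lipase_hits, annotations, dom_idx,
                                               lipase_rules, config)

    for cls in _EXPANSION_CLASSES:
        seeds = io_formats.read_fasta(p("seeds", f"{cls}_seeds.fasta"))
        if use_engine:
            source = lambda prot, db: similarity.search(prot, db, config.nuclease_evalue_cutoff)
        else:
            source = _read_optional("similarity", p("similarity", f"{cls}.tsv"))
        calls[cls] = enzymes.iterative_expansion(seeds, proteins, source,
                                                 load_ruleset(cls), dom_idx, config)

    enzyme_calls = calls["cazy"] + calls["peptidase"] + calls["lipase"]
    for cls in _EXPANSION_CLASSES:
        enzyme_calls += calls[cls]

    # --- heme --------------------------------------------------------------
    gene_ann = enzymes.annotation_index(annotations, "gene_caller")
    og_ann = enzymes.annotation_index(annotations, "og_mapper")
    heme_profiles: dict[str, heme.HemeProfile] = {}
    n_motifs_all: dict[str, int] = {}
    for rec in proteins:
        a = by_protein.get(rec.protein_id)
        if a is None:
            continue
        in_secreted = a.is_extra_cytoplasmic or a.unk_sp
        if heme_scan_scope == _SECRETED_SCAN and not in_secreted:
            continue
        positions = heme.scan_heme_motifs(rec.sequence)
        n_motifs_all[rec.protein_id] = len(positions)
        if not positions:
            continue
        if in_secreted:
            g = gene_ann.get(rec.protein_id)
            o = og_ann.get(rec.protein_id)
            heme_profiles[rec.protein_id] = heme.classify_heme_protein(
                rec.protein_id, positions,
                gene_caller_name=g.descriptor if g else "",
                descriptor=o.descriptor if o else "",
                domains=dom_idx.get(rec.protein_id, ()),
                config=config,
            )
        else:
            heme_profiles[rec.protein_id] = heme.HemeProfile(
                protein_id=rec.protein_id, motif_positions=tuple(positions),
                is_multiheme=len(positions) >= config.multiheme_min_sites,
                is_cytochrome=False,
            )

    # --- catalog -----------------------------------------------------------
    enzyme_cols = {e.value.lower() for e in EnzymeClass}
    calls_by_protein: dict[str, set] = {}
    for call in enzyme_calls:
        calls_by_protein.setdefault(call.protein_id, set()).add(call.enzyme_class.value.lower())
    rows = []
    for rec in proteins:
        a = by_protein.get(rec.protein_id)
        if a is None:
            raise FormatError(f"protein {rec.protein_id!r} has no location call")
        hp = heme_profiles.get(rec.protein_id)
        row = {
            "protein_id": rec.protein_id,
            "mag_id": rec.mag_id,
            "length": rec.length,
            "category": a.category.value,
            "raw_location": a.raw_label,
            "unk_sp": a.unk_sp,
            "sp_support": a.sp_support,
            "is_extra_cytoplasmic": a.is_extra_cytoplasmic,
            "n_heme_motifs": n_motifs_all.get(rec.protein_id, 0),
            "heme_motif_positions": ",".join(map(str, hp.motif_positions)) if hp else "",
            "is_multiheme": bool(hp.is_multiheme) if hp else False,
            "is_cytochrome": bool(hp.is_cytochrome) if hp else False,
            "heme_rules": ",".join(sorted(hp.rule_fired)) if hp else "",
        }
        mine = calls_by_protein.get(rec.protein_id, set())
        for col in sorted(enzyme_cols):
            row[col] = col in mine
        rows.append(row)
    catalog = pd.DataFrame(rows).sort_values(["mag_id", "protein_id"], kind="mergesort")
    catalog = catalog.reset_index(drop=True)

    # --- per-MAG profiles --------------------------------------------------
    abundance_by_mag = {a.mag_id: a for a in abundance}
    assignments_by_mag: dict[str, list] = {}
    for a in assignments:
        assignments_by_mag.setdefault(a.mag_id, []).append(a)
    enzymes_by_mag: dict[str, list] = {}
    for call in enzyme_calls:
        enzymes_by_mag.setdefault(protein_to_mag.get(call.protein_id, ""), []).append(call)
    heme_by_mag: dict[str, dict] = {}
    for pid, hp in heme_profiles.items():
        heme_by_mag.setdefault(protein_to_mag.get(pid, ""), {})[pid] = hp
    mag_profiles = []
    for mag_id in sorted(assignments_by_mag):
        mag_profiles.append(
            profiling.build_mag_profile(
                mag_id,
                assignments_by_mag[mag_id],
                enzymes_by_mag.get(mag_id, []),
                heme_by_mag.get(mag_id, {}),
                abundance_by_mag.get(mag_id),
                config,
            )
        )
    profiles = pd.DataFrame([m.as_row() for m in mag_profiles])

    summary = profiling.summarize_cohort(catalog, profiles, config)
    for metric, fr in summary.flag_stats.items():
        for m in mag_profiles:
            if m.mag_id in fr.flagged:
                m.flags.add((metric, "HIGH"))
    profiles = pd.DataFrame([m.as_row() for m in mag_profiles])

    og_matrix = profiling.og_count_matrix(og_rows, protein_to_mag)
    return PipelineResult(catalog=catalog, profiles=profiles, summary=summary,
                          og_matrix=og_matrix)


def run_and_write(cohort_dir, outdir, config: PipelineConfig | None = None,
                  seed: int | None = None, use_engine: bool = False) -> PipelineResult:
    """Run the pipeline and write catalog/profiles/manifest plus, when the
    orthogroup matrix is clusterable, its row/column dendrograms in Newick."""
    config = config or PipelineConfig()
    result = run_pipeline(cohort_dir, config, use_engine=use_engine)
    io_formats.write_outputs(result.catalog, result.profiles, outdir, config, seed)
    matrix = result.og_matrix
    if len(matrix):
        # constant rows carry no correlation signal and are unclusterable
        matrix = matrix[matrix.std(axis=1, ddof=1) > 0]
    if matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
        try:
            clustering = profiling.cluster_og_matrix(matrix)
        except Exception as exc:  # degenerate matrices are not fatal for a run
            logger.warning("orthogroup clustering skipped: %s", exc)
        else:
            with open(os.path.join(outdir, "og_rows.nwk"), "w") as fh:
                fh.write(clustering.row_newick + "\n")
            with open(os.path.join(outdir, "og_cols.nwk"), "w") as fh:
                fh.write(clustering.col_newick + "\n")
        result.og_matrix.to_csv(os.path.join(outdir, "og_matrix.tsv"), sep="\t")
    return result
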