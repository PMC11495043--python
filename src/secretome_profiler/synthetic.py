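"""Synthetic cohorts with planted, machine-readable ground truth.

The generator emits everything the pipeline consumes — per-MAG protein FASTA,
location calls, signal-peptide calls, conserved-domain hits, functional
annotations, CAZyme calls, peptidase-database hits, similarity hits, seed
databases, orthogroup membership and relative abundances — together with a
truth manifest recording what was planted where. Default proportions are
anchored to the category breakdown reported for large activated-sludge MAG
cohorts (about 2% extracellular,
1.6% outer-membrane and periplasmic each, 20% membrane-bound, 36% unknown of
which roughly a third carry signal peptides).

Construction guarantees, relied on by tests:

* background sequences are sampled from the 18 residues excluding C and H, so
  a planted heme protein contains *exactly* its manifest number of CxxCH
  motifs and nothing else in the cohort contains any;
* planted homology chains place their e-values at least two orders of
  magnitude below the class cutoffs, and decoy evidence (single-method CAZyme
  calls, wrong-COG peptidases, PhoD lipases, domain-negative homologs) is
  planted on proteins whose manifest entry marks them negative, so
  precision/recall against the manifest is exactly 1.0 for every class under
  noise-free settings.

Signal peptides are planted as table rows (the detectors themselves are out of
scope); ``sp_prefix`` optionally prepends a stylised N-terminal signal-like
sequence for realism. Similarity evidence is planted directly as hit rows
(``similarity_mode="table"``), or — to exercise the built-in aligner end to
end — as genuinely similar sequences derived from the seeds by point
mutation (``similarity_mode="sequence"``).
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ConfigError, IntegrityError
from . import io_formats
from .records import (
    AbundanceRecord,
    CazyCall,
    DomainHit,
    Envelope,
    EnvelopeType,
    FunctionalAnnotation,
    Location,
    LocationCall,
    MeropsHit,
    OrthogroupMembership,
    ProteinRecord,
    SignalPeptideCall,
    SimilarityHit,
    SpMethod,
    SpType,
)
from .rulesets import load_heme_rules, load_ruleset

#: background alphabet: the 18 standard residues excluding C and H
BACKGROUND_ALPHABET = "ADEFGIKLMNPQRSTVWY"

_EXPANSION_CLASSES = ("NUCLEASE", "RNASE", "NUCLEOTIDASE")

_RAW_LOCATION_LABELS = {
    Location.EXTRACELLULAR: ("Extracellular",),
    Location.OUTER_MEMBRANE: ("OuterMembrane", "Outer Membrane"),
    Location.CELL_WALL: ("Cellwall", "CellWall"),
    Location.PERIPLASMIC: ("Periplasmic",),
    Location.CYTOPLASMIC_MEMBRANE: ("CytoplasmicMembrane",),
    Location.CYTOPLASMIC: ("Cytoplasmic",),
    Location.UNKNOWN: ("Unknown", "Unknown (multiple localizations)"),
}

_CAZY_FAMILY_POOL = {
    "GH": ("GH13", "GH5", "GH109", "GH23"),
    "CBM": ("CBM48", "CBM2"),
    "CE": ("CE1", "CE4"),
    "PL": ("PL9", "PL1"),
}

_MEROPS_FAMILIES = ("M4", "S8", "M28", "M36")


def default_planted_fractions() -> dict:
    return {
        "extracellular": 0.019,
        "outer_membrane": 0.016,
        "cell_wall": 0.004,
        "periplasmic": 0.016,
        "cm": 0.199,
        "cytoplasmic": 0.387,
        "unknown_with_sp": 0.117,
        "cazyme_by_subtype": {"GH": 0.006, "CBM": 0.003, "CE": 0.003, "PL": 0.002},
        "peptidase_nutrient": 0.004,
        "peptidase_housekeeping": 0.004,
        "lipase": 0.004,
        "nuclease": 0.004,
        "rnase": 0.004,
        "nucleotidase": 0.004,
        "multiheme_cytochrome": 0.004,
    }


@dataclass(frozen=True)
class CohortConfig:
    n_mags: int = 20
    proteins_per_mag: int | tuple = 500
    envelope_mix: float = 0.5  # fraction of MAGs with a diderm envelope
    planted_fractions: dict = field(default_factory=default_planted_fractions)
    homology_chain_length: int = 3
    seed: int = 0
    decoys: bool = True
    sp_prefix: bool = False
    similarity_mode: str = "table"  # "table" | "sequence"
    peptidase_planned_misses: int = 0

    def __post_init__(self) -> None:
        f = self.planted_fractions
        flat = [v for k, v in f.items() if k != "cazyme_by_subtype"]
        flat += list(f.get("cazyme_by_subtype", {}).values())
        if any(not (0.0 <= v <= 1.0) for v in flat):
            raise ConfigError("planted fractions must lie in [0, 1]")
        compartments = ("extracellular", "outer_membrane", "cell_wall", "periplasmic",
                        "cm", "cytoplasmic", "unknown_with_sp")
        if sum(f[c] for c in compartments) > 1.0:
            raise ConfigError("compartment fractions sum to more than 1")
        if not 0.0 <= self.envelope_mix <= 1.0:
            raise ConfigError("envelope_mix must lie in [0, 1]")
        n_diderm = round(self.envelope_mix * self.n_mags)
        if n_diderm == 0 and (f["outer_membrane"] > 0 or f["periplasmic"] > 0):
            raise ConfigError(
                "outer-membrane/periplasmic fractions are infeasible without diderm MAGs"
            )
        if n_diderm == self.n_mags and self.n_mags > 0 and f["cell_wall"] > 0:
            raise ConfigError("cell-wall fraction is infeasible without monoderm MAGs")
        if self.similarity_mode not in ("table", "sequence"):
            raise ConfigError("similarity_mode must be 'table' or 'sequence'")
        if self.homology_chain_length < 1:
            raise ConfigError("homology_chain_length must be >= 1")


@dataclass
class TruthManifest:
    """Planted labels per protein, keyed by protein id."""

    proteins: dict
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "proteins": self.proteins},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(proteins=data["proteins"], config=data.get("config", {}))

    def counts_by_class(self) -> dict:
        counts: dict[str, int] = {}
        for t in self.proteins.values():
            for c in t["enzyme_classes"]:
                counts[c] = counts.get(c, 0) + 1
        return counts


@dataclass
class Cohort:
    """Paths of a generated cohort plus its truth manifest."""

    root: str
    paths: dict
    manifest: TruthManifest


def _new_truth(mag_id: str, compartment: Location, unk_sp: bool = False) -> dict:
    return {
        "mag_id": mag_id,
        "compartment": compartment.value,
        "unk_sp": unk_sp,
        "enzyme_classes": [],
        "n_heme_motifs": 0,
        "is_multiheme": False,
        "is_cytochrome": False,
        "is_seed_homolog": False,
        "sp": {},
        "planned_miss": False,
    }


def _background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_ALPHABET), size=length))


def _heme_sequence(rng: np.random.Generator, n_motifs: int) -> str:
    parts = [_background(rng, int(rng.integers(10, 30)))]
    for _ in range(n_motifs):
        x1, x2 = rng.choice(list(BACKGROUND_ALPHABET), size=2)
        parts.append(f"C{x1}{x2}CH")
        parts.append(_background(rng, int(rng.integers(3, 12))))
    return "".join(parts)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    chars = list(seq)
    sites = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
    for i in sites:
        chars[int(i)] = str(rng.choice(list(BACKGROUND_ALPHABET)))
    return "".join(chars)


def _planted_evalue(rng: np.random.Generator, cutoff: float) -> float:
    # at least two orders of magnitude below the cutoff
    lo = -np.log10(cutoff) + 2.0
    return float(10.0 ** -(rng.uniform(lo, lo + 20.0)))


class _CohortBuilder:
    def __init__(self, config: CohortConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.proteins: list[ProteinRecord] = []
        self.truth: dict[str, dict] = {}
        self.locations: list[LocationCall] = []
        self.sp_calls: list[SignalPeptideCall] = []
        self.domains: list[DomainHit] = []
        self.annotations: list[FunctionalAnnotation] = []
        self.cazy: list[CazyCall] = []
        self.merops: list[MeropsHit] = []
        self.orthogroups: list[OrthogroupMembership] = []
        self.abundance: list[AbundanceRecord] = []
        self.envelopes: list[EnvelopeType] = []
        self.similarity: dict[str, list[SimilarityHit]] = {
            c.lower(): [] for c in _EXPANSION_CLASSES + ("LIPASE",)
        }
        self.seeds: dict[str, list[ProteinRecord]] = {}
        # cohort-wide member lists for homology-chain construction
        self.expansion_members: dict[str, list[str]] = {c: [] for c in _EXPANSION_CLASSES}
        self.sequences: dict[str, str] = {}
        self._peptidase_misses_left = config.peptidase_planned_misses

    # -- helpers ----------------------------------------------------------
    def _add_protein(self, pid: str, mag_id: str, compartment: Location,
                     unk_sp: bool, sequence: str) -> dict:
        self.proteins.append(ProteinRecord(pid, mag_id, sequence))
        self.sequences[pid] = sequence
        t = _new_truth(mag_id, compartment, unk_sp)
        self.truth[pid] = t
        raw_pool = _RAW_LOCATION_LABELS[compartment]
        raw = raw_pool[int(self.rng.integers(len(raw_pool)))]
        self.locations.append(
            LocationCall(pid, compartment, round(float(self.rng.uniform(7.5, 10.0)), 2), raw)
        )
        return t

    def _plant_sp(self, pid: str, methods: Mapping[SpMethod, bool]) -> None:
        t = self.truth[pid]
        for method, has in methods.items():
            sp_type = SpType.NONE
            if has:
                sp_type = SpType.TAT if self.rng.random() < 0.15 else SpType.SEC
            self.sp_calls.append(SignalPeptideCall(pid, method, has, sp_type))
            t["sp"][method.value] = bool(has)
        if self.cfg.sp_prefix and any(methods.values()):
            sig = "M" + _background(self.rng, 14).replace("D", "L").replace("E", "L") + "A"
            seq = sig + self.sequences[pid]
            self.sequences[pid] = seq
            for i, rec in enumerate(self.proteins):
                if rec.protein_id == pid:
                    self.proteins[i] = ProteinRecord(pid, rec.mag_id, seq)
                    break

    # -- seed databases ---------------------------------------------------
    def build_seed_dbs(self) -> None:
        for cls in _EXPANSION_CLASSES + ("LIPASE",):
            recs = []
            for k in range(2):
                sid = f"{cls}_SEED_{k + 1:02d}"
                recs.append(ProteinRecord(sid, "SEEDDB", _background(self.rng, 120)))
            self.seeds[cls.lower()] = recs

    # -- per-MAG generation -----------------------------------------------
    def build_mags(self) -> None:
        cfg = self.cfg
        n_diderm = round(cfg.envelope_mix * cfg.n_mags)
        for i in range(cfg.n_mags):
            mag_id = f"MAG{i + 1:04d}"
            envelope = Envelope.DIDERM if i < n_diderm else Envelope.MONODERM
            self.envelopes.append(EnvelopeType(mag_id, envelope))
            self.abundance.append(
                AbundanceRecord(mag_id, round(float(self.rng.uniform(0.0, 0.5)), 3))
            )
            self._build_one_mag(mag_id, envelope)

    def _count(self, n: int, fraction: float) -> int:
        # binomial draws give the between-genome count variation real cohorts
        # show; the expected proportions stay at the configured fractions
        return int(self.rng.binomial(n, min(1.0, fraction))) if fraction > 0 else 0

    def _compartment_counts(self, n: int, envelope: Envelope, scale: float) -> dict:
        f = self.cfg.planted_fractions
        counts = {
            Location.EXTRACELLULAR: self._count(n, f["extracellular"] * scale),
            Location.CYTOPLASMIC_MEMBRANE: self._count(n, f["cm"]),
            Location.CYTOPLASMIC: self._count(n, f["cytoplasmic"]),
        }
        if envelope == Envelope.DIDERM:
            counts[Location.OUTER_MEMBRANE] = self._count(n, f["outer_membrane"] * scale)
            counts[Location.PERIPLASMIC] = self._count(n, f["periplasmic"] * scale)
            counts[Location.CELL_WALL] = 0
        else:
            counts[Location.OUTER_MEMBRANE] = 0
            counts[Location.PERIPLASMIC] = 0
            counts[Location.CELL_WALL] = self._count(n, f["cell_wall"] * scale)
        n_unk_sp = self._count(n, f["unknown_with_sp"] * scale)
        used = sum(counts.values()) + n_unk_sp
        if used > n:
            raise ConfigError("compartment fractions are infeasible for the proteome size")
        return counts, n_unk_sp, n - used

    def _build_one_mag(self, mag_id: str, envelope: Envelope) -> None:
        cfg, rng = self.cfg, self.rng
        if isinstance(cfg.proteins_per_mag, int):
            n = cfg.proteins_per_mag
        else:
            lo, hi = cfg.proteins_per_mag
            n = int(rng.integers(lo, hi + 1))
        # per-MAG secretion propensity: lineages differ in how much of the
        # proteome is exported, and UNK+SP counts co-vary with it
        scale = float(rng.uniform(0.5, 1.5))
        counts, n_unk_sp, n_unk_plain = self._compartment_counts(n, envelope, scale)

        idx = 0
        # every protein sits in at most one pool, so planting never reuses a host
        pools: dict[str, list[str]] = {"UNK_SP": [], "CY": [], "SECRETED": []}

        def new_pid() -> str:
            nonlocal idx
            idx += 1
            return f"{mag_id}_P{idx:05d}"

        for loc, k in counts.items():
            for _ in range(k):
                pid = new_pid()
                self._add_protein(pid, mag_id, loc, False,
                                  _background(rng, int(rng.integers(80, 201))))
                if loc == Location.EXTRACELLULAR:
                    pools["SECRETED"].append(pid)
                    has = bool(rng.random() < 0.81)
                    self._plant_sp(pid, {SpMethod.PRIMARY: has, SpMethod.TAT: has,
                                         SpMethod.COMBINED: has})
                elif loc in (Location.OUTER_MEMBRANE, Location.CELL_WALL, Location.PERIPLASMIC):
                    pools["SECRETED"].append(pid)
                    self._plant_sp(pid, {SpMethod.PRIMARY: bool(rng.random() < 0.6)})
                elif loc == Location.CYTOPLASMIC:
                    pools["CY"].append(pid)
        for _ in range(n_unk_sp):
            pid = new_pid()
            self._add_protein(pid, mag_id, Location.UNKNOWN, True,
                              _background(rng, int(rng.integers(80, 201))))
            self._plant_sp(pid, {SpMethod.PRIMARY: True})
            pools["UNK_SP"].append(pid)
        for _ in range(n_unk_plain):
            pid = new_pid()
            self._add_protein(pid, mag_id, Location.UNKNOWN, False,
                              _background(rng, int(rng.integers(80, 201))))
            self._plant_sp(pid, {SpMethod.PRIMARY: False})

        self._plant_heme(mag_id, pools, n)
        self._plant_enzymes(mag_id, pools, n)

    # -- heme planting -----------------------------------------------------
    def _take(self, pools: dict, names: tuple, k: int, mag_id: str) -> list[str]:
        out: list[str] = []
        for name in names:
            while pools[name] and len(out) < k:
                out.append(pools[name].pop(0))
            if len(out) == k:
                break
        if len(out) < k:
            raise ConfigError(
                f"MAG {mag_id}: planted fractions are infeasible — not enough host "
                f"proteins in pools {names}"
            )
        return out

    def _replace_sequence(self, pid: str, seq: str) -> None:
        self.sequences[pid] = seq
        for i, rec in enumerate(self.proteins):
            if rec.protein_id == pid:
                self.proteins[i] = ProteinRecord(pid, rec.mag_id, seq)
                return

    def _plant_heme(self, mag_id: str, pools: dict, n: int) -> None:
        cfg, rng = self.cfg, self.rng
        heme_rules = load_heme_rules()
        k = self._count(n, cfg.planted_fractions["multiheme_cytochrome"])
        hosts = self._take(pools, ("SECRETED", "UNK_SP"), k, mag_id)
        cyt_domains = sorted(heme_rules.cytochrome_domains)
        for j, pid in enumerate(hosts):
            n_motifs = int(rng.integers(4, 10))
            self._replace_sequence(pid, _heme_sequence(rng, n_motifs))
            t = self.truth[pid]
            t["n_heme_motifs"] = n_motifs
            t["is_multiheme"] = True
            t["is_cytochrome"] = True
            rule = j % 4
            if rule == 0:
                self.annotations.append(FunctionalAnnotation(
                    pid, "gene_caller", "Cytochrome c biogenesis protein"))
            elif rule == 1:
                self.annotations.append(FunctionalAnnotation(
                    pid, "og_mapper", "cytochrome c family protein", frozenset("C")))
            elif rule == 2:
                dom = cyt_domains[j % len(cyt_domains)]
                self.domains.append(DomainHit(pid, dom, 1e-8))
            else:
                self.annotations.append(FunctionalAnnotation(
                    pid, "og_mapper", "heat shock protein Hsp70-like", frozenset("O")))
        if cfg.decoys and (pools["SECRETED"] or pools["UNK_SP"]):
            # multi-heme but nothing cytochrome-like about it
            pid = self._take(pools, ("SECRETED", "UNK_SP"), 1, mag_id)[0]
            n_motifs = int(rng.integers(4, 8))
            self._replace_sequence(pid, _heme_sequence(rng, n_motifs))
            t = self.truth[pid]
            t["n_heme_motifs"] = n_motifs
            t["is_multiheme"] = True
            self.annotations.append(FunctionalAnnotation(
                pid, "og_mapper", "hypothetical protein", frozenset("S")))

    # -- enzyme planting ---------------------------------------------------
    def _plant_enzymes(self, mag_id: str, pools: dict, n: int) -> None:
        cfg, rng = self.cfg, self.rng
        f = cfg.planted_fractions
        host_pools = ("SECRETED", "UNK_SP", "CY")

        for prefix, frac in f["cazyme_by_subtype"].items():
            fams = _CAZY_FAMILY_POOL[prefix]
            for pid in self._take(pools, host_pools, self._count(n, frac), mag_id):
                methods = [frozenset({"HMM", "HOTPEP"}),
                           frozenset({"HMM", "DIAMOND_METHOD"}),
                           frozenset({"HMM", "HOTPEP", "DIAMOND_METHOD"})][int(rng.integers(3))]
                fam = fams[int(rng.integers(len(fams)))]
                self.cazy.append(CazyCall(pid, fam, methods,
                                          f"Glycoside hydrolase family {fam[2:]}"
                                          if prefix == "GH" else f"{prefix} family protein"))
                self.truth[pid]["enzyme_classes"].append(f"CAZY_{prefix}")

        for pid in self._take(pools, host_pools, self._count(n, f["peptidase_nutrient"]), mag_id):
            missed = self._peptidase_misses_left > 0
            if missed:
                self._peptidase_misses_left -= 1
                evalue = 1e-15
            else:
                evalue = _planted_evalue(rng, 1e-20)
            fam = _MEROPS_FAMILIES[int(rng.integers(len(_MEROPS_FAMILIES)))]
            self.merops.append(MeropsHit(pid, fam, evalue))
            self.annotations.append(FunctionalAnnotation(
                pid, "og_mapper", f"Thermolysin-like metallopeptidase {fam}", frozenset("E")))
            t = self.truth[pid]
            t["enzyme_classes"].append("PEPTIDASE_NUTRIENT")
            t["planned_miss"] = missed

        for pid in self._take(pools, host_pools,
                              self._count(n, f["peptidase_housekeeping"]), mag_id):
            self.merops.append(MeropsHit(pid, "C26", _planted_evalue(rng, 1e-20)))
            self.annotations.append(FunctionalAnnotation(
                pid, "og_mapper", "Cell-wall biosynthesis peptidase", frozenset("M")))

        lipase_rules = load_ruleset("lipase")
        lip_domains = sorted(lipase_rules.accept_domains)
        for j, pid in enumerate(self._take(pools, host_pools,
                                           self._count(n, f["lipase"]), mag_id)):
            self.domains.append(DomainHit(pid, lip_domains[j % len(lip_domains)], 1e-8))
            if j % 2 == 0:
                seed = self.seeds["lipase"][j % 2]
                if cfg.similarity_mode == "table":
                    self.similarity["lipase"].append(self._hit_row(
                        pid, seed.protein_id, _planted_evalue(rng, 1e-5)))
                else:
                    self._replace_sequence(pid, _mutate(rng, seed.sequence, 8))
            else:
                self.annotations.append(FunctionalAnnotation(
                    pid, "gene_caller", "Multifunctional_esterase family protein"))
            self.truth[pid]["enzyme_classes"].append("LIPASE")

        for cls in _EXPANSION_CLASSES:
            key = cls.lower()
            rules = load_ruleset(key)
            accept = sorted(rules.accept_domains)
            for j, pid in enumerate(
                self._take(pools, host_pools, self._count(n, f[key]), mag_id)
            ):
                self.domains.append(DomainHit(pid, accept[j % len(accept)], 1e-8))
                t = self.truth[pid]
                t["enzyme_classes"].append(cls)
                t["is_seed_homolog"] = True
                self.expansion_members[cls].append(pid)

        if cfg.decoys:
            self._plant_decoys(mag_id, pools, n)

    def _plant_decoys(self, mag_id: str, pools: dict, n: int) -> None:
        # decoys are best-effort realism; tiny proteomes simply get fewer
        rng = self.rng

        def take() -> str | None:
            for name in ("CY", "SECRETED", "UNK_SP"):
                if pools[name]:
                    return pools[name].pop(0)
            return None

        # CAZyme: one-method call, GT family, excluded murein label
        if (pid := take()) is not None:
            self.cazy.append(CazyCall(pid, "GH13", frozenset({"HMM"}),
                                      "Glycoside hydrolase family 13"))
        if (pid := take()) is not None:
            self.cazy.append(CazyCall(pid, "GT2",
                                      frozenset({"HMM", "HOTPEP", "DIAMOND_METHOD"}),
                                      "Glycoside transferases"))
        if (pid := take()) is not None:
            self.cazy.append(CazyCall(pid, "GH23", frozenset({"HMM", "HOTPEP"}),
                                      "Soluble_lytic_murein_transglycosylase"))
        # peptidase: E-plus-other COG, glutathione hydrolase
        if (pid := take()) is not None:
            self.merops.append(MeropsHit(pid, "M4", _planted_evalue(rng, 1e-20)))
            self.annotations.append(FunctionalAnnotation(
                pid, "og_mapper", "Peptidase with biosynthetic role", frozenset("EM")))
        if (pid := take()) is not None:
            self.merops.append(MeropsHit(pid, "T3", _planted_evalue(rng, 1e-20)))
            self.annotations.append(FunctionalAnnotation(
                pid, "og_mapper", "Glutathione hydrolase proenzyme", frozenset("E")))
        # lipase: PhoD carrier and domain-negative candidate
        if (pid := take()) is not None:
            self.domains.append(DomainHit(pid, "Lipase_3", 1e-8))
            self.domains.append(DomainHit(pid, "PhoD", 1e-9))
            self.similarity["lipase"].append(self._hit_row(
                pid, self.seeds["lipase"][0].protein_id, _planted_evalue(rng, 1e-5)))
        if (pid := take()) is not None:
            self.domains.append(DomainHit(pid, "DUF9999", 1e-6))
            self.similarity["lipase"].append(self._hit_row(
                pid, self.seeds["lipase"][0].protein_id, _planted_evalue(rng, 1e-5)))

    # -- cohort-wide homology chains ---------------------------------------
    def _hit_row(self, query: str, subject: str, evalue: float) -> SimilarityHit:
        length = int(self.rng.integers(60, 120))
        return SimilarityHit(
            query_id=query, subject_id=subject,
            percent_identity=round(float(self.rng.uniform(35.0, 95.0)), 1),
            alignment_length=length, mismatches=int(length * 0.3), gap_opens=1,
            qstart=1, qend=length, sstart=1, send=length,
            evalue=evalue, bitscore=round(float(self.rng.uniform(80.0, 400.0)), 1),
        )

    def build_homology_chains(self) -> None:
        cfg, rng = self.cfg, self.rng
        for cls in _EXPANSION_CLASSES:
            key = cls.lower()
            members = self.expansion_members[cls]
            seeds = self.seeds[key]
            L = cfg.homology_chain_length
            for c, start in enumerate(range(0, len(members), L)):
                chain = members[start : start + L]
                anchor = seeds[c % len(seeds)]
                prev_id, prev_seq = anchor.protein_id, anchor.sequence
                for pid in chain:
                    if cfg.similarity_mode == "table":
                        self.similarity[key].append(
                            self._hit_row(pid, prev_id, _planted_evalue(rng, 1e-10)))
                    else:
                        seq = _mutate(rng, prev_seq, 8)
                        self._replace_sequence(pid, seq)
                        prev_seq = seq
                    prev_id = pid
            if cfg.decoys and cfg.similarity_mode == "table":
                # blocker chain: X hits the seed but lacks an accept domain,
                # Y hits only X — neither may be accepted.
                for suffix in ("X", "Y"):
                    pid = f"BLOCK_{cls}_{suffix}"
                    # blockers live in the first MAG's cytoplasm
                    mag_id = self.envelopes[0].mag_id
                    self._add_protein(pid, mag_id, Location.CYTOPLASMIC, False,
                                      _background(rng, 120))
                    self.domains.append(DomainHit(pid, "DUF9999", 1e-6))
                x, y = f"BLOCK_{cls}_X", f"BLOCK_{cls}_Y"
                self.similarity[key].append(
                    self._hit_row(x, seeds[0].protein_id, _planted_evalue(rng, 1e-10)))
                self.similarity[key].append(self._hit_row(y, x, _planted_evalue(rng, 1e-10)))

    # -- orthogroups -------------------------------------------------------
    def build_orthogroups(self) -> None:
        by_class: dict[str, list[str]] = {}
        for pid in sorted(self.truth):
            t = self.truth[pid]
            for c in t["enzyme_classes"]:
                by_class.setdefault(f"OG_{c}", []).append(pid)
            if t["is_multiheme"] and t["is_cytochrome"]:
                by_class.setdefault("OG_MULTIHEME_CYT", []).append(pid)
        for og_id in sorted(by_class):
            for pid in by_class[og_id]:
                self.orthogroups.append(OrthogroupMembership(og_id, pid))
        # housekeeping orthogroups shared across MAGs, with copy numbers that
        # vary between genomes (paralog expansions) so the count matrix has
        # between-MAG structure
        per_mag: dict[str, list[str]] = {}
        for pid in sorted(self.truth):
            t = self.truth[pid]
            if t["compartment"] == "CYTOPLASMIC" and not t["enzyme_classes"]:
                per_mag.setdefault(t["mag_id"], []).append(pid)
        for mag_id in sorted(per_mag):
            pool = per_mag[mag_id]
            cursor = 0
            for j in range(3):
                copies = int(self.rng.integers(0, 4))
                for _ in range(copies):
                    if cursor >= len(pool):
                        break
                    self.orthogroups.append(
                        OrthogroupMembership(f"OG_CORE_{j + 1}", pool[cursor]))
                    cursor += 1

    # -- output ------------------------------------------------------------
    def write(self, outdir) -> Cohort:
        os.makedirs(outdir, exist_ok=True)
        os.makedirs(os.path.join(outdir, "seeds"), exist_ok=True)
        os.makedirs(os.path.join(outdir, "similarity"), exist_ok=True)
        paths = {"fasta": os.path.join(outdir, "proteins.fasta")}
        io_formats.write_fasta(self.proteins, paths["fasta"])
        tables = {
            "location": ("locations.tsv", self.locations),
            "signal_peptide": ("signal_peptides.tsv", self.sp_calls),
            "domain": ("domains.tsv", self.domains),
            "annotation": ("annotations.tsv", self.annotations),
            "cazy": ("cazy.tsv", self.cazy),
            "merops": ("merops.tsv", self.merops),
            "orthogroup": ("orthogroups.tsv", self.orthogroups),
            "abundance": ("abundance.tsv", self.abundance),
            "envelope": ("envelopes.tsv", self.envelopes),
        }
        for kind, (name, records) in tables.items():
            path = os.path.join(outdir, name)
            io_formats.write_table(kind, records, path)
            paths[kind] = path
        for key, recs in self.seeds.items():
            path = os.path.join(outdir, "seeds", f"{key}_seeds.fasta")
            io_formats.write_fasta(recs, path)
            paths[f"seeds_{key}"] = path
        if self.cfg.similarity_mode == "table":
            for key, hits in self.similarity.items():
                path = os.path.join(outdir, "similarity", f"{key}.tsv")
                io_formats.write_table("similarity", hits, path)
                paths[f"similarity_{key}"] = path
        manifest = TruthManifest(proteins=self.truth, config=_config_dict(self.cfg))
        paths["truth"] = os.path.join(outdir, "truth.json")
        manifest.to_json(paths["truth"])
        return Cohort(root=os.fspath(outdir), paths=paths, manifest=manifest)


def _config_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    if isinstance(d["proteins_per_mag"], tuple):
        d["proteins_per_mag"] = list(d["proteins_per_mag"])
    return d


def generate_cohort(config: CohortConfig, outdir) -> Cohort:
    """Generate a full synthetic cohort under *outdir* (deterministic in the
    config seed; identical configs produce byte-identical files)."""
    builder = _CohortBuilder(config)
    builder.build_seed_dbs()
    builder.build_mags()
    builder.build_homology_chains()
    builder.build_orthogroups()
    return builder.write(outdir)


# ---------------------------------------------------------------------------
# recovery evaluation

_RECOVERY_ENZYME_CLASSES = (
    "CAZY_GH", "CAZY_CBM", "CAZY_CE", "CAZY_PL", "PEPTIDASE_NUTRIENT",
    "LIPASE", "NUCLEASE", "RNASE", "NUCLEOTIDASE",
)


def evaluate_recovery(manifest: TruthManifest, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-class precision/recall of a pipeline catalog against planted truth.

    Classes: the seven compartments, UNK+SP, the enzyme classes and multi-heme
    cytochromes. Precision/recall are reported as 1.0 when their denominator
    is zero (nothing predicted / nothing planted).
    """
    truth_ids = set(manifest.proteins)
    if len(catalog) == 0 and not truth_ids:
        return pd.DataFrame(columns=["class", "tp", "fp", "fn", "precision", "recall"])
    catalog_ids = set(catalog["protein_id"])
    if catalog_ids != truth_ids:
        raise IntegrityError(
            f"catalog/manifest id mismatch: {len(catalog_ids - truth_ids)} unknown, "
            f"{len(truth_ids - catalog_ids)} missing"
        )
    cat = catalog.set_index("protein_id")
    rows = []

    def prf(name: str, truth_set: set, pred_set: set) -> None:
        tp = len(truth_set & pred_set)
        fp = len(pred_set - truth_set)
        fn = len(truth_set - pred_set)
        rows.append({
            "class": name, "tp": tp, "fp": fp, "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else 1.0,
            "recall": tp / (tp + fn) if tp + fn else 1.0,
        })

    for loc in Location:
        truth_set = {p for p, t in manifest.proteins.items() if t["compartment"] == loc.value}
        pred_set = set(cat.index[cat["category"] == loc.value])
        prf(loc.value, truth_set, pred_set)
    prf("UNK_SP",
        {p for p, t in manifest.proteins.items() if t["unk_sp"]},
        set(cat.index[cat["unk_sp"]]))
    for cls in _RECOVERY_ENZYME_CLASSES:
        truth_set = {p for p, t in manifest.proteins.items() if cls in t["enzyme_classes"]}
        pred_set = set(cat.index[cat[cls.lower()]])
        prf(cls, truth_set, pred_set)
    prf("MULTIHEME_CYTOCHROME",
        {p for p, t in manifest.proteins.items() if t["is_multiheme"] and t["is_cytochrome"]},
        set(cat.index[cat["is_multiheme"] & cat["is_cytochrome"]]))
    return pd.DataFrame(rows)
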