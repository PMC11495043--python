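"""The four catabolic-enzyme classification procedures.

* CAZymes — accept calls detected by at least two of the three methods and
  drop families/labels with probable biosynthetic function (all GT families
  plus murein-remodelling labels).
* Nutrient peptidases — peptidase-database hits at e ≤ 1e-20 whose COG mapping
  is exactly "E" (amino-acid transport and metabolism) and whose descriptor is
  not a glutathione hydrolase.
* Lipases — seed-database hits at e ≤ 1e-5 or gene-caller keyword candidates,
  accepted only with a lipase functional domain and never with a PhoD domain.
* Nucleases / RNases / nucleotidases — iterative seed expansion: search the
  proteome against the seed database, keep hits carrying an accept-listed
  domain, add them to the database and repeat to a fixed point. Domain-negative
  candidates are discarded permanently and never re-seeded, so they also block
  propagation through themselves.
"""
from __future__ import annotations

import logging
import re
from collections import defaultdict
from typing import Callable, Iterable, Mapping, Sequence

from .config import PipelineConfig
from .errors import FormatError, UsageError
from .records import (
    CazyCall,
    DomainHit,
    EnzymeCall,
    EnzymeClass,
    FunctionalAnnotation,
    MeropsHit,
    ProteinRecord,
    SimilarityHit,
)
from .rulesets import DomainRuleSet, load_cazy_rules

logger = logging.getLogger(__name__)

_FAMILY_RE = re.compile(r"^(GH|GT|CBM|CE|PL|AA)(\d*)(?:_\d+)?$")

_SUBTYPE_BY_PREFIX = {
    "GH": EnzymeClass.CAZY_GH,
    "CBM": EnzymeClass.CAZY_CBM,
    "CE": EnzymeClass.CAZY_CE,
    "PL": EnzymeClass.CAZY_PL,
}


def domain_index(domain_hits: Iterable[DomainHit]) -> dict:
    """protein_id → set of domain names."""
    idx: dict[str, set] = defaultdict(set)
    for h in domain_hits:
        idx[h.protein_id].add(h.domain_name)
    return idx


def annotation_index(annotations: Iterable[FunctionalAnnotation],
                     source: str) -> dict:
    """protein_id → annotation for one source; last row wins per protein."""
    return {a.protein_id: a for a in annotations if a.source == source}


# ---------------------------------------------------------------------------
# CAZymes

def filter_cazymes(calls: Sequence[CazyCall],
                   config: PipelineConfig | None = None) -> list[EnzymeCall]:
    """Apply the two-method acceptance rule and the biosynthetic exclusions."""
    config = config or PipelineConfig()
    rules = load_cazy_rules()
    out: list[EnzymeCall] = []
    seen: set[tuple] = set()
    for call in calls:
        m = _FAMILY_RE.match(call.family)
        if not m:
            raise FormatError(f"CAZy family {call.family!r} fails the family grammar")
        if len(call.methods_detected) < config.cazy_min_methods:
            continue
        prefix = m.group(1)
        if prefix in rules.excluded_prefixes:
            continue
        if call.class_label.strip() in rules.excluded_class_labels:
            continue
        subtype = _SUBTYPE_BY_PREFIX.get(prefix)
        if subtype is None:
            # AA (auxiliary-activity) families are not part of the four
            # reported secreted-CAZyme subtypes.
            continue
        key = (call.protein_id, subtype)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            EnzymeCall(
                protein_id=call.protein_id,
                enzyme_class=subtype,
                evidence={
                    "family": call.family,
                    "methods": sorted(call.methods_detected),
                    "class_label": call.class_label,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# nutrient peptidases

def classify_peptidases(hits: Sequence[MeropsHit],
                        annotations: Sequence[FunctionalAnnotation],
                        config: PipelineConfig | None = None) -> list[EnzymeCall]:
    """Peptidase-database hits filtered down to probable nutrient-acquisition
    peptidases.

    Uses each protein's best (minimum) e-value; requires COG category E —
    exactly {E} in strict mode, containing E in relaxed mode — and excludes
    glutathione hydrolases (housekeeping). Hits without an annotation row are
    excluded and logged, not fatal.
    """
    config = config or PipelineConfig()
    ann = annotation_index(annotations, "og_mapper")
    best: dict[str, MeropsHit] = {}
    families: dict[str, set] = defaultdict(set)
    for h in hits:
        families[h.protein_id].add(h.merops_family)
        if h.protein_id not in best or h.evalue < best[h.protein_id].evalue:
            best[h.protein_id] = h
    out: list[EnzymeCall] = []
    for pid in sorted(best):
        hit = best[pid]
        if not config.evalue_passes(hit.evalue, config.merops_evalue_cutoff):
            continue
        a = ann.get(pid)
        if a is None:
            logger.warning("peptidase hit for %r has no functional annotation; excluded", pid)
            continue
        if config.peptidase_strict_cog:
            if a.cog_categories != frozenset("E"):
                continue
        elif "E" not in a.cog_categories:
            continue
        if "glutathione hydrolase" in a.descriptor.lower():
            continue
        out.append(
            EnzymeCall(
                protein_id=pid,
                enzyme_class=EnzymeClass.PEPTIDASE_NUTRIENT,
                evidence={
                    "merops_families": sorted(families[pid]),
                    "best_evalue": hit.evalue,
                    "cog": "".join(sorted(a.cog_categories)),
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# iterative seed expansion (nucleases, RNases, nucleotidases)

HitsSource = Callable[[Sequence[ProteinRecord], Sequence[ProteinRecord]], Sequence[SimilarityHit]]


def iterative_expansion(seed_db: Sequence[ProteinRecord],
                        proteome: Sequence[ProteinRecord],
                        hits_source: Sequence[SimilarityHit] | HitsSource,
                        rules: DomainRuleSet,
                        domain_hits: Sequence[DomainHit] | Mapping[str, set],
                        config: PipelineConfig | None = None) -> list[EnzymeCall]:
    """Grow the seed database by rounds of homology search + domain filtering.

    Each round searches the proteome against the current database (seeds plus
    everything accepted so far) at the class e-value cutoff. Candidates with at
    least one accept-listed domain are accepted and appended to the database;
    candidates lacking one are discarded permanently (they never re-enter and
    cannot propagate hits). Iteration stops at a fixed point or after
    ``max_expansion_iterations`` rounds (the latter flagged in the evidence).

    ``hits_source`` is either a static list of externally computed similarity
    hits (query = proteome protein, subject = seed or accepted protein) or a
    callable ``(proteome, db_records) -> hits`` wrapping the built-in engine.
    """
    config = config or PipelineConfig()
    if not seed_db:
        raise UsageError("iterative expansion requires a non-empty seed database")
    if rules.class_label not in ("NUCLEASE", "RNASE", "NUCLEOTIDASE"):
        raise UsageError(f"iterative expansion does not apply to class {rules.class_label}")
    enzyme_class = EnzymeClass[rules.class_label]
    domains = domain_hits if isinstance(domain_hits, Mapping) else domain_index(domain_hits)
    by_protein = {p.protein_id: p for p in proteome}
    static_hits: list[SimilarityHit] | None = None
    if not callable(hits_source):
        static_hits = [h for h in hits_source
                       if config.evalue_passes(h.evalue, config.nuclease_evalue_cutoff)]

    db_ids = {p.protein_id for p in seed_db}
    db_records = list(seed_db)
    accepted: dict[str, dict] = {}
    discarded: set[str] = set()
    converged = False
    rounds_run = 0
    for rnd in range(1, config.max_expansion_iterations + 1):
        rounds_run = rnd
        if static_hits is not None:
            round_hits = [h for h in static_hits if h.subject_id in db_ids]
        else:
            round_hits = [
                h for h in hits_source(proteome, db_records)
                if config.evalue_passes(h.evalue, config.nuclease_evalue_cutoff)
            ]
        added = False
        for h in sorted(round_hits, key=lambda h: (h.query_id, h.evalue)):
            pid = h.query_id
            if pid in db_ids or pid in accepted or pid in discarded:
                continue
            if pid not in by_protein:
                continue
            if rules.accepts(domains.get(pid, ())):
                accepted[pid] = {"iteration": rnd, "via": h.subject_id, "evalue": h.evalue}
                db_ids.add(pid)
                db_records.append(by_protein[pid])
                added = True
            else:
                discarded.add(pid)
        if not added:
            converged = True
            break
    if not converged:
        logger.warning(
            "%s expansion did not converge within %d rounds; returning partial result",
            rules.class_label, config.max_expansion_iterations,
        )
    return [
        EnzymeCall(
            protein_id=pid,
            enzyme_class=enzyme_class,
            evidence={**ev, "converged": converged, "rounds_run": rounds_run},
        )
        for pid, ev in sorted(accepted.items())
    ]


# ---------------------------------------------------------------------------
# lipases

def classify_lipases(hits: Sequence[SimilarityHit],
                     annotations: Sequence[FunctionalAnnotation],
                     domain_hits: Sequence[DomainHit] | Mapping[str, set],
                     rules: DomainRuleSet,
                     config: PipelineConfig | None = None) -> list[EnzymeCall]:
    """Single-pass lipase classification.

    Candidates are proteins hitting the lipase seed database at the lipase
    cutoff, plus proteins whose gene-caller descriptor contains a lipase
    keyword. A candidate is accepted with at least one accept-listed lipase
    domain, and rejected outright if it carries any reject-listed (PhoD)
    domain, regardless of other evidence.
    """
    config = config or PipelineConfig()
    domains = domain_hits if isinstance(domain_hits, Mapping) else domain_index(domain_hits)
    gene_ann = annotation_index(annotations, "gene_caller")
    seed_route: dict[str, float] = {}
    for h in hits:
        if config.evalue_passes(h.evalue, config.lipase_evalue_cutoff):
            if h.query_id not in seed_route or h.evalue < seed_route[h.query_id]:
                seed_route[h.query_id] = h.evalue
    keyword_route: dict[str, str] = {}
    keywords = [k.lower() for k in rules.annotation_include_keywords]
    for pid, a in gene_ann.items():
        desc = a.descriptor.lower()
        for kw in keywords:
            if kw in desc:
                keyword_route[pid] = kw
                break
    out: list[EnzymeCall] = []
    for pid in sorted(set(seed_route) | set(keyword_route)):
        pdomains = domains.get(pid, ())
        if rules.rejects(pdomains):
            continue
        if not rules.accepts(pdomains):
            continue
        evidence: dict = {"domains": sorted(pdomains)}
        if pid in seed_route:
            evidence["seed_evalue"] = seed_route[pid]
        if pid in keyword_route:
            evidence["keyword"] = keyword_route[pid]
        out.append(EnzymeCall(protein_id=pid, enzyme_class=EnzymeClass.LIPASE, evidence=evidence))
    return out
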