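"""CxxCH heme-binding motif scanning and cytochrome classification.

c-type cytochromes attach heme covalently at CxxCH motifs (cysteine, any two
residues, cysteine, histidine). A protein with at least ``multiheme_min_sites``
motifs (default 4) is called multi-heme; such proteins in secreted
compartments often mediate extracellular electron transfer.

A motif-bearing protein is classified as a cytochrome when any of four rules
fires:

1. PROKKA_NAME        — the gene caller named it "cytochrome";
2. FUNCTIONAL_DESCRIPTOR — the annotation descriptor contains "cytochrome",
   "respiration" or another configured respiration-related keyword;
3. CYTOCHROME_DOMAIN  — it carries a cytochrome-type conserved domain;
4. HEAT_SHOCK_MULTIHEME — a multi-heme protein whose descriptor says
   "heat shock protein" (a recurrent mis-annotation of heme-rich proteins,
   collected deliberately).

Motif anchors must be literal C/H (the ambiguity letter X does not match);
the two wildcard positions accept any letter. Overlapping motifs are counted
individually. Positions are 1-based.
"""
from __future__ import annotations

from typing import Iterable

from .config import PipelineConfig
from .errors import UsageError
from .records import HemeProfile
from .rulesets import HemeRules, load_heme_rules

RULE_PROKKA_NAME = "PROKKA_NAME"
RULE_FUNCTIONAL_DESCRIPTOR = "FUNCTIONAL_DESCRIPTOR"
RULE_CYTOCHROME_DOMAIN = "CYTOCHROME_DOMAIN"
RULE_HEAT_SHOCK_MULTIHEME = "HEAT_SHOCK_MULTIHEME"


def scan_heme_motifs(sequence: str) -> list[int]:
    """1-based start positions of every CxxCH occurrence (overlaps counted)."""
    s = sequence
    return [
        i + 1
        for i in range(len(s) - 4)
        if s[i] == "C" and s[i + 3] == "C" and s[i + 4] == "H"
    ]


def classify_heme_protein(protein_id: str, motif_positions: Iterable[int],
                          gene_caller_name: str = "", descriptor: str = "",
                          domains: Iterable[str] = (),
                          config: PipelineConfig | None = None,
                          rules: HemeRules | None = None) -> HemeProfile:
    """Build a :class:`HemeProfile` for a motif-bearing protein."""
    config = config or PipelineConfig()
    rules = rules or load_heme_rules()
    positions = tuple(motif_positions)
    if not positions:
        raise UsageError(
            f"protein {protein_id!r} has no CxxCH motif; only motif-bearing "
            "proteins are profiled"
        )
    is_multiheme = len(positions) >= config.multiheme_min_sites
    name_l = gene_caller_name.lower()
    desc_l = descriptor.lower()
    fired = set()
    if "cytochrome" in name_l:
        fired.add(RULE_PROKKA_NAME)
    if any(kw.lower() in desc_l for kw in config.respiration_keywords):
        fired.add(RULE_FUNCTIONAL_DESCRIPTOR)
    from .rulesets import normalize_domain

    if any(normalize_domain(d) in rules.cytochrome_domains for d in domains):
        fired.add(RULE_CYTOCHROME_DOMAIN)
    if is_multiheme and rules.heat_shock_keyword in desc_l:
        fired.add(RULE_HEAT_SHOCK_MULTIHEME)
    return HemeProfile(
        protein_id=protein_id,
        motif_positions=positions,
        is_multiheme=is_multiheme,
        is_cytochrome=bool(fired),
        rule_fired=frozenset(fired),
    )
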