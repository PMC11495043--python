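"""Pipeline configuration.

All thresholds used by the classification stages live here, so a run is fully
described by one config object plus one seed. ``config_hash`` feeds the run manifest for reproducibility audits.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .errors import ConfigError


def _default_respiration_keywords() -> tuple:
    # The descriptor screen for cytochrome-like function is open-ended in
    # practice; this list is configurable and intentionally conservative.
    return (
        "cytochrome",
        "respiration",
        "respiratory",
        "denitrification",
        "nitrate reductase",
        "oxidase",
        "reductase",
    )


@dataclass(frozen=True)
class PipelineConfig:
    #: dbCAN-style calls need hits from at least this many detection methods.
    cazy_min_methods: int = 2
    #: peptidase-database hits must reach this e-value to count.
    merops_evalue_cutoff: float = 1e-20
    #: per-round cutoff of the iterative nuclease/RNase/nucleotidase expansion.
    nuclease_evalue_cutoff: float = 1e-10
    #: cutoff of the single-pass lipase seed search.
    lipase_evalue_cutoff: float = 1e-5
    #: minimum CxxCH sites for a protein to count as multi-heme.
    multiheme_min_sites: int = 4
    #: "especially high" = count > mean + this multiple of the sample SD.
    flag_sd_multiplier: float = 2.0
    #: MAGs above this mean relative abundance (%) are labelled abundant (strict >).
    abundance_cutoff: float = 0.1
    #: orthogroups reported after ranking by summed counts.
    top_og_n: int = 100
    #: hard cap on homology-expansion rounds.
    max_expansion_iterations: int = 10
    #: relative tolerance applied to e-value cutoffs, absorbing the limited
    #: precision with which upstream tools print e-values in text tables.
    evalue_rel_tol: float = 0.01
    #: strict: a nutrient peptidase's COG string must be exactly {E};
    #: relaxed (False): containing E suffices.
    peptidase_strict_cog: bool = True
    #: descriptor keywords (beyond "cytochrome") that fire the respiration rule.
    respiration_keywords: tuple = field(default_factory=_default_respiration_keywords)

    def __post_init__(self) -> None:
        for name in (
            "merops_evalue_cutoff",
            "nuclease_evalue_cutoff",
            "lipase_evalue_cutoff",
            "abundance_cutoff",
            "flag_sd_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cazy_min_methods not in (1, 2, 3):
            raise ConfigError("cazy_min_methods must be 1, 2 or 3")
        if self.multiheme_min_sites < 1 or self.top_og_n < 1:
            raise ConfigError("multiheme_min_sites and top_og_n must be >= 1")
        if self.max_expansion_iterations < 1:
            raise ConfigError("max_expansion_iterations must be >= 1")
        if self.evalue_rel_tol < 0:
            raise ConfigError("evalue_rel_tol must be >= 0")

    def evalue_passes(self, evalue: float, cutoff: float) -> bool:
        """``evalue <= cutoff`` with the configured relative tolerance."""
        return evalue <= cutoff * (1.0 + self.evalue_rel_tol)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["respiration_keywords"] = list(self.respiration_keywords)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_overrides(cls, **overrides) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - valid
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**overrides)
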