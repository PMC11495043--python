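"""Loaders for the packaged, versioned rule files.

The accept/reject domain lists and keyword lists driving enzyme and cytochrome
classification are data, not code: they ship as editable YAML under
``secretome_profiler/rules`` and are loaded here into typed objects. Domain
names are matched exactly after whitespace normalisation (a trailing
" superfamily" is part of the name as printed by domain-search tools).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .errors import ConfigError


def normalize_domain(name: str) -> str:
    """Collapse internal whitespace; matching is exact on the result."""
    return " ".join(name.split())


def _load_yaml(name: str) -> dict:
    ref = resources.files("secretome_profiler.rules").joinpath(f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ConfigError(f"no packaged rule file {name!r}") from exc
    return yaml.safe_load(text)


@dataclass(frozen=True)
class DomainRuleSet:
    class_label: str
    accept_domains: frozenset
    reject_domains: frozenset = frozenset()
    annotation_include_keywords: tuple = ()
    version: int = 1

    def __post_init__(self) -> None:
        if self.accept_domains & self.reject_domains:
            raise ConfigError(
                f"rule set {self.class_label}: accept and reject domain lists overlap"
            )

    def accepts(self, domains) -> bool:
        return any(normalize_domain(d) in self.accept_domains for d in domains)

    def rejects(self, domains) -> bool:
        return any(normalize_domain(d) in self.reject_domains for d in domains)


@lru_cache(maxsize=None)
def load_ruleset(name: str) -> DomainRuleSet:
    """Load one of the packaged rule sets: nuclease, rnase, nucleotidase, lipase."""
    data = _load_yaml(name)
    return DomainRuleSet(
        class_label=data["class_label"],
        accept_domains=frozenset(normalize_domain(d) for d in data["accept_domains"]),
        reject_domains=frozenset(normalize_domain(d) for d in data.get("reject_domains", [])),
        annotation_include_keywords=tuple(data.get("annotation_include_keywords", [])),
        version=int(data.get("version", 1)),
    )


@dataclass(frozen=True)
class HemeRules:
    cytochrome_domains: frozenset
    heat_shock_keyword: str
    version: int = 1


@lru_cache(maxsize=None)
def load_heme_rules() -> HemeRules:
    data = _load_yaml("heme")
    return HemeRules(
        cytochrome_domains=frozenset(normalize_domain(d) for d in data["cytochrome_domains"]),
        heat_shock_keyword=data["heat_shock_keyword"].lower(),
        version=int(data.get("version", 1)),
    )


@dataclass(frozen=True)
class CazyRules:
    excluded_prefixes: tuple
    excluded_class_labels: frozenset
    version: int = 1


@lru_cache(maxsize=None)
def load_cazy_rules() -> CazyRules:
    data = _load_yaml("cazy")
    return CazyRules(
        excluded_prefixes=tuple(data["excluded_prefixes"]),
        excluded_class_labels=frozenset(data["excluded_class_labels"]),
        version=int(data.get("version", 1)),
    )


@lru_cache(maxsize=None)
def location_vocabulary() -> dict:
    """Raw-label → canonical-location mapping (keys pre-normalised)."""
    data = _load_yaml("locations")
    return {str(k).strip().lower(): v for k, v in data["labels"].items()}
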