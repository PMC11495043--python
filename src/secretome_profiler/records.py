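"""Domain types shared across the pipeline.

Each record mirrors one row of an external tool-output dialect after
normalisation, or one internal result the pipeline attaches to a protein.
Records are plain frozen dataclasses; tabular aggregation happens in pandas
downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import IntegrityError

# 20 standard residues plus the ambiguity letters tools emit.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_RESIDUES = "XBZJUO"
ALLOWED_RESIDUES = frozenset(STANDARD_RESIDUES + AMBIGUITY_RESIDUES)


class Location(str, Enum):
    """Closed subcellular-location vocabulary after dialect normalisation."""

    EXTRACELLULAR = "EXTRACELLULAR"
    OUTER_MEMBRANE = "OUTER_MEMBRANE"
    CELL_WALL = "CELL_WALL"
    PERIPLASMIC = "PERIPLASMIC"
    CYTOPLASMIC_MEMBRANE = "CYTOPLASMIC_MEMBRANE"
    CYTOPLASMIC = "CYTOPLASMIC"
    UNKNOWN = "UNKNOWN"


#: Locations outside the cytoplasm and its membrane: the predicted secretome.
EXTRA_CYTOPLASMIC = frozenset(
    {
        Location.EXTRACELLULAR,
        Location.OUTER_MEMBRANE,
        Location.CELL_WALL,
        Location.PERIPLASMIC,
    }
)


class Envelope(str, Enum):
    DIDERM = "DIDERM"
    MONODERM = "MONODERM"
    ARCHAEAL = "ARCHAEAL"


class SpMethod(str, Enum):
    """The three signal-peptide detectors (SignalP-, PRED-TAT- and Phobius-like)."""

    PRIMARY = "primary_sp"
    TAT = "tat_sp_method"
    COMBINED = "combined_method"


class SpType(str, Enum):
    SEC = "SEC"
    TAT = "TAT"
    NONE = "NONE"


class EnzymeClass(str, Enum):
    CAZY_GH = "CAZY_GH"
    CAZY_CBM = "CAZY_CBM"
    CAZY_CE = "CAZY_CE"
    CAZY_PL = "CAZY_PL"
    PEPTIDASE_NUTRIENT = "PEPTIDASE_NUTRIENT"
    LIPASE = "LIPASE"
    NUCLEASE = "NUCLEASE"
    RNASE = "RNASE"
    NUCLEOTIDASE = "NUCLEOTIDASE"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its MAG membership."""

    protein_id: str
    mag_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise IntegrityError(f"protein {self.protein_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LocationCall:
    protein_id: str
    location: Location
    score: float
    raw_label: str = ""


@dataclass(frozen=True)
class SignalPeptideCall:
    protein_id: str
    method: SpMethod
    has_sp: bool
    sp_type: SpType

    def __post_init__(self) -> None:
        if (self.sp_type == SpType.NONE) == self.has_sp:
            raise IntegrityError(
                f"signal-peptide call for {self.protein_id!r}/{self.method.value}: "
                f"sp_type {self.sp_type.value} inconsistent with has_sp={self.has_sp}"
            )


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_name: str
    evalue: float


@dataclass(frozen=True)
class FunctionalAnnotation:
    protein_id: str
    source: str  # "gene_caller" | "og_mapper"
    descriptor: str
    cog_categories: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class CazyCall:
    protein_id: str
    family: str
    methods_detected: frozenset  # subset of {"HMM", "HOTPEP", "DIAMOND_METHOD"}
    class_label: str = ""


@dataclass(frozen=True)
class MeropsHit:
    protein_id: str
    merops_family: str
    evalue: float


@dataclass(frozen=True)
class SimilarityHit:
    """One row of the 12-column tabular hit format (outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class OrthogroupMembership:
    og_id: str
    protein_id: str


@dataclass(frozen=True)
class AbundanceRecord:
    mag_id: str
    mean_relative_abundance: float  # % of mapped reads averaged across plants


@dataclass(frozen=True)
class EnvelopeType:
    mag_id: str
    envelope: Envelope


@dataclass(frozen=True)
class CompartmentAssignment:
    """Integrated subcellular category for one protein.

    ``unk_sp`` marks proteins with an UNKNOWN location that nonetheless carry a
    signal peptide from the primary detector — treated as likely secreted.
    ``sp_support`` counts how many of the three detectors called a signal
    peptide (0–3).
    """

    protein_id: str
    mag_id: str
    category: Location
    unk_sp: bool
    sp_support: int
    raw_label: str = ""

    @property
    def is_extra_cytoplasmic(self) -> bool:
        return self.category in EXTRA_CYTOPLASMIC


@dataclass(frozen=True)
class EnzymeCall:
    protein_id: str
    enzyme_class: EnzymeClass
    evidence: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class HemeProfile:
    """CxxCH motif content and cytochrome classification for one protein."""

    protein_id: str
    motif_positions: tuple  # 1-based start positions
    is_multiheme: bool
    is_cytochrome: bool
    rule_fired: frozenset = frozenset()  # subset of the four classification rules

    @property
    def n_motifs(self) -> int:
        return len(self.motif_positions)
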