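"""Integration of location and signal-peptide evidence into compartments.

The compartment of a protein is taken verbatim from its (single) location
call; signal-peptide evidence adds two things on top:

* ``unk_sp`` — proteins with an UNKNOWN location whose *primary* detector
  calls a signal peptide are flagged as likely secreted ("UNK+SP"). Only the
  primary detector decides this flag; the tri-method screen exists for
  predicted extracellular proteins and is carried as ``sp_support``.
* ``sp_support`` — how many of the three detectors called a signal peptide.

Compartment validity depends on the cell-envelope architecture: the outer
membrane and periplasm exist only in diderms, a (profiled) cell wall location
only in monoderms. Archaeal envelopes are treated as monoderm for validity
because location predictors' archaeal profiles have no OM/PP classes.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .errors import IntegrityError
from .records import (
    CompartmentAssignment,
    Envelope,
    EnvelopeType,
    Location,
    LocationCall,
    SignalPeptideCall,
    SpMethod,
)

_DIDERM_ONLY = {Location.OUTER_MEMBRANE, Location.PERIPLASMIC}
_MONODERM_ONLY = {Location.CELL_WALL}


def _effective_envelope(envelope: Envelope) -> Envelope:
    return Envelope.MONODERM if envelope == Envelope.ARCHAEAL else envelope


def assign_compartment(call: LocationCall, sp_calls: Sequence[SignalPeptideCall],
                       envelope: EnvelopeType) -> CompartmentAssignment:
    """Integrate one protein's location call with its signal-peptide calls."""
    eff = _effective_envelope(envelope.envelope)
    if call.location in _DIDERM_ONLY and eff != Envelope.DIDERM:
        raise IntegrityError(
            f"protein {call.protein_id!r}: location {call.location.value} is "
            f"impossible in {envelope.envelope.value} MAG {envelope.mag_id!r}"
        )
    if call.location in _MONODERM_ONLY and eff != Envelope.MONODERM:
        raise IntegrityError(
            f"protein {call.protein_id!r}: location {call.location.value} is "
            f"impossible in {envelope.envelope.value} MAG {envelope.mag_id!r}"
        )
    sp_for_protein = [c for c in sp_calls if c.protein_id == call.protein_id]
    primary = next((c for c in sp_for_protein if c.method == SpMethod.PRIMARY), None)
    unk_sp = call.location == Location.UNKNOWN and primary is not None and primary.has_sp
    sp_support = sum(1 for c in sp_for_protein if c.has_sp)
    return CompartmentAssignment(
        protein_id=call.protein_id,
        mag_id=envelope.mag_id,
        category=call.location,
        unk_sp=unk_sp,
        sp_support=sp_support,
        raw_label=call.raw_label,
    )


#: keys of a per-MAG partition beyond the seven location categories
UNK_SP_KEY = "UNK_SP"
EXTRA_CYTOPLASMIC_KEY = "EXTRA_CYTOPLASMIC"


def partition_proteome(assignments: Iterable[CompartmentAssignment]) -> dict:
    """Per-MAG index: category → protein-id set, plus UNK+SP and the
    extra-cytoplasmic union.

    Every protein must be assigned exactly once; set sizes therefore sum to
    the proteome size per MAG (the UNK+SP set is a subset of UNKNOWN and the
    extra-cytoplasmic union a union of four disjoint categories, so neither is
    part of the sum).
    """
    seen: set[str] = set()
    index: dict[str, dict[str, set]] = defaultdict(
        lambda: {**{loc.value: set() for loc in Location},
                 UNK_SP_KEY: set(), EXTRA_CYTOPLASMIC_KEY: set()}
    )
    for a in assignments:
        if a.protein_id in seen:
            raise IntegrityError(f"protein {a.protein_id!r} assigned more than once")
        seen.add(a.protein_id)
        mag = index[a.mag_id]
        mag[a.category.value].add(a.protein_id)
        if a.unk_sp:
            mag[UNK_SP_KEY].add(a.protein_id)
        if a.is_extra_cytoplasmic:
            mag[EXTRA_CYTOPLASMIC_KEY].add(a.protein_id)
    return dict(index)


def assign_all(calls: Sequence[LocationCall], sp_calls: Sequence[SignalPeptideCall],
               envelopes: Mapping[str, EnvelopeType],
               protein_to_mag: Mapping[str, str]) -> list[CompartmentAssignment]:
    """Vector form of :func:`assign_compartment` over a cohort.

    ``protein_to_mag`` resolves each call to its MAG (and thus envelope);
    exactly one location call per protein is enforced.
    """
    sp_by_protein: dict[str, list[SignalPeptideCall]] = defaultdict(list)
    for c in sp_calls:
        sp_by_protein[c.protein_id].append(c)
    out = []
    seen: set[str] = set()
    for call in calls:
        if call.protein_id in seen:
            raise IntegrityError(f"protein {call.protein_id!r} has multiple location calls")
        seen.add(call.protein_id)
        mag_id = protein_to_mag.get(call.protein_id)
        if mag_id is None:
            raise IntegrityError(f"location call references unknown protein {call.protein_id!r}")
        envelope = envelopes.get(mag_id)
        if envelope is None:
            raise IntegrityError(f"no envelope type for MAG {mag_id!r}")
        out.append(assign_compartment(call, sp_by_protein.get(call.protein_id, ()), envelope))
    return out
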