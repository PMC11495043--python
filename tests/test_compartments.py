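"""Compartment integration: UNK+SP logic, envelope constraints, partitioning."""
from __future__ import annotations

import pytest

from secretome_profiler import (
    Envelope,
    EnvelopeType,
    IntegrityError,
    Location,
    LocationCall,
    SignalPeptideCall,
    SpMethod,
    SpType,
    assign_compartment,
    partition_proteome,
)
from secretome_profiler.compartments import EXTRA_CYTOPLASMIC_KEY, UNK_SP_KEY
from secretome_profiler.records import CompartmentAssignment

DIDERM = EnvelopeType("m1", Envelope.DIDERM)
MONODERM = EnvelopeType("m2", Envelope.MONODERM)
ARCHAEAL = EnvelopeType("m3", Envelope.ARCHAEAL)


def sp(method, has):
    return SignalPeptideCall("p1", method, has, SpType.SEC if has else SpType.NONE)


class TestAssignCompartment:
    def test_unknown_with_primary_sp_is_unk_sp(self):
        a = assign_compartment(
            LocationCall("p1", Location.UNKNOWN, 2.0), [sp(SpMethod.PRIMARY, True)], DIDERM
        )
        assert a.category == Location.UNKNOWN and a.unk_sp and a.sp_support == 1

    def test_secreted_without_sp_calls_keeps_category(self):
        # secreted proteins may legitimately lack signal peptides
        a = assign_compartment(LocationCall("p1", Location.EXTRACELLULAR, 9.9), [], DIDERM)
        assert a.category == Location.EXTRACELLULAR
        assert not a.unk_sp and a.sp_support == 0 and a.is_extra_cytoplasmic

    def test_non_primary_sp_does_not_set_unk_sp(self):
        a = assign_compartment(
            LocationCall("p1", Location.UNKNOWN, 2.0),
            [sp(SpMethod.TAT, True), sp(SpMethod.COMBINED, True)],
            DIDERM,
        )
        assert not a.unk_sp and a.sp_support == 2

    def test_unk_sp_requires_unknown_category(self):
        a = assign_compartment(
            LocationCall("p1", Location.EXTRACELLULAR, 9.9), [sp(SpMethod.PRIMARY, True)], DIDERM
        )
        assert not a.unk_sp and a.sp_support == 1

    @pytest.mark.parametrize(
        "location, envelope",
        [
            (Location.PERIPLASMIC, MONODERM),
            (Location.OUTER_MEMBRANE, MONODERM),
            (Location.CELL_WALL, DIDERM),
            (Location.PERIPLASMIC, ARCHAEAL),  # archaeal validity == monoderm
        ],
    )
    def test_envelope_incompatible_location_rejected(self, location, envelope):
        with pytest.raises(IntegrityError, match=envelope.mag_id):
            assign_compartment(LocationCall("p1", location, 9.0), [], envelope)

    def test_archaeal_cell_wall_allowed(self):
        a = assign_compartment(LocationCall("p1", Location.CELL_WALL, 9.0), [], ARCHAEAL)
        assert a.category == Location.CELL_WALL


def _assignment(pid, mag, category, unk_sp=False):
    return CompartmentAssignment(pid, mag, category, unk_sp, int(unk_sp))


class TestPartitionProteome:
    def test_counts_and_unions(self):
        parts = partition_proteome(
            [
                _assignment("a", "m1", Location.EXTRACELLULAR),
                _assignment("b", "m1", Location.EXTRACELLULAR),
                _assignment("c", "m1", Location.UNKNOWN, unk_sp=True),
                _assignment("d", "m1", Location.CYTOPLASMIC),
            ]
        )
        m = parts["m1"]
        assert len(m["EXTRACELLULAR"]) == 2
        assert m[UNK_SP_KEY] == {"c"} and m["UNKNOWN"] == {"c"}
        assert m[EXTRA_CYTOPLASMIC_KEY] == {"a", "b"}

    def test_empty_input(self):
        assert partition_proteome([]) == {}

    def test_duplicate_assignment_rejected(self):
        a = _assignment("a", "m1", Location.CYTOPLASMIC)
        with pytest.raises(IntegrityError, match="'a'"):
            partition_proteome([a, a])

    def test_conservation_against_catalog_recount(self, small_result):
        """Category set sizes per MAG sum to proteome size; the UNK+SP set is
        inside UNKNOWN; extra-cytoplasmic equals EC+OM+CW+PP (recounted
        independently from the catalog)."""
        catalog = small_result.catalog
        for mag_id, sub in catalog.groupby("mag_id"):
            by_cat = sub.groupby("category").size()
            assert int(by_cat.sum()) == len(sub)
            ec_union = sub["is_extra_cytoplasmic"].sum()
            assert ec_union == sum(
                int(by_cat.get(c, 0))
                for c in ("EXTRACELLULAR", "OUTER_MEMBRANE", "CELL_WALL", "PERIPLASMIC")
            )
            assert set(sub[sub["unk_sp"]]["protein_id"]) <= set(
                sub[sub["category"] == "UNKNOWN"]["protein_id"]
            )
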