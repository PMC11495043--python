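"""Readers and writers for every external file dialect the pipeline consumes.

All tabular inputs are tab-separated, one record per line, with ``#``-prefixed
comment lines ignored — the common denominator of the emulated tool outputs
(location predictor, signal-peptide detectors, conserved-domain search,
functional annotation, CAZyme overview, peptidase-database hits, 12-column
"outfmt 6" similarity hits, orthogroup membership, relative abundance).
Vocabulary normalisation (location labels, detector names, CAZyme method
names) happens at parse time so downstream code only ever sees the closed
vocabularies in :mod:`secretome_profiler.records`.

Writers emit canonical spellings, so a write→read round trip reproduces the
record list exactly, and normalisation is idempotent.
"""
from __future__ import annotations

import json
import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .config import PipelineConfig
from .errors import FormatError, IntegrityError, UsageError
from .records import (
    ALLOWED_RESIDUES,
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
from .rulesets import location_vocabulary

TABLE_KINDS = (
    "location",
    "signal_peptide",
    "domain",
    "annotation",
    "cazy",
    "merops",
    "similarity",
    "orthogroup",
    "abundance",
    "envelope",
)

_SP_METHOD_ALIASES = {
    "primary_sp": SpMethod.PRIMARY,
    "signalp": SpMethod.PRIMARY,
    "tat_sp_method": SpMethod.TAT,
    "pred-tat": SpMethod.TAT,
    "predtat": SpMethod.TAT,
    "combined_method": SpMethod.COMBINED,
    "phobius": SpMethod.COMBINED,
}

_CAZY_METHOD_ALIASES = {
    "hmm": "HMM",
    "hotpep": "HOTPEP",
    "diamond": "DIAMOND_METHOD",
    "diamond_method": "DIAMOND_METHOD",
}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, mapping: dict | None = None) -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    MAG membership is resolved from a ``MAGID|PROTEINID`` header convention,
    or from an explicit ``protein_id -> mag_id`` *mapping* which takes
    precedence. Sequences are upper-cased and a trailing ``*`` stop character
    is stripped.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(os.fspath(path), "fasta"):
        token = entry.id
        if mapping is not None and token in mapping:
            protein_id, mag_id = token, mapping[token]
        elif "|" in token:
            mag_id, protein_id = token.split("|", 1)
        elif mapping is not None:
            raise FormatError(f"{path}: no MAG mapping for protein {token!r}")
        else:
            raise FormatError(
                f"{path}: header {token!r} lacks the MAGID|PROTEINID convention "
                "and no mapping file was given"
            )
        seq = str(entry.seq).upper().rstrip("*")
        bad = set(seq) - ALLOWED_RESIDUES
        if bad:
            raise FormatError(
                f"{path}: record {protein_id!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        if protein_id in seen:
            raise IntegrityError(f"{path}: duplicate protein id {protein_id!r}")
        seen.add(protein_id)
        records.append(ProteinRecord(protein_id=protein_id, mag_id=mag_id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: empty or non-FASTA file")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.mag_id}|{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def read_mag_mapping(path) -> dict:
    """Two-column ``protein_id<TAB>mag_id`` mapping file."""
    mapping: dict[str, str] = {}
    for lineno, fields in _iter_rows(path, 2):
        mapping[fields[0]] = fields[1]
    return mapping


# ---------------------------------------------------------------------------
# generic TSV plumbing

def _iter_rows(path, ncols: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncols} tab-separated columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def _parse_float(value: str, path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: unparseable {what} {value!r}") from exc


def _parse_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: unparseable {what} {value!r}") from exc


def normalize_location_label(raw: str) -> Location:
    """Map a predictor's raw location label onto the closed vocabulary."""
    key = " ".join(raw.strip().lower().replace("_", " ").split())
    vocab = location_vocabulary()
    if key not in vocab:
        raise FormatError(f"unknown location label {raw!r}")
    return Location(vocab[key])


def _parse_bool(value: str, path, lineno: int) -> bool:
    v = value.strip().lower()
    if v in ("y", "yes", "true", "1"):
        return True
    if v in ("n", "no", "false", "0"):
        return False
    raise FormatError(f"{path}:{lineno}: unparseable boolean {value!r}")


# ---------------------------------------------------------------------------
# per-kind parsers

def _read_location(path):
    out = []
    for lineno, f in _iter_rows(path, 3):
        out.append(
            LocationCall(
                protein_id=f[0],
                location=normalize_location_label(f[1]),
                score=_parse_float(f[2], path, lineno, "score"),
                raw_label=f[1],
            )
        )
    return out


def _read_signal_peptide(path):
    out = []
    seen = set()
    for lineno, f in _iter_rows(path, 4):
        method_key = f[1].strip().lower()
        if method_key not in _SP_METHOD_ALIASES:
            raise FormatError(f"{path}:{lineno}: unknown signal-peptide method {f[1]!r}")
        method = _SP_METHOD_ALIASES[method_key]
        key = (f[0], method)
        if key in seen:
            raise IntegrityError(
                f"{path}:{lineno}: duplicate signal-peptide call for {f[0]!r}/{method.value}"
            )
        seen.add(key)
        has_sp = _parse_bool(f[2], path, lineno)
        sp_type = SpType(f[3].strip().upper())
        out.append(SignalPeptideCall(protein_id=f[0], method=method, has_sp=has_sp, sp_type=sp_type))
    return out


def _read_domain(path):
    out = []
    for lineno, f in _iter_rows(path, 3):
        ev = _parse_float(f[2], path, lineno, "e-value")
        if ev <= 0:
            raise FormatError(f"{path}:{lineno}: e-value must be positive")
        out.append(DomainHit(protein_id=f[0], domain_name=f[1], evalue=ev))
    return out


def _read_annotation(path):
    out = []
    for lineno, f in _iter_rows(path, 4):
        if f[1] not in ("gene_caller", "og_mapper"):
            raise FormatError(f"{path}:{lineno}: unknown annotation source {f[1]!r}")
        cogs = frozenset() if f[2] in ("-", "") else frozenset(f[2])
        if not all("A" <= c <= "Z" for c in cogs):
            raise FormatError(f"{path}:{lineno}: COG categories must be single letters A-Z")
        out.append(
            FunctionalAnnotation(protein_id=f[0], source=f[1], descriptor=f[3], cog_categories=cogs)
        )
    return out


def _read_cazy(path):
    out = []
    for lineno, f in _iter_rows(path, 4):
        methods = set()
        for tok in f[2].replace(",", "+").split("+"):
            tok = tok.strip().lower()
            if not tok:
                continue
            if tok not in _CAZY_METHOD_ALIASES:
                raise FormatError(f"{path}:{lineno}: unknown CAZyme detection method {tok!r}")
            methods.add(_CAZY_METHOD_ALIASES[tok])
        if not methods:
            raise FormatError(f"{path}:{lineno}: empty detection-method field")
        out.append(
            CazyCall(protein_id=f[0], family=f[1], methods_detected=frozenset(methods), class_label=f[3])
        )
    return out


def _read_merops(path):
    out = []
    for lineno, f in _iter_rows(path, 3):
        ev = _parse_float(f[2], path, lineno, "e-value")
        if ev <= 0:
            raise FormatError(f"{path}:{lineno}: e-value must be positive")
        out.append(MeropsHit(protein_id=f[0], merops_family=f[1], evalue=ev))
    return out


def _read_similarity(path):
    out = []
    for lineno, f in _iter_rows(path, 12):
        out.append(
            SimilarityHit(
                query_id=f[0],
                subject_id=f[1],
                percent_identity=_parse_float(f[2], path, lineno, "percent identity"),
                alignment_length=_parse_int(f[3], path, lineno, "alignment length"),
                mismatches=_parse_int(f[4], path, lineno, "mismatch count"),
                gap_opens=_parse_int(f[5], path, lineno, "gap-open count"),
                qstart=_parse_int(f[6], path, lineno, "qstart"),
                qend=_parse_int(f[7], path, lineno, "qend"),
                sstart=_parse_int(f[8], path, lineno, "sstart"),
                send=_parse_int(f[9], path, lineno, "send"),
                evalue=_parse_float(f[10], path, lineno, "e-value"),
                bitscore=_parse_float(f[11], path, lineno, "bitscore"),
            )
        )
    return out


def _read_orthogroup(path):
    return [OrthogroupMembership(og_id=f[0], protein_id=f[1]) for _, f in _iter_rows(path, 2)]


def _read_abundance(path):
    out = []
    for lineno, f in _iter_rows(path, 2):
        v = _parse_float(f[1], path, lineno, "relative abundance")
        if v < 0:
            raise FormatError(f"{path}:{lineno}: relative abundance must be >= 0")
        out.append(AbundanceRecord(mag_id=f[0], mean_relative_abundance=v))
    return out


def _read_envelope(path):
    out = []
    for lineno, f in _iter_rows(path, 2):
        try:
            env = Envelope(f[1].strip().upper())
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unknown envelope type {f[1]!r}") from exc
        out.append(EnvelopeType(mag_id=f[0], envelope=env))
    return out


_READERS = {
    "location": _read_location,
    "signal_peptide": _read_signal_peptide,
    "domain": _read_domain,
    "annotation": _read_annotation,
    "cazy": _read_cazy,
    "merops": _read_merops,
    "similarity": _read_similarity,
    "orthogroup": _read_orthogroup,
    "abundance": _read_abundance,
    "envelope": _read_envelope,
}


def read_table(kind: str, path) -> list:
    """Read one tool-output table into typed records.

    ``kind`` selects the dialect (one of :data:`TABLE_KINDS`). Rows referencing
    protein ids unknown to the caller are *not* rejected here; join checks
    happen in the pipeline (see :func:`unknown_ids`).
    """
    if kind not in _READERS:
        raise UsageError(f"unknown table kind {kind!r}; expected one of {TABLE_KINDS}")
    return _READERS[kind](path)


def unknown_ids(records: Sequence, known_protein_ids: set) -> list:
    """Protein ids referenced by *records* that are absent from the proteome."""
    out = []
    for rec in records:
        pid = getattr(rec, "protein_id", None) or getattr(rec, "query_id", None)
        if pid is not None and pid not in known_protein_ids:
            out.append(pid)
    return sorted(set(out))


# ---------------------------------------------------------------------------
# per-kind writers (canonical spellings; round-trips exactly)

def _fmt(x) -> str:
    return repr(x) if isinstance(x, float) else str(x)


def _rows_location(r):
    return (r.protein_id, r.raw_label or r.location.value, _fmt(r.score))


def _rows_signal_peptide(r):
    return (r.protein_id, r.method.value, "Y" if r.has_sp else "N", r.sp_type.value)


def _rows_domain(r):
    return (r.protein_id, r.domain_name, _fmt(r.evalue))


def _rows_annotation(r):
    cogs = "".join(sorted(r.cog_categories)) or "-"
    return (r.protein_id, r.source, cogs, r.descriptor)


def _rows_cazy(r):
    return (r.protein_id, r.family, "+".join(sorted(r.methods_detected)), r.class_label)


def _rows_merops(r):
    return (r.protein_id, r.merops_family, _fmt(r.evalue))


def _rows_similarity(r):
    return (
        r.query_id, r.subject_id, _fmt(r.percent_identity), str(r.alignment_length),
        str(r.mismatches), str(r.gap_opens), str(r.qstart), str(r.qend),
        str(r.sstart), str(r.send), _fmt(r.evalue), _fmt(r.bitscore),
    )


def _rows_orthogroup(r):
    return (r.og_id, r.protein_id)


def _rows_abundance(r):
    return (r.mag_id, _fmt(r.mean_relative_abundance))


def _rows_envelope(r):
    return (r.mag_id, r.envelope.value)


_WRITERS = {
    "location": _rows_location,
    "signal_peptide": _rows_signal_peptide,
    "domain": _rows_domain,
    "annotation": _rows_annotation,
    "cazy": _rows_cazy,
    "merops": _rows_merops,
    "similarity": _rows_similarity,
    "orthogroup": _rows_orthogroup,
    "abundance": _rows_abundance,
    "envelope": _rows_envelope,
}


def write_table(kind: str, records: Iterable, path) -> None:
    if kind not in _WRITERS:
        raise UsageError(f"unknown table kind {kind!r}; expected one of {TABLE_KINDS}")
    rows = _WRITERS[kind]
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(rows(rec)) + "\n")


# ---------------------------------------------------------------------------
# pipeline outputs

_OUTPUT_PREAMBLE = "# coordinates: 1-based inclusive (motif positions, alignment spans)\n"


def write_outputs(catalog: pd.DataFrame, profiles: pd.DataFrame, outdir,
                  config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Write the per-protein catalog, per-MAG profiles and a run manifest.

    Files are deterministic: rows sorted by (mag_id, protein_id) / mag_id and
    identical inputs produce byte-identical output. Returns the paths written.
    """
    os.makedirs(outdir, exist_ok=True)
    if len(catalog) and not set(catalog["mag_id"]) <= set(profiles["mag_id"]):
        missing = sorted(set(catalog["mag_id"]) - set(profiles["mag_id"]))
        raise IntegrityError(f"catalog references MAGs absent from profiles: {missing}")
    catalog = catalog.sort_values(["mag_id", "protein_id"], kind="mergesort")
    profiles = profiles.sort_values("mag_id", kind="mergesort")
    paths = {
        "catalog": os.path.join(outdir, "catalog.tsv"),
        "profiles": os.path.join(outdir, "profiles.tsv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    for key, frame in (("catalog", catalog), ("profiles", profiles)):
        with open(paths[key], "w") as fh:
            fh.write(_OUTPUT_PREAMBLE)
            frame.to_csv(fh, sep="\t", index=False)
    manifest = {
        "config": (config or PipelineConfig()).to_dict(),
        "config_hash": (config or PipelineConfig()).config_hash(),
        "seed": seed,
        "n_proteins": int(len(catalog)),
        "n_mags": int(len(profiles)),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
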