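"""Readers and writers: FASTA proteomes, annotation tables, MTF reports.

All coordinates written to reports are 1-based inclusive, stated in the
report header. Reports are TSV (family labels may contain commas).
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .model import (
    AnnotationRow,
    AnnotationTable,
    DomainInterval,
    FormatError,
    MtfRecord,
    MtfscanError,
    ProteinRecord,
    TmSpan,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "read_domain_intervals",
    "write_mtf_report",
    "MTF_REPORT_COLUMNS",
]

MTF_REPORT_COLUMNS = (
    "id",
    "locus",
    "species",
    "family",
    "tm_count",
    "spans",
    "location_pattern",
    "provenance",
)


def read_fasta(
    path: str | os.PathLike,
    annotations: AnnotationTable | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA into ProteinRecords.

    Sequences are case-normalized to upper case.  When *annotations* is
    given, locus/species/family are joined on the FASTA id; ids missing
    from the table fall back to "NA" defaults.  Raises FormatError for a
    file that does not start with a header line, SequenceError for
    disallowed residue letters (everything outside the 20 standard amino
    acids plus X).
    """
    with open(path) as fh:
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if first and not first.startswith(">"):
            raise FormatError(
                f"{path}: not FASTA — first non-blank line is not a '>' header"
            )
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        if sr.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {sr.id!r}")
        seen.add(sr.id)
        ann = annotations.get(sr.id) if annotations is not None else None
        if ann is not None:
            rec = ProteinRecord(
                id=sr.id,
                seq=str(sr.seq),
                locus=ann.locus,
                species=ann.species,
                family=ann.family,
            )
        else:
            rec = ProteinRecord(id=sr.id, seq=str(sr.seq))
        records.append(rec)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write ProteinRecords as plain FASTA (60-column wrapping)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


def read_annotation_table(path: str | os.PathLike) -> AnnotationTable:
    """Read a 4-column TSV: id, locus, species, family.

    Lines starting with '#' are headers/comments and are skipped.
    Duplicate ids and wrong column counts raise FormatError with the
    offending line number.
    """
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            pid, locus, species, family = parts
            try:
                table.add(pid, AnnotationRow(locus=locus, species=species, family=family))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return table


def read_domain_intervals(path: str | os.PathLike) -> dict[str, DomainInterval]:
    """Read a domain-interval TSV: protein_id, start, end (1-based inclusive)."""
    out: dict[str, DomainInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            pid, start, end = parts
            if pid in out:
                raise FormatError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            try:
                out[pid] = DomainInterval(pid, int(start), int(end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    return out


def read_mtf_report(
    path: str | os.PathLike,
    proteins: dict[str, ProteinRecord] | None = None,
) -> list[MtfRecord]:
    """Read back a TSV report written by :func:`write_mtf_report`.

    When *proteins* is given, records are joined on id (the report's own
    annotation columns win for locus/species/family); otherwise minimal
    placeholder sequences of the right order are not reconstructable, so
    *proteins* is required.
    """
    if proteins is None:
        raise MtfscanError("read_mtf_report requires the proteins mapping for sequences")
    out: list[MtfRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != len(MTF_REPORT_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            pid, locus, species, family, tm_count, spans_s, pattern, prov = parts
            if pid not in proteins:
                raise FormatError(f"{path}:{lineno}: unknown protein id {pid!r}")
            base = proteins[pid]
            rec = ProteinRecord(
                id=pid, seq=base.seq, locus=locus, species=species, family=family
            )
            spans = tuple(
                TmSpan(int(s.split("-")[0]), int(s.split("-")[1]))
                for s in spans_s.split(";")
                if s
            )
            if len(spans) != int(tm_count):
                raise FormatError(f"{path}:{lineno}: tm_count does not match spans")
            out.append(
                MtfRecord(
                    protein=rec,
                    spans=spans,
                    location_pattern=pattern,
                    provenance=frozenset(prov.split(",")),
                )
            )
    return out


def write_mtf_report(mtfs: list[MtfRecord], path: str | os.PathLike) -> None:
    """Write the final MTF table as TSV, one row per MTF.

    Columns: id, locus, species, family, tm_count, spans ("start-end"
    semicolon-joined, 1-based inclusive), location_pattern, provenance.
    Rows are ordered by (species, id) so reruns are byte-identical.
    """
    rows = sorted(mtfs, key=lambda m: (m.protein.species, m.protein.id))
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive\n")
        fh.write("\t".join(MTF_REPORT_COLUMNS) + "\n")
        for m in rows:
            spans = ";".join(f"{s.start}-{s.end}" for s in m.spans)
            prov = ",".join(sorted(m.provenance))
            fh.write(
                "\t".join(
                    (
                        m.protein.id,
                        m.protein.locus,
                        m.protein.species,
                        m.protein.family,
                        str(m.tm_count),
                        spans,
                        m.location_pattern,
                        prov,
                    )
                )
                + "\n"
            )
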