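"""Readers and writers for the annotation and alignment formats the pipeline touches.

Formats:

* GFF3 (1-based inclusive; converted to the internal 0-based half-open
  convention at this boundary) — parsed with :mod:`gffutils`.
* BED 3/6-column (already 0-based half-open).
* FASTA — Biopython.
* PSL 21-column (BLAT output), with or without the 5-line header.
* RepeatMasker ``.out`` tables (3 header lines, whitespace-separated).
* 12-column tabular homology hits (query, subject, %id, length, mismatches,
  gaps, qstart, qend, sstart, send, evalue, bitscore).

PSL and RepeatMasker ``.out`` have no parser among the installed format
libraries, so the column handling lives here.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Union

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .model import AlignmentHit, Assembly, GeneAnnotation, TEAnnotation
from .taxonomy import classify_label

PathLike = Union[str, Path]

_GENE_TYPES = {"gene", "mRNA", "protein_coding_gene"}


class FormatError(ValueError):
    """A structurally invalid input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: PathLike) -> list:
    """Parse a GFF3 file into GeneAnnotation / TEAnnotation records.

    Feature types in ``{gene, mRNA}`` become genes; every other feature is
    treated as a repeat and classified into the TE taxonomy from its type and
    its ``superfamily`` / ``classification`` attributes (first match wins),
    falling back to unclassified.
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            try:
                feature = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            start1, end1 = int(feature.start), int(feature.end)
            if end1 < start1:
                raise FormatError(
                    f"{path}: line {lineno}: end {end1} < start {start1}"
                )
            interval = GenomicInterval(
                feature.seqid,
                start1 - 1,
                end1,
                feature.strand if feature.strand in ("+", "-") else ".",
            )
            if feature.featuretype in _GENE_TYPES:
                gene_id = (
                    feature.attributes.get("ID", [None])[0]
                    or feature.attributes.get("Name", [f"gene_{lineno}"])[0]
                )
                records.append(GeneAnnotation(interval=interval, gene_id=gene_id))
            else:
                labels = [feature.featuretype]
                for key in ("superfamily", "classification", "Name"):
                    labels.extend(feature.attributes.get(key, []))
                superfamily = "unclassified"
                for label in labels:
                    candidate = classify_label(label)[0]
                    if candidate != "unclassified":
                        superfamily = candidate
                        break
                family = feature.attributes.get("family_id", [None])[0]
                records.append(
                    TEAnnotation(
                        interval=interval,
                        superfamily=superfamily,
                        family_id=family,
                        source=feature.source,
                    )
                )
    return records


def write_gff3(records: Iterable, path: PathLike) -> None:
    """Write gene/TE records as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for record in records:
            iv = record.interval
            if isinstance(record, GeneAnnotation):
                ftype, source = "gene", "telandscape"
                attrs = f"ID={record.gene_id}"
            else:
                ftype = "dispersed_repeat"
                source = record.source or "telandscape"
                attrs = f"superfamily={record.superfamily}"
                if record.family_id:
                    attrs += f";family_id={record.family_id}"
            handle.write(
                f"{iv.scaffold_id}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand if iv.strand != '.' else '.'}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read 3- or 6-column BED into plain intervals (0-based half-open already)."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_assembly_fasta(path: PathLike) -> Assembly:
    assembly = Assembly()
    for name, seq in read_fasta(path).items():
        assembly.add(name, sequence=seq)
    return assembly


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

_PSL_COLUMNS = 21


def read_psl(path: PathLike) -> list[AlignmentHit]:
    """Parse BLAT PSL (21 columns; the optional 5-line header is skipped).

    ``matched_bases`` is the ``matches`` column; the gap count pools query
    and target gap bases.
    """
    hits = []
    with open(path) as handle:
        lines = handle.read().splitlines()
    start_idx = 0
    if lines and lines[0].startswith("psLayout"):
        start_idx = 5  # fixed-size header block
    for lineno, line in enumerate(lines[start_idx:], start=start_idx + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) != _PSL_COLUMNS:
            raise FormatError(
                f"{path}: line {lineno}: expected {_PSL_COLUMNS} PSL columns, "
                f"got {len(fields)}"
            )
        try:
            matches = int(fields[0])
            mismatches = int(fields[1])
            q_gap_bases = int(fields[5])
            t_gap_bases = int(fields[7])
            strand = fields[8]
            q_name, q_size = fields[9], int(fields[10])
            t_name, t_size = fields[13], int(fields[14])
            t_start, t_end = int(fields[15]), int(fields[16])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        if min(matches, mismatches, q_gap_bases, t_gap_bases, q_size, t_size) < 0:
            raise FormatError(f"{path}: line {lineno}: negative field")
        target_interval = None
        if t_end > t_start:
            target_interval = GenomicInterval(
                t_name, t_start, t_end, strand[-1] if strand[-1] in "+-" else "."
            )
        hits.append(
            AlignmentHit(
                query_id=q_name,
                target_id=t_name,
                matched_bases=matches,
                query_length=q_size,
                target_length=t_size,
                gap_count=q_gap_bases + t_gap_bases,
                mismatch_count=mismatches,
                target_interval=target_interval,
            )
        )
    return hits


def write_psl(hits: Iterable[AlignmentHit], path: PathLike) -> None:
    """Write hits as headerless PSL rows (fields the pipeline does not track are 0)."""
    with open(path, "w") as handle:
        for hit in hits:
            iv = hit.target_interval
            t_start = iv.start if iv else 0
            t_end = iv.end if iv else 0
            strand = iv.strand if iv and iv.strand in "+-" else "+"
            row = [
                hit.matched_bases, hit.mismatch_count, 0, 0,
                0, hit.gap_count, 0, 0,
                strand,
                hit.query_id, hit.query_length, 0, hit.query_length,
                hit.target_id, hit.target_length, t_start, t_end,
                1, f"{hit.matched_bases},", "0,", f"{t_start},",
            ]
            handle.write("\t".join(str(f) for f in row) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: PathLike) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` annotation table into TEAnnotations.

    Layout: up to 3 header lines, then whitespace-separated rows with the
    query sequence in column 5, 1-based begin/end in columns 6-7, strand in
    column 9 (``+`` or ``C``), repeat name in column 10 and class/family in
    column 11. The class/family label is mapped through the taxonomy table;
    unknown labels become unclassified.
    """
    annotations = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split()[0]
            if first in ("SW", "score") or stripped.startswith("There were no"):
                continue
            fields = stripped.split()
            if len(fields) < 11:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 11 RepeatMasker columns, "
                    f"got {len(fields)}"
                )
            try:
                scaffold = fields[4]
                begin1, end1 = int(fields[5]), int(fields[6])
                strand = "+" if fields[8] == "+" else "-"
                repeat_name = fields[9]
                class_family = fields[10]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if end1 < begin1:
                raise FormatError(f"{path}: line {lineno}: end < begin")
            superfamily = classify_label(class_family)[0]
            annotations.append(
                TEAnnotation(
                    interval=GenomicInterval(scaffold, begin1 - 1, end1, strand),
                    superfamily=superfamily,
                    family_id=repeat_name,
                    source="RepeatMasker",
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# 12-column tabular homology hits
# ---------------------------------------------------------------------------

def read_tabular_hits(path: PathLike) -> list[AlignmentHit]:
    """Read blast-style 12-column tabular hits.

    ``matched_bases`` is reconstructed as alignment length − mismatches −
    gap opens (the closest the format allows); query/target lengths are not
    in the format and are set to the aligned span on each side.
    """
    hits = []
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(row)}"
                )
            (query, subject, _pid, length, mism, gaps,
             qstart, qend, sstart, send, evalue, _bits) = row
            length, mism, gaps = int(length), int(mism), int(gaps)
            qspan = abs(int(qend) - int(qstart)) + 1
            sspan = abs(int(send) - int(sstart)) + 1
            hits.append(
                AlignmentHit(
                    query_id=query,
                    target_id=subject,
                    matched_bases=max(0, length - mism - gaps),
                    query_length=qspan,
                    target_length=sspan,
                    gap_count=gaps,
                    mismatch_count=mism,
                    e_value=float(evalue),
                )
            )
    return hits
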