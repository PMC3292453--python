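"""Readers and writers for the pipeline's on-disk formats.

Conventions: internal coordinates are 0-based half-open everywhere; BED6
stays 0-based half-open, while the RepeatMasker-style ``.out`` table and
GFF3 are 1-based inclusive.
"""

from __future__ import annotations

import csv
from importlib import resources

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .annotate import CopyAnnotation
from .errors import InputError

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_library_fasta",
    "read_library_fasta",
    "write_rm_out",
    "read_rm_out",
    "write_gff3",
    "write_bed",
    "write_truth_tsv",
    "write_alignments",
    "read_alignments",
    "read_table_fixture",
]


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0]
            if name in out:
                raise InputError(f"{path}: duplicate sequence name {name!r}")
            out[name] = seq.upper()
    if not out:
        raise InputError(f"{path}: no FASTA records")
    return out


def write_fasta(path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_library_fasta(path, families, width: int = 60) -> None:
    """Library FASTA with ``>ID class=... source=...`` headers."""
    with open(path, "w") as fh:
        for fam in families:
            fh.write(f">{fam.family_id} class={fam.te_class} source={fam.source}\n")
            for i in range(0, len(fam.consensus), width):
                fh.write(fam.consensus[i : i + width] + "\n")


def read_library_fasta(path):
    """Read a family library; plain headers default to class=unknown.

    Known-library naming (RUxxxx) implies source=known unless stated.
    """
    from .discovery import TEFamily

    out = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            fields = header.split()
            fid = fields[0]
            attrs = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            source = attrs.get("source", "known" if fid.startswith("RU") else "de_novo")
            out.append(
                TEFamily(
                    family_id=fid,
                    consensus=seq.upper(),
                    te_class=attrs.get("class", "unknown"),
                    source=source,
                )
            )
    if not out:
        raise InputError(f"{path}: no library records")
    return out


_RM_COLS = [
    "score",
    "div_pct",
    "contig",
    "begin",
    "end",
    "strand",
    "family",
    "te_class",
    "cons_begin",
    "cons_end",
    "copy_id",
]


def write_rm_out(path, hits, class_of=None) -> None:
    """RepeatMasker-.out-style table; 1-based inclusive coordinates."""
    class_of = class_of or {}
    with open(path, "w") as fh:
        fh.write("\t".join(_RM_COLS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.score,
                        f"{100 * (1 - h.identity):.2f}",
                        h.contig,
                        h.start + 1,
                        h.end,
                        h.strand,
                        h.family_id,
                        class_of.get(h.family_id, "unknown"),
                        h.cstart + 1,
                        h.cend,
                        h.copy_id,
                    )
                )
                + "\n"
            )


def read_rm_out(path, genome_id="g"):
    hits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _RM_COLS:
            raise InputError(f"{path}: unexpected header {reader.fieldnames}")
        for ln, row in enumerate(reader, start=2):
            try:
                hits.append(
                    CopyAnnotation(
                        copy_id=row["copy_id"],
                        genome_id=genome_id,
                        contig=row["contig"],
                        start=int(row["begin"]) - 1,
                        end=int(row["end"]),
                        strand=row["strand"],
                        family_id=row["family"],
                        score=int(row["score"]),
                        identity=1.0 - float(row["div_pct"]) / 100.0,
                        cstart=int(row["cons_begin"]) - 1,
                        cend=int(row["cons_end"]),
                        cigar="",
                    )
                )
            except (KeyError, ValueError) as exc:
                raise InputError(f"{path}:{ln}: malformed record ({exc})") from exc
    return hits


def write_gff3(path, hits, class_of=None, source="tedyn") -> None:
    """GFF3 (1-based inclusive) with family and class in the attributes."""
    class_of = class_of or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            attrs = (
                f"ID={h.copy_id};family={h.family_id};"
                f"class={class_of.get(h.family_id, 'unknown')};"
                f"identity={h.identity:.4f}"
            )
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.contig,
                        source,
                        "dispersed_repeat",
                        h.start + 1,
                        h.end,
                        h.score,
                        h.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )


def write_bed(path, intervals) -> None:
    """BED6 (0-based half-open). Accepts CopyAnnotation or TruthRecord items."""
    with open(path, "w") as fh:
        for it in intervals:
            name = getattr(it, "copy_id", None) or getattr(it, "family_id", ".")
            score = getattr(it, "score", 0)
            fh.write(
                f"{it.contig}\t{it.start}\t{it.end}\t{name}\t{score}\t{it.strand}\n"
            )


def write_truth_tsv(path, truth) -> None:
    cols = [
        "copy_id",
        "lineage",
        "contig",
        "start",
        "end",
        "strand",
        "family_id",
        "true_insertion_time",
        "parent_copy_id",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        t.copy_id,
                        t.lineage,
                        t.contig,
                        t.start,
                        t.end,
                        t.strand,
                        t.family_id,
                        f"{t.true_insertion_time:.6f}",
                        t.parent_copy_id,
                    )
                )
                + "\n"
            )


_ALN_COLS = [
    "copy_id",
    "genome_id",
    "contig",
    "start",
    "end",
    "strand",
    "family_id",
    "score",
    "identity",
    "cons_start",
    "cons_end",
    "cigar",
    "copy_seq",
]


def write_alignments(path, hits) -> None:
    """Per-copy alignment table: everything dating needs to rebuild stacks.

    Coordinates 0-based half-open; the cigar aligns the copy (consensus
    orientation) against the family consensus.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.copy_id,
                        h.genome_id,
                        h.contig,
                        h.start,
                        h.end,
                        h.strand,
                        h.family_id,
                        h.score,
                        repr(h.identity),  # shortest exact float round-trip
                        h.cstart,
                        h.cend,
                        h.cigar,
                        h.copy_seq,
                    )
                )
                + "\n"
            )


def read_alignments(path):
    hits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _ALN_COLS:
            raise InputError(f"{path}: unexpected header {reader.fieldnames}")
        for ln, row in enumerate(reader, start=2):
            try:
                hits.append(
                    CopyAnnotation(
                        copy_id=row["copy_id"],
                        genome_id=row["genome_id"],
                        contig=row["contig"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=row["strand"],
                        family_id=row["family_id"],
                        score=int(row["score"]),
                        identity=float(row["identity"]),
                        cstart=int(row["cons_start"]),
                        cend=int(row["cons_end"]),
                        cigar=row["cigar"],
                        copy_seq=row["copy_seq"],
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise InputError(f"{path}:{ln}: malformed record ({exc})") from exc
    return hits


def read_table_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table (data/*.tsv) as a DataFrame.

    Available fixtures: ``arabidopsis_te_census`` (published per-class TE
    copy census for A. thaliana vs A. lyrata) and
    ``arabidopsis_family_partition`` (shared/unique/absent family counts).
    """
    ref = resources.files("tedyn.data") / f"{name}.tsv"
    if not ref.is_file():
        raise InputError(f"no packaged fixture named {name!r}")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
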