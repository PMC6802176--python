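"""File-format plumbing: FASTA/FASTQ via Biopython, annotation intervals from
GFF3/BED, tabular alignment reports, and PHYLIP distance matrices."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import AlignmentHit, NucleotideSequence, ProteinSequence


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[NucleotideSequence]:
    with _open_text(path) as fh:
        return [
            NucleotideSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")
        ]


def read_protein_fasta(path) -> list[ProteinSequence]:
    """Protein FASTA; an ``id|label`` header keeps the full string as id (the
    consumer splits the label off)."""
    with _open_text(path) as fh:
        return [ProteinSequence(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, seqs: Iterable[NucleotideSequence | ProteinSequence]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path) -> list[tuple[str, str]]:
    """(read id, sequence) pairs; qualities are not used downstream."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# annotation intervals (GFF3 / BED)
# ---------------------------------------------------------------------------


def read_intervals(path, feature_types: set[str] | None = None) -> dict[str, list[tuple[int, int]]]:
    """Read per-sequence intervals from GFF3 or BED (sniffed by extension).

    Returns 1-based inclusive intervals keyed by sequence id.  For GFF3,
    ``feature_types`` restricts to those ``type`` column values (e.g.
    {"tRNA"}); BED rows are taken as-is (BED is 0-based half-open on disk).
    """
    path = Path(path)
    out: dict[str, list[tuple[int, int]]] = {}
    is_bed = path.suffix.lower() in (".bed",)
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_bed:
                seqid, start, end = fields[0], int(fields[1]), int(fields[2])
                out.setdefault(seqid, []).append((start + 1, end))
            else:
                if len(fields) < 5:
                    continue
                if feature_types and fields[2] not in feature_types:
                    continue
                out.setdefault(fields[0], []).append((int(fields[3]), int(fields[4])))
    return out


def write_gff3(path, features: Iterable[tuple[str, str, int, int, str, str]]) -> None:
    """Rows are (seqid, type, start_1based, end_inclusive, strand, attributes)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, strand, attrs in features:
            fh.write(f"{seqid}\tlakephage\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# alignment report (12-column tabular)
# ---------------------------------------------------------------------------

HITS_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "score",
]


def write_hits_tsv(path, hits: Iterable[AlignmentHit]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            ss, se = h.subject_interval
            if h.subject_strand == "-":
                ss, se = se, ss  # minus-strand hits print reversed subject coords
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t{h.alignment_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.query_interval[0]}\t{h.query_interval[1]}\t"
                f"{ss}\t{se}\t{h.expectation:.3g}\t{h.score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix
# ---------------------------------------------------------------------------


def write_phylip(path, ids: list[str], matrix) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"{len(ids)}\n")
        for i, name in enumerate(ids):
            row = " ".join(f"{matrix[i][j]:.6f}" for j in range(len(ids)))
            fh.write(f"{name} {row}\n")


def read_phylip(path) -> tuple[list[str], list[list[float]]]:
    with _open_text(path) as fh:
        n = int(fh.readline().split()[0])
        ids, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
    return ids, rows
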