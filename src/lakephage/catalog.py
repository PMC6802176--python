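"""Dataset-level summaries for cross-habitat comparison.

Protein novelty is measured by greedy incremental clustering at fixed
identity levels (30% and 60% by default, as used to compare habitat
catalogs): proteins are sorted longest first and each joins the first cluster
whose representative it matches at the identity level over at least 80% of
the shorter sequence, else it founds a new cluster.  Clusters whose members
all come from one dataset are that dataset's "unique" clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .discovery import PhageGenome
from .seqcore import ProteinSequence

IDENTITY_LEVELS = (30, 60)
DEFAULT_MIN_COVERAGE = 0.8


@dataclass
class ProteinCluster:
    representative: str
    members: list[tuple[str, str]]  # (protein id, dataset label)
    identity_level: float

    @property
    def datasets(self) -> set[str]:
        return {label for _pid, label in self.members}


def split_dataset_label(protein_id: str) -> tuple[str, str]:
    """Protein FASTA headers carry the dataset as ``id|dataset``."""
    name, _, label = protein_id.partition("|")
    return name, label or "unknown"


def _cluster_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def pair_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> tuple[float, float]:
    """(percent identity over aligned columns, aligned fraction of the shorter
    sequence) for the best local alignment of two proteins."""
    aligner = aligner or _cluster_aligner()
    a = a.replace("*", "X")
    b = b.replace("*", "X")
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0
    qa, sa = aln.aligned
    if len(qa) == 0:
        return 0.0, 0.0
    cols = sum(int(e - s) for s, e in qa)
    matches = sum(
        sum(x == y for x, y in zip(a[qs:qe], b[ss:se]))
        for (qs, qe), (ss, se) in zip(qa, sa)
    )
    coverage = cols / min(len(a), len(b))
    return (100.0 * matches / cols if cols else 0.0), coverage


def cluster_proteins(
    proteins: list[ProteinSequence],
    identity_level: float,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[ProteinCluster]:
    """Greedy longest-first incremental clustering (CD-HIT style).

    Deterministic: proteins are processed in descending length (ties by id)
    and join the first existing cluster whose *representative* they match at
    >= ``identity_level`` % identity over >= ``min_coverage`` of the shorter
    sequence.
    """
    aligner = _cluster_aligner()
    ordered = sorted(proteins, key=lambda p: (-len(p), p.id))
    clusters: list[ProteinCluster] = []
    reps: list[ProteinSequence] = []
    for protein in ordered:
        name, label = split_dataset_label(protein.id)
        placed = False
        for cluster, rep in zip(clusters, reps):
            identity, coverage = pair_identity(protein.residues, rep.residues, aligner)
            if identity >= identity_level and coverage >= min_coverage:
                cluster.members.append((protein.id, label))
                placed = True
                break
        if not placed:
            clusters.append(
                ProteinCluster(
                    representative=protein.id,
                    members=[(protein.id, label)],
                    identity_level=identity_level,
                )
            )
            reps.append(protein)
    return clusters


def unique_cluster_counts(
    clusters: list[ProteinCluster], datasets: list[str]
) -> dict[str, int]:
    """Clusters found in exactly one dataset, counted per dataset."""
    counts = {d: 0 for d in datasets}
    for cluster in clusters:
        ds = cluster.datasets
        if len(ds) == 1:
            (only,) = ds
            if only in counts:
                counts[only] += 1
    return counts


def genome_summary(genomes: list[PhageGenome]) -> pd.DataFrame:
    """Deterministic per-genome table of id, length, GC, and size class."""
    rows = [
        {"id": g.id, "length": g.length_bp, "gc": g.gc, "size_class": g.size_class}
        for g in sorted(genomes, key=lambda g: g.id)
    ]
    return pd.DataFrame(rows, columns=["id", "length", "gc", "size_class"])


def length_histogram(
    genomes: list[PhageGenome], bin_width_bp: int = 5000
) -> pd.DataFrame:
    """Genome-length histogram with configurable bins."""
    if not genomes:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    lengths = np.array([g.length_bp for g in genomes])
    lo = (lengths.min() // bin_width_bp) * bin_width_bp
    hi = ((lengths.max() // bin_width_bp) + 1) * bin_width_bp
    edges = np.arange(lo, hi + 1, bin_width_bp)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
        }
    )


def gc_histogram(genomes: list[PhageGenome], bin_width: float = 0.02) -> pd.DataFrame:
    if not genomes:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    gc = np.array([g.gc for g in genomes])
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(gc, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1].round(4), "bin_end": edges[1:].round(4), "count": counts}
    )
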