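"""Fragment-recruitment abundance profiling across a metagenome time series.

Reads are recruited to each genome (best local hit, counted when identity
exceeds 95% over an alignment of at least 50 bp); per-base depth over
unmasked positions gives the abundance metric "coverage per gigabase of
metagenome" (mean depth divided by sample gigabases), making values
comparable across samples of different sizes.  A genome is *present* in a
sample only when its breadth — the fraction of unmasked positions covered at
least once — strictly exceeds 0.80.  rRNA loci are masked before comparison
so conserved ribosomal sequence cannot recruit foreign reads.  Per-genome
profiles are Z-score normalized across samples and clustered with average
linkage on 1 - Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from ._intervals import merge_intervals
from .seqcore import AlignerParams, NucleotideSequence, ReadBatch, ReferenceIndex

log = logging.getLogger(__name__)

RECRUIT_MIN_IDENTITY = 95.0  # strict: identity must exceed this
RECRUIT_MIN_LENGTH_BP = 50  # inclusive
PRESENCE_MIN_BREADTH = 0.80  # strict
MICROBIAL_MAX_READS = 20_000_000


@dataclass
class Sample:
    """One metagenome: reads plus typed metadata."""

    id: str
    reads: list[tuple[str, str]]  # (read id, sequence); mates are separate entries
    date: str | None = None
    depth_m: float | None = None
    temperature_C: float | None = None

    @property
    def total_bases(self) -> int:
        return sum(len(seq) for _rid, seq in self.reads)


def recruit_params(seed_length: int = 13) -> AlignerParams:
    return AlignerParams.nucleotide(
        seed_length=seed_length,
        min_alignment_length=RECRUIT_MIN_LENGTH_BP,
        max_expectation=10.0,
    )


# ---------------------------------------------------------------------------
# masking and subsampling
# ---------------------------------------------------------------------------


def mask_rrna(
    genome: NucleotideSequence, intervals: list[tuple[int, int]]
) -> NucleotideSequence:
    """Replace the given 1-based inclusive intervals with N (length kept).

    Masked positions are excluded from the breadth denominator and from the
    mean-depth numerator downstream.
    """
    if not intervals:
        return genome
    n = len(genome)
    res = list(genome.residues)
    for start, end in merge_intervals(intervals):
        if start < 1 or end > n:
            raise ValueError(f"interval ({start}, {end}) outside genome bounds")
        res[start - 1 : end] = "N" * (end - start + 1)
    return NucleotideSequence(genome.id, "".join(res), genome.topology)


def subsample_reads(sample: Sample, max_reads: int, seed: int) -> Sample:
    """Uniform random subsample without replacement; deterministic per seed."""
    if max_reads <= 0:
        raise ValueError("max_reads must be positive")
    if len(sample.reads) <= max_reads:
        return sample
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(sample.reads), size=max_reads, replace=False)
    keep.sort()
    return replace(sample, reads=[sample.reads[i] for i in keep])


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------


@dataclass
class RecruitmentResult:
    genome_id: str
    depth: np.ndarray  # per-base coverage depth
    mapped_reads: int
    unmasked: np.ndarray  # bool mask of positions that count

    @property
    def breadth(self) -> float:
        m = int(self.unmasked.sum())
        if m == 0:
            return 0.0
        return float(np.count_nonzero(self.depth[self.unmasked] > 0)) / m

    def mean_depth(self) -> float:
        m = int(self.unmasked.sum())
        if m == 0:
            return 0.0
        return float(self.depth[self.unmasked].sum()) / m


def _read_passes(hit) -> bool:
    return (
        hit is not None
        and hit.percent_identity > RECRUIT_MIN_IDENTITY
        and hit.alignment_length >= RECRUIT_MIN_LENGTH_BP
    )


def recruit(
    genome: NucleotideSequence,
    sample: Sample,
    params: AlignerParams | None = None,
    index: ReferenceIndex | None = None,
) -> RecruitmentResult:
    """Recruit a sample's reads to one genome.

    Each read (mates independently) is aligned; its best hit counts when the
    identity exceeds 95% over >= 50 aligned bp, incrementing depth over the
    covered reference interval.
    """
    if index is None:
        index = ReferenceIndex(genome, params or recruit_params())
    n = len(genome)
    depth = np.zeros(n, dtype=np.int32)
    mapped = 0
    batch = ReadBatch([seq for _rid, seq in sample.reads], index.params.seed_length)
    for hit in index.best_hits_batch(batch):
        if _read_passes(hit):
            start, end = hit.subject_interval
            depth[start - 1 : end] += 1
            mapped += 1
    unmasked = np.frombuffer(genome.residues.encode(), dtype=np.uint8) != ord("N")
    return RecruitmentResult(genome.id, depth, mapped, unmasked)


def coverage_per_gb(
    mean_depth: float | RecruitmentResult, sample_total_bases: int
) -> float:
    """Mean per-base depth over unmasked positions per gigabase of metagenome."""
    if sample_total_bases <= 0:
        raise ValueError("sample_total_bases must be positive")
    if isinstance(mean_depth, RecruitmentResult):
        mean_depth = mean_depth.mean_depth()
    return mean_depth / (sample_total_bases / 1e9)


def presence_call(breadth: float, min_breadth: float = PRESENCE_MIN_BREADTH) -> bool:
    """Present iff breadth strictly exceeds the threshold (default 0.80)."""
    return breadth > min_breadth


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    coverage_per_gb: pd.DataFrame  # genomes x samples
    breadth: pd.DataFrame
    present: pd.DataFrame
    zscores: pd.DataFrame

    @property
    def genome_ids(self) -> list[str]:
        return list(self.coverage_per_gb.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coverage_per_gb.columns)


def zscore_rows(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Per-row (x - mean) / population-sd; constant rows map to zeros."""
    values = np.asarray(matrix, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def build_abundance_matrix(
    genomes: Sequence[NucleotideSequence],
    samples: Sequence[Sample],
    params: AlignerParams | None = None,
    rrna_intervals: dict[str, list[tuple[int, int]]] | None = None,
    best_hit_across_genomes: bool = True,
    subsample_microbial: bool = False,
    max_reads: int = MICROBIAL_MAX_READS,
    seed: int = 0,
    min_breadth: float = PRESENCE_MIN_BREADTH,
) -> AbundanceMatrix:
    """Genome x sample abundance profiling.

    With ``best_hit_across_genomes`` each read counts only for the genome
    where it scores best (ties go to the first genome in input order, matching
    a best-hit mapper); otherwise every genome passing the cutoffs counts it.
    ``subsample_microbial`` applies the 20-million-read cap used for microbial
    (host) genomes; phage genomes are profiled against full read sets.
    """
    params = params or recruit_params()
    masked = [
        mask_rrna(g, (rrna_intervals or {}).get(g.id, [])) for g in genomes
    ]
    indexes = [ReferenceIndex(g, params) for g in masked]
    unmasked = [
        np.frombuffer(g.residues.encode(), dtype=np.uint8) != ord("N") for g in masked
    ]
    cov = np.zeros((len(genomes), len(samples)))
    breadth = np.zeros_like(cov)
    for s_idx, sample in enumerate(samples):
        if subsample_microbial:
            sample = subsample_reads(sample, max_reads, seed)
        depths = [np.zeros(len(g), dtype=np.int32) for g in masked]
        n_ties = 0
        batch = ReadBatch([seq for _rid, seq in sample.reads], params.seed_length)
        per_genome_hits = [index.best_hits_batch(batch) for index in indexes]
        for r_idx in range(len(sample.reads)):
            best = [
                (g_idx, hits[r_idx])
                for g_idx, hits in enumerate(per_genome_hits)
                if _read_passes(hits[r_idx])
            ]
            if not best:
                continue
            if best_hit_across_genomes:
                top = max(h.score for _g, h in best)
                tied = [(g, h) for g, h in best if h.score == top]
                if len(tied) > 1:
                    n_ties += 1
                best = tied[:1]  # tie -> first-encountered genome
            for g_idx, hit in best:
                start, end = hit.subject_interval
                depths[g_idx][start - 1 : end] += 1
        if n_ties:
            log.warning(
                "%s: %d reads tied between genomes; assigned to first encountered",
                sample.id,
                n_ties,
            )
        for g_idx in range(len(masked)):
            result = RecruitmentResult(
                masked[g_idx].id, depths[g_idx], 0, unmasked[g_idx]
            )
            cov[g_idx, s_idx] = coverage_per_gb(result, sample.total_bases)
            breadth[g_idx, s_idx] = result.breadth
    genome_ids = [g.id for g in genomes]
    sample_ids = [s.id for s in samples]
    cov_df = pd.DataFrame(cov, index=genome_ids, columns=sample_ids)
    breadth_df = pd.DataFrame(breadth, index=genome_ids, columns=sample_ids)
    present_df = breadth_df.gt(min_breadth)
    return AbundanceMatrix(
        coverage_per_gb=cov_df,
        breadth=breadth_df,
        present=present_df,
        zscores=zscore_rows(cov_df),
    )


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------


def spearman_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman rho between rows (average ranks for ties)."""
    ranks = np.apply_along_axis(rankdata, 1, np.asarray(values, dtype=float))
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    n = values.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 or norms[j] == 0:
                rho = 0.0  # constant profile: correlation undefined, treated as 0
            else:
                rho = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
            dist[i, j] = dist[j, i] = 1.0 - rho
    return dist


def cluster_profiles(
    matrix: pd.DataFrame | np.ndarray, ids: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomeration on 1 - Spearman rank correlation.

    Returns the scipy linkage matrix and the deterministic leaf order (ties
    within the dendrogram resolve by input order; input rows are taken in id
    order when a DataFrame is given).
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.sort_index()
        ids = list(matrix.index)
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        ids = ids or [str(i) for i in range(values.shape[0])]
    if values.shape[0] < 2:
        raise ValueError("need at least two profiles")
    dist = spearman_distance_matrix(values)
    condensed = dist[np.triu_indices(values.shape[0], k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    leaf_order = [ids[i] for i in hierarchy.leaves_list(linkage)]
    return linkage, leaf_order


def linkage_to_newick(linkage: np.ndarray, ids: list[str]) -> str:
    """Dendrogram as a newick string (heights become branch lengths)."""
    tree = hierarchy.to_tree(linkage)

    def _rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{max(node.dist, 0):.6f}" if parent_height is None else (
                f"{ids[node.id]}:{length:.6f}"
            )
        inner = ",".join(_rec(c, node.dist) for c in (node.left, node.right))
        if parent_height is None:
            return f"({inner})"
        return f"({inner}):{length:.6f}"

    return _rec(tree, None) + ";"
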