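"""Genome dereplication: collapse near-identical phage genomes.

All-vs-all nucleotide comparison retains significant hits (expectation
< 1e-3, identity > 95%); two genomes are linked when the merged hit intervals
cover >= 95% of *both* genomes.  Clusters are the connected components of the
link graph (single linkage) and the longest member represents each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from ._intervals import total_length
from .discovery import PhageGenome
from .seqcore import AlignerParams, align

DEFAULT_MAX_EXPECTATION = 1e-3
DEFAULT_MIN_HIT_IDENTITY = 95.0  # strict: hits must exceed this
DEFAULT_MIN_COVERAGE = 0.95  # inclusive: both genomes >= 95% covered


@dataclass(frozen=True)
class PairwiseGenomeComparison:
    a_id: str
    b_id: str
    coverage_a: float
    coverage_b: float
    mean_identity: float

    @property
    def linked(self) -> bool:
        return min(self.coverage_a, self.coverage_b) >= DEFAULT_MIN_COVERAGE


@dataclass(frozen=True)
class DereplicationCluster:
    members: tuple[str, ...]
    representative: str

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


def _derep_params(seed_length: int = 13) -> AlignerParams:
    # identity is filtered strictly (>95) on the emitted hits, not here
    return AlignerParams.nucleotide(
        seed_length=seed_length,
        max_expectation=DEFAULT_MAX_EXPECTATION,
        min_alignment_length=0,
    )


def compare_pair(
    a: PhageGenome,
    b: PhageGenome,
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    min_hit_identity: float = DEFAULT_MIN_HIT_IDENTITY,
) -> PairwiseGenomeComparison:
    """Mutual-coverage comparison from significant high-identity hits.

    Coverage of each genome is the merged-interval union of its hit
    footprints (no double counting); mean identity is alignment-length
    weighted over the contributing hits.
    """
    hits = [
        h
        for h in align(a.sequence, b.sequence, _derep_params())
        if h.expectation < max_expectation and h.percent_identity > min_hit_identity
    ]
    if not hits:
        return PairwiseGenomeComparison(a.id, b.id, 0.0, 0.0, 0.0)
    cov_a = total_length([h.query_interval for h in hits]) / a.length_bp
    cov_b = total_length([h.subject_interval for h in hits]) / b.length_bp
    wsum = sum(h.alignment_length for h in hits)
    mean_id = sum(h.percent_identity * h.alignment_length for h in hits) / wsum
    return PairwiseGenomeComparison(a.id, b.id, min(cov_a, 1.0), min(cov_b, 1.0), mean_id)


def _length_prefilter(a: PhageGenome, b: PhageGenome, min_coverage: float) -> bool:
    """Mutual >= 95% coverage is impossible when lengths differ too much."""
    short, long_ = sorted((a.length_bp, b.length_bp))
    return short >= min_coverage * long_


def cluster_genomes(
    genomes: list[PhageGenome],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_hit_identity: float = DEFAULT_MIN_HIT_IDENTITY,
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
) -> list[DereplicationCluster]:
    """Single-linkage clustering over the mutual-coverage link graph.

    Representatives are the longest members (ties broken by lexicographically
    smallest id); clusters are sorted by representative id.  The result is
    invariant to input order.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    by_id = {g.id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise ValueError("duplicate genome ids")
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    ordered = sorted(genomes, key=lambda g: g.id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if not _length_prefilter(a, b, min_coverage):
                continue
            cmp = compare_pair(a, b, max_expectation, min_hit_identity)
            if min(cmp.coverage_a, cmp.coverage_b) >= min_coverage:
                graph.add_edge(a.id, b.id)
    clusters = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        rep = min(members, key=lambda gid: (-by_id[gid].length_bp, gid))
        clusters.append(DereplicationCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.representative)
    return clusters


def dereplicate(
    genomes: list[PhageGenome], **cluster_kwargs
) -> tuple[list[PhageGenome], list[DereplicationCluster]]:
    """One representative genome per cluster, plus the cluster manifest."""
    clusters = cluster_genomes(genomes, **cluster_kwargs)
    by_id = {g.id: g for g in genomes}
    reps = [by_id[c.representative] for c in clusters]
    return reps, clusters


def cluster_manifest_rows(
    clusters: list[DereplicationCluster], genomes: list[PhageGenome]
) -> list[dict]:
    by_id = {g.id: g for g in genomes}
    rows = []
    for idx, cluster in enumerate(clusters, start=1):
        rep = by_id[cluster.representative]
        for member in cluster.members:
            if member == cluster.representative:
                cov, ident = 1.0, 100.0
            else:
                cmp = compare_pair(by_id[member], rep)
                cov, ident = cmp.coverage_a, cmp.mean_identity
            rows.append(
                {
                    "cluster_id": f"cluster_{idx}",
                    "representative": cluster.representative,
                    "member": member,
                    "coverage_to_rep": round(cov, 4),
                    "identity_to_rep": round(ident, 2),
                }
            )
    return rows
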