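"""Host prediction from four evidence channels.

A phage is linked to a host (or a host taxon) through:

* ``crispr_spacer`` — a spacer archived in a host CRISPR array matches the
  phage at stringent cutoffs (>= 30 bp, >= 97% identity, >= 97% spacer
  coverage, expectation <= 1e-5); strain resolution.
* ``trna_attb`` — phage/host shared sequence overlapping an annotated host
  tRNA locus (the usual attB integration site); strain resolution.
* ``shared_sequence`` — any other shared nucleotide stretch at the same
  per-hit cutoffs (prophage remnants, recent exchange); strain resolution.
* ``marker_gene`` — a taxon-restricted protein (e.g. a WhiB-family regulator
  marking actinophages) encoded on the phage; phylum resolution only.

Channels are integrated with precedence spacer > attB > shared > marker; ties
between hosts inside the winning channel leave the call ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from ._intervals import overlap_length
from .discovery import PhageGenome
from .seqcore import (
    AlignerParams,
    AlignmentHit,
    NucleotideSequence,
    ProteinSequence,
    _encode_nt,
    _kmer_codes,
    align,
    expectation_value,
)

CHANNEL_PRECEDENCE = ("crispr_spacer", "trna_attb", "shared_sequence", "marker_gene")

# stringent nucleotide cutoffs shared by the spacer / attB / shared channels
MIN_HIT_LENGTH_BP = 30
MIN_HIT_IDENTITY = 97.0
MIN_QUERY_COVERAGE = 0.97  # spacer channel only
MAX_HIT_EXPECTATION = 1e-5

# marker-gene channel (protein level)
MARKER_MIN_IDENTITY = 30.0
MARKER_MIN_COVERAGE = 0.70
MARKER_MAX_EXPECTATION = 1e-5

TRNA_MIN_OVERLAP_BP = 20


@dataclass(frozen=True)
class CrisprArray:
    """A CRISPR repeat-spacer array detected in a host genome."""

    host_id: str
    repeat_consensus: str
    repeats: tuple[tuple[int, int], ...]
    spacers: tuple[tuple[str, tuple[int, int]], ...]

    def __post_init__(self):
        if self.n_repeats < 3:
            raise ValueError("an array needs at least three repeats")
        if len(self.spacers) != self.n_repeats - 1:
            raise ValueError("spacer count must be repeat count - 1")

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


@dataclass(frozen=True)
class HostEvidence:
    phage_id: str
    host_id: str
    channel: str
    taxon_resolution: str
    hit: AlignmentHit | None = None
    marker_name: str = ""

    def __post_init__(self):
        if self.channel not in CHANNEL_PRECEDENCE:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass(frozen=True)
class HostCall:
    phage_id: str
    host_id: str | None
    winning_channel: str | None
    status: str  # assigned | ambiguous | unassigned
    all_evidence: tuple[HostEvidence, ...] = ()


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------


def _marker_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def split_marker_taxon(marker_id: str) -> tuple[str, str]:
    """Marker FASTA headers carry the taxon as ``name|taxon``."""
    name, _, taxon = marker_id.partition("|")
    return name, taxon or "unknown"


def detect_marker_genes(
    phage: PhageGenome,
    markers: list[ProteinSequence],
    min_identity: float = MARKER_MIN_IDENTITY,
    min_marker_coverage: float = MARKER_MIN_COVERAGE,
    max_expectation: float = MARKER_MAX_EXPECTATION,
) -> list[HostEvidence]:
    """Search phage ORFs for host-restricted marker proteins.

    Evidence requires >= ``min_identity`` % identity over >=
    ``min_marker_coverage`` of the marker length at expectation <=
    ``max_expectation``; one record per (ORF, marker) pair, so multi-copy
    markers yield multiple records.  Phylum-level resolution.
    """
    if not markers:
        raise ValueError("marker set is empty")
    aligner = _marker_aligner()
    params = AlignerParams(matrix="BLOSUM62")
    evidence: list[HostEvidence] = []
    for orf in phage.orfs:
        clean = orf.residues.replace("*", "X")
        for marker in markers:
            name, taxon = split_marker_taxon(marker.id)
            try:
                aln = aligner.align(clean, marker.residues)[0]
            except (IndexError, ValueError):
                continue
            qa, sa = aln.aligned
            if len(qa) == 0:
                continue
            cols = sum(int(e - s) for s, e in qa)
            matches = sum(
                sum(a == b for a, b in zip(clean[qs:qe], marker.residues[ss:se]))
                for (qs, qe), (ss, se) in zip(qa, sa)
            )
            marker_cov = sum(int(e - s) for s, e in sa) / len(marker)
            identity = 100.0 * matches / cols if cols else 0.0
            e_val = expectation_value(aln.score, len(orf), len(marker), params, "translated")
            if (
                identity >= min_identity
                and marker_cov >= min_marker_coverage
                and e_val <= max_expectation
            ):
                hit = AlignmentHit(
                    query_id=orf.id,
                    subject_id=marker.id,
                    query_interval=(int(qa[0][0]) + 1, int(qa[-1][1])),
                    subject_interval=(int(sa[0][0]) + 1, int(sa[-1][1])),
                    percent_identity=identity,
                    alignment_length=cols,
                    score=float(aln.score),
                    expectation=e_val,
                    mode="translated",
                    matches=matches,
                    mismatches=cols - matches,
                )
                evidence.append(
                    HostEvidence(
                        phage_id=phage.id,
                        host_id=taxon,
                        channel="marker_gene",
                        taxon_resolution="phylum",
                        hit=hit,
                        marker_name=name,
                    )
                )
    return evidence


# ---------------------------------------------------------------------------
# CRISPR array detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrisprParams:
    min_repeats: int = 3
    repeat_length: tuple[int, int] = (23, 47)
    spacer_length: tuple[int, int] = (26, 50)
    max_mismatch_to_consensus: int = 1
    seed_length: int = 16


def _consensus(strings: list[str]) -> str:
    out = []
    for column in zip(*strings):
        out.append(Counter(column).most_common(1)[0][0])
    return "".join(out)


def detect_crispr_arrays(
    host: NucleotideSequence, params: CrisprParams | None = None
) -> list[CrisprArray]:
    """CRT-style repeat-spacer array detection.

    Candidate arrays are seeded by an exact k-mer recurring at spacings
    compatible with one repeat plus one spacer; repeat boundaries are then
    extended across all copies while each copy stays within
    ``max_mismatch_to_consensus`` of the column consensus, and arrays are kept
    when >= 3 repeats with in-range repeat and spacer lengths remain.
    """
    p = params or CrisprParams()
    res = host.residues
    n = len(res)
    k = p.seed_length
    min_gap = p.repeat_length[0] + p.spacer_length[0]
    max_gap = p.repeat_length[1] + p.spacer_length[1]
    # recurring k-mers located vectorially; only those with >= min_repeats
    # occurrences can seed an array
    arr = _encode_nt(res)
    codes, pos = _kmer_codes(arr, k, 4, invalid=(4,))
    order = np.lexsort((pos, codes))
    codes, pos = codes[order], pos[order]
    boundaries = np.nonzero(np.diff(codes))[0] + 1
    groups = np.split(pos, boundaries)
    arrays: list[CrisprArray] = []
    claimed: set[int] = set()
    seed_groups = sorted(
        (g.tolist() for g in groups if g.size >= p.min_repeats),
        key=lambda g: g[0],
    )
    for positions in seed_groups:
        # greedy chains of positions with plausible spacing
        i = 0
        while i < len(positions):
            chain = [positions[i]]
            j = i + 1
            while j < len(positions):
                gap = positions[j] - chain[-1]
                if min_gap <= gap <= max_gap:
                    chain.append(positions[j])
                    j += 1
                elif gap < min_gap:
                    j += 1
                else:
                    break
            i += 1
            if len(chain) < p.min_repeats or chain[0] in claimed:
                continue
            array = _refine_array(host, res, chain, k, p)
            if array is not None:
                arrays.append(array)
                claimed.update(range(array.repeats[0][0] - 1, array.repeats[-1][1]))
    arrays.sort(key=lambda a: a.repeats[0][0])
    return arrays


def _refine_array(
    host: NucleotideSequence, res: str, starts: list[int], k: int, p: CrisprParams
) -> CrisprArray | None:
    n = len(res)
    max_len = p.repeat_length[1]
    # extend repeat boundaries symmetrically around the seed while all copies
    # agree with the consensus within tolerance
    left, right = 0, k  # repeat = [start - left, start + right)
    while right + left < max_len:
        grew = False
        for dleft, dright in ((1, 0), (0, 1)):
            nl, nr = left + dleft, right + dright
            if nr + nl > max_len:
                continue
            if any(s - nl < 0 or s + nr > n for s in starts):
                continue
            copies = [res[s - nl : s + nr] for s in starts]
            cons = _consensus(copies)
            if all(
                sum(a != b for a, b in zip(c, cons)) <= p.max_mismatch_to_consensus
                for c in copies
            ):
                left, right = nl, nr
                grew = True
        if not grew:
            break
    # trim non-unanimous boundary columns: the mismatch tolerance lets the
    # extension creep one or two bases into the (random) spacers
    def _column(offset: int) -> list[str]:
        return [res[s + offset] for s in starts]

    while left + right > k and len(set(_column(-left))) > 1:
        left -= 1
    while left + right > k and len(set(_column(right - 1))) > 1:
        right -= 1
    rep_len = left + right
    if not p.repeat_length[0] <= rep_len <= p.repeat_length[1]:
        return None
    repeat_ivs = [(s - left + 1, s + right) for s in starts]  # 1-based inclusive
    spacers = []
    for (s1, e1), (s2, e2) in zip(repeat_ivs, repeat_ivs[1:]):
        seq = res[e1 : s2 - 1]
        if not p.spacer_length[0] <= len(seq) <= p.spacer_length[1]:
            return None
        spacers.append((seq, (e1 + 1, s2 - 1)))
    copies = [res[s - left : s + right] for s in starts]
    return CrisprArray(
        host_id=host.id,
        repeat_consensus=_consensus(copies),
        repeats=tuple(repeat_ivs),
        spacers=tuple(spacers),
    )


# ---------------------------------------------------------------------------
# nucleotide evidence channels
# ---------------------------------------------------------------------------


def _stringent_params(seed_length: int = 13) -> AlignerParams:
    return AlignerParams.nucleotide(
        seed_length=seed_length,
        min_alignment_length=MIN_HIT_LENGTH_BP,
        max_expectation=MAX_HIT_EXPECTATION,
    )


def _stringent_hits(query: NucleotideSequence, subject: NucleotideSequence) -> list[AlignmentHit]:
    return [
        h
        for h in align(query, subject, _stringent_params())
        if h.alignment_length >= MIN_HIT_LENGTH_BP
        and h.percent_identity >= MIN_HIT_IDENTITY
        and h.expectation <= MAX_HIT_EXPECTATION
    ]


def match_spacers(
    arrays: list[CrisprArray], phages: list[PhageGenome]
) -> list[HostEvidence]:
    """CRISPR spacers vs phage genomes at the stringent cutoffs, requiring
    >= 97% of the spacer to be covered by the hit.  Strain resolution."""
    evidence: list[HostEvidence] = []
    for array in arrays:
        for s_idx, (spacer_seq, _iv) in enumerate(array.spacers):
            spacer = NucleotideSequence(f"{array.host_id}_spacer{s_idx+1}", spacer_seq)
            for phage in phages:
                for hit in _stringent_hits(spacer, phage.sequence):
                    if hit.query_span() / len(spacer) < MIN_QUERY_COVERAGE:
                        continue
                    evidence.append(
                        HostEvidence(
                            phage_id=phage.id,
                            host_id=array.host_id,
                            channel="crispr_spacer",
                            taxon_resolution="strain",
                            hit=hit,
                        )
                    )
    return evidence


def match_trna_attb(
    phage: PhageGenome,
    host: NucleotideSequence,
    trna_loci: list[tuple[int, int]],
    min_overlap_bp: int = TRNA_MIN_OVERLAP_BP,
) -> list[HostEvidence]:
    """Phage/host shared sequence restricted to annotated tRNA loci (attB
    integration-site signature); hits must overlap a locus by >= 20 bp."""
    if not trna_loci:
        return []
    evidence = []
    for hit in _stringent_hits(phage.sequence, host):
        if any(overlap_length(hit.subject_interval, locus) >= min_overlap_bp for locus in trna_loci):
            evidence.append(
                HostEvidence(
                    phage_id=phage.id,
                    host_id=host.id,
                    channel="trna_attb",
                    taxon_resolution="strain",
                    hit=hit,
                )
            )
    return evidence


def shared_sequence_evidence(
    phage: PhageGenome, host: NucleotideSequence
) -> list[HostEvidence]:
    """Direct phage-vs-host genome comparison at the stringent per-hit
    cutoffs (>= 30 bp, >= 97% identity, <= 1e-5).  Strain resolution."""
    return [
        HostEvidence(
            phage_id=phage.id,
            host_id=host.id,
            channel="shared_sequence",
            taxon_resolution="strain",
            hit=hit,
        )
        for hit in _stringent_hits(phage.sequence, host)
    ]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def assign_host(evidence: list[HostEvidence], phage_id: str | None = None) -> HostCall:
    """Integrate evidence into one host call.

    Channel precedence: crispr_spacer > trna_attb > shared_sequence >
    marker_gene.  Within the winning channel the host with the most evidence
    records is assigned; a tie yields an ambiguous call, no evidence at all an
    unassigned one.  Pure function of the evidence multiset.
    """
    if phage_id is None:
        phage_id = evidence[0].phage_id if evidence else ""
    relevant = tuple(sorted(
        (e for e in evidence if e.phage_id == phage_id),
        key=lambda e: (e.channel, e.host_id),
    ))
    for channel in CHANNEL_PRECEDENCE:
        records = [e for e in relevant if e.channel == channel]
        if not records:
            continue
        tally = Counter(e.host_id for e in records)
        ranked = tally.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return HostCall(phage_id, None, channel, "ambiguous", relevant)
        return HostCall(phage_id, ranked[0][0], channel, "assigned", relevant)
    return HostCall(phage_id, None, None, "unassigned", relevant)


def predict_hosts(
    phages: list[PhageGenome],
    hosts: list[NucleotideSequence],
    markers: list[ProteinSequence] | None = None,
    trna_loci: dict[str, list[tuple[int, int]]] | None = None,
    crispr_params: CrisprParams | None = None,
) -> tuple[list[HostCall], list[HostEvidence]]:
    """Run all four channels over a community and integrate per phage."""
    evidence: list[HostEvidence] = []
    arrays: list[CrisprArray] = []
    for host in hosts:
        arrays.extend(detect_crispr_arrays(host, crispr_params))
    evidence.extend(match_spacers(arrays, phages))
    for phage in phages:
        for host in hosts:
            loci = (trna_loci or {}).get(host.id, [])
            attb = match_trna_attb(phage, host, loci)
            evidence.extend(attb)
            attb_keys = {(e.hit.query_interval, e.hit.subject_interval) for e in attb}
            for e in shared_sequence_evidence(phage, host):
                # a hit already explained as an attB match is not double-reported
                if (e.hit.query_interval, e.hit.subject_interval) not in attb_keys:
                    evidence.append(e)
        if markers:
            evidence.extend(detect_marker_genes(phage, markers))
    calls = [assign_host(evidence, phage_id=p.id) for p in phages]
    return calls, evidence
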