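"""Shared sequence primitives.

Everything downstream (circularity detection, dereplication, host linkage,
fragment recruitment, the proteomic tree) is built on four primitives defined
here: nucleotide/protein sequence records, a six-frame ORF caller, a
seed-and-extend local aligner with a nucleotide and a translated mode, and
Karlin-Altschul expectation values for threshold filtering.

The aligner uses exact k-mer seeding (default word size 13 nt / 4 aa), ungapped
X-drop extension along each seeded diagonal, and colinear chaining of the
resulting segments with affine gap costs.  All pipeline thresholds sit at high
identity (>= 95-97%), where exact seeding at these word sizes is essentially
lossless; see docs/methods.md for the sensitivity argument.

Coordinates are 0-based half-open internally and 1-based inclusive on every
emitted record, matching the common tabular alignment-report dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "NucleotideSequence",
    "ProteinSequence",
    "AlignmentHit",
    "AlignerParams",
    "gc_content",
    "reverse_complement",
    "find_orfs",
    "align",
    "translated_align",
    "expectation_value",
    "ReferenceIndex",
]

# ---------------------------------------------------------------------------
# sequence records
# ---------------------------------------------------------------------------

_NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# residue -> small integer; N = 4 (never matches anything, including itself)
_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"
_AA_CODE = np.full(256, PROTEIN_ALPHABET.index("X"), dtype=np.uint8)
for _i, _c in enumerate(PROTEIN_ALPHABET):
    _AA_CODE[ord(_c)] = _i


def reverse_complement(residues: str) -> str:
    return residues.translate(_NT_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence record (contig, genome, read, or spacer).

    ``topology`` is 'circular' only for sequences that were either synthesized
    circular or passed terminal-repeat circularity detection.
    """

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        canonical = self.residues.upper()
        if canonical is not self.residues and canonical != self.residues:
            object.__setattr__(self, "residues", canonical)
        bad = set(canonical) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {self.id!r} has non-ACGTN residues {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.residues), self.topology)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein record, optionally anchored to a source genome.

    ``frame`` is 1..3 / -1..-3 for called ORFs (0 for free-standing proteins
    such as marker references).  ``interval`` is 1-based inclusive on the
    forward strand of the source; for ORFs wrapping a circular origin the end
    may exceed the source length (positions are taken modulo length).
    """

    id: str
    residues: str
    source_genome: str = ""
    frame: int = 0
    interval: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"protein {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentHit:
    """One scored local alignment between two sequences.

    ``alignment_length`` counts aligned columns (bp in nucleotide mode, aa in
    translated mode; gap columns included).  Intervals are 1-based inclusive;
    ``subject_interval`` is always on the forward strand of the subject, with
    ``subject_strand`` recording the matched strand.  The query strand is
    always '+'.
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    percent_identity: float
    alignment_length: int
    score: float
    expectation: float
    subject_strand: str = "+"
    mode: str = "nucleotide"
    matches: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    def query_span(self) -> int:
        return self.query_interval[1] - self.query_interval[0] + 1


@dataclass(frozen=True)
class AlignerParams:
    """Thresholds and scoring for the seed-and-extend aligner.

    Nucleotide mode scores +match/-mismatch with affine gaps; translated mode
    uses a named substitution matrix (BLOSUM45 by default, as for the
    proteomic-tree comparison).  ``min_identity`` and ``min_alignment_length``
    are inclusive (>=); callers that need a strict '>' cutoff filter on the
    emitted hit fields.
    """

    seed_length: int = 13
    min_identity: float = 0.0
    min_alignment_length: int = 0
    max_expectation: float = 10.0
    match: int = 1
    mismatch: int = 2  # penalty, applied as negative
    gap_open: int = 5
    gap_extend: int = 2
    matrix: str = "BLOSUM45"
    xdrop: float = 50.0
    max_chain_gap: int = 50
    two_hit_window: int | None = None  # translated mode: classic two-hit gating
    karlin_lambda: float | None = None
    karlin_k: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if self.seed_length < 3:
            raise ValueError("seed_length too small")

    @staticmethod
    def nucleotide(**kw) -> "AlignerParams":
        if kw.get("seed_length", 13) < 8:
            raise ValueError("nucleotide seed_length must be >= 8")
        return AlignerParams(**kw)

    @staticmethod
    def translated(**kw) -> "AlignerParams":
        kw.setdefault("seed_length", 4)
        kw.setdefault("max_expectation", 1e-3)
        kw.setdefault("gap_open", 14)
        kw.setdefault("gap_extend", 2)
        kw.setdefault("xdrop", 40.0)
        kw.setdefault("two_hit_window", 40)
        return AlignerParams(**kw)


# Ungapped Karlin-Altschul parameters by scoring scheme (published values).
_KARLIN_NT = {"lambda": 1.28, "K": 0.46}  # +1/-2
_KARLIN_PROT = {
    "BLOSUM45": {"lambda": 0.2291, "K": 0.0924},
    "BLOSUM62": {"lambda": 0.3176, "K": 0.134},
}


def _karlin(params: AlignerParams, mode: str) -> tuple[float, float]:
    if params.karlin_lambda is not None and params.karlin_k is not None:
        return params.karlin_lambda, params.karlin_k
    if mode == "nucleotide":
        return _KARLIN_NT["lambda"], _KARLIN_NT["K"]
    tab = _KARLIN_PROT.get(params.matrix, _KARLIN_PROT["BLOSUM62"])
    return tab["lambda"], tab["K"]


def expectation_value(
    score: float,
    query_len: int,
    subject_len: int,
    params: AlignerParams | None = None,
    mode: str = "nucleotide",
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S).

    Strictly decreasing in the score, linear in the m*n search space.  Used
    only for threshold comparisons (the pipeline cutoffs 1e-3 / 1e-5 sit at
    generous margins), so calibration-grade accuracy is not claimed.
    """
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    if params is None:
        params = AlignerParams()
    lam, k = _karlin(params, mode)
    return k * query_len * subject_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def gc_content(seq: NucleotideSequence) -> float:
    """GC fraction over unambiguous bases; N excluded from both counts."""
    arr = _NT_CODE[np.frombuffer(seq.residues.encode(), dtype=np.uint8)]
    counts = np.bincount(arr, minlength=5)
    acgt = int(counts[:4].sum())
    if acgt == 0:
        raise ValueError(f"sequence {seq.id!r} has no unambiguous bases")
    return float(counts[1] + counts[2]) / acgt  # C + G


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

START_CODONS = ("ATG", "GTG", "TTG")  # translation table 11


def _scan_frame(s: str, off: int, min_aa: int, limit_codons: int):
    """Yield (start_idx, end_idx_exclusive, has_stop) for maximal ORFs in one
    frame of string ``s`` (0-based indices into ``s``)."""
    n = len(s)
    start = None
    i = off
    while i + 3 <= n:
        codon = s[i : i + 3]
        if start is None and codon in START_CODONS:
            start = i
        if codon in ("TAA", "TAG", "TGA"):
            if start is not None:
                n_aa = (i - start) // 3
                if n_aa >= min_aa and n_aa <= limit_codons:
                    yield start, i + 3, True
            start = None
        i += 3
    if start is not None:
        n_aa = (i - start) // 3
        if n_aa >= min_aa and n_aa <= limit_codons:
            yield start, i, False


def _translate_cds(cds: str) -> str:
    prot = str(Seq(cds).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    # alternative starts are initiator Met
    if prot:
        prot = "M" + prot[1:]
    return prot


def find_orfs(seq: NucleotideSequence, min_length_aa: int = 30) -> list[ProteinSequence]:
    """Call maximal ORFs on all six frames (translation table 11).

    An ORF runs from the first start codon (ATG/GTG/TTG) after the previous
    in-frame stop to the next stop (or the sequence end on linear sequences).
    On circular sequences the scan runs over the doubled sequence so ORFs may
    span the origin; ORF length is capped at one full circle.  The stop codon
    is included in the interval but not in the residues.
    """
    if min_length_aa < 1:
        raise ValueError("min_length_aa must be >= 1")
    n = len(seq)
    circular = seq.topology == "circular"
    orfs: list[ProteinSequence] = []
    counter = 0
    for strand in (1, -1):
        s = seq.residues if strand == 1 else reverse_complement(seq.residues)
        scan = s + s if circular else s
        limit = n // 3 if circular else n
        for off in (0, 1, 2):
            for start, end, has_stop in _scan_frame(scan, off, min_length_aa, limit):
                if start >= n:  # duplicate from the second copy
                    continue
                cds = scan[start : end - 3] if has_stop else scan[start:end]
                prot = _translate_cds(cds)
                if len(prot) < min_length_aa:
                    continue
                counter += 1
                if strand == 1:
                    interval = (start + 1, end)
                    frame = (start % 3) + 1
                else:
                    # map [start, end) on the reverse strand to forward coords
                    fs, fe = n - end, n - start  # may be negative when wrapped
                    if fs < 0:
                        fs += n
                        fe += n
                    interval = (fs + 1, fe)
                    frame = -((start % 3) + 1)
                orfs.append(
                    ProteinSequence(
                        id=f"{seq.id}_orf{counter}",
                        residues=prot,
                        source_genome=seq.id,
                        frame=frame,
                        interval=interval,
                    )
                )
    orfs.sort(key=lambda p: (p.interval[0], p.interval[1], p.frame))
    # stable renumbering for deterministic ids
    return [replace(p, id=f"{seq.id}_orf{i+1}") for i, p in enumerate(orfs)]


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------


def _encode_nt(residues: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(residues.encode(), dtype=np.uint8)]


def _encode_aa(residues: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(residues.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int, n_symbols: int, invalid: Iterable[int]):
    """Rolling k-mer codes; returns (codes, positions) for valid windows only
    (windows containing an 'invalid' symbol — N or stop — are dropped)."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    a = arr.astype(np.int64)
    for i in range(k):
        codes = codes * n_symbols + a[i : i + m]
    bad = np.zeros(n, dtype=np.int32)
    for sym in invalid:
        bad |= arr == sym
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return codes[pos], pos


class _SortedKmerIndex:
    """Sorted-array exact k-mer index over one encoded sequence."""

    def __init__(self, arr: np.ndarray, k: int, n_symbols: int, invalid: Iterable[int]):
        codes, pos = _kmer_codes(arr, k, n_symbols, invalid)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]
        self.k = k
        self.n_symbols = n_symbols
        self.invalid = tuple(invalid)

    def seeds(self, qarr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All exact seed matches of the query against the index as
        (query_pos, subject_pos) arrays."""
        qcodes, qpos = _kmer_codes(qarr, self.k, self.n_symbols, self.invalid)
        if qcodes.size == 0 or self.codes.size == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z
        left = np.searchsorted(self.codes, qcodes, "left")
        right = np.searchsorted(self.codes, qcodes, "right")
        counts = right - left
        total = int(counts.sum())
        if total == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z
        qout = np.repeat(qpos, counts)
        grp_start = np.repeat(np.cumsum(counts) - counts, counts)
        offs = np.arange(total) - grp_start + np.repeat(left, counts)
        sout = self.pos[offs]
        return qout, sout


def _build_protein_score_matrix(name: str) -> np.ndarray:
    sub = substitution_matrices.load(name)
    size = len(PROTEIN_ALPHABET)
    mat = np.full((size, size), -4.0)
    alpha = sub.alphabet
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            if a in alpha and b in alpha:
                mat[i, j] = sub[a, b]
    return mat


_SCORE_MATRICES: dict[str, np.ndarray] = {}


def _protein_scores(name: str) -> np.ndarray:
    if name not in _SCORE_MATRICES:
        _SCORE_MATRICES[name] = _build_protein_score_matrix(name)
    return _SCORE_MATRICES[name]


# ---------------------------------------------------------------------------
# HSP extension and chaining
# ---------------------------------------------------------------------------


@dataclass
class _Hsp:
    qstart: int  # 0-based
    qend: int  # exclusive
    sstart: int
    send: int
    score: float
    matches: int
    mismatches: int
    gap_opens: int = 0
    gap_cols: int = 0

    @property
    def length(self) -> int:
        return self.qend - self.qstart + self.gap_cols


_XDROP_CHUNK = 512


def _xdrop_scan(colfn, limit: int, xdrop: float) -> tuple[int, float]:
    """Best X-drop-terminated prefix along one direction.

    ``colfn(start, stop)`` lazily yields per-column scores for that window;
    scanning proceeds in chunks so extensions through random sequence
    terminate after one block instead of touching the whole diagonal.
    Returns (#columns kept, their summed score)."""
    best_len, best_score = 0, 0.0
    carry = 0.0  # cumulative score entering the chunk
    carry_max = 0.0  # running maximum so far
    for off in range(0, limit, _XDROP_CHUNK):
        cs = carry + np.cumsum(colfn(off, min(off + _XDROP_CHUNK, limit)))
        runmax = np.maximum.accumulate(np.maximum(cs, carry_max))
        bad = np.nonzero(runmax - cs > xdrop)[0]
        end = int(bad[0]) if bad.size else cs.size
        if end:
            i = int(np.argmax(cs[:end]))
            if cs[i] > best_score:
                best_score = float(cs[i])
                best_len = off + i + 1
        if bad.size:
            return best_len, best_score
        carry = float(cs[-1])
        carry_max = float(runmax[-1])
    return best_len, best_score


def _extend_seed_nt(qarr, sarr, q0, s0, k, params) -> _Hsp:
    m, mm = float(params.match), float(params.mismatch)

    def col_right(a, b):
        qa = qarr[q0 + k + a : q0 + k + b]
        sa = sarr[s0 + k + a : s0 + k + b]
        return np.where((qa == sa) & (qa != 4), m, -mm)

    def col_left(a, b):
        qa = qarr[q0 - b : q0 - a][::-1]
        sa = sarr[s0 - b : s0 - a][::-1]
        return np.where((qa == sa) & (qa != 4), m, -mm)

    lim_r = min(qarr.size - (q0 + k), sarr.size - (s0 + k))
    lim_l = min(q0, s0)
    right_len, right_score = _xdrop_scan(col_right, lim_r, params.xdrop)
    left_len, left_score = _xdrop_scan(col_left, lim_l, params.xdrop)
    qa_r = qarr[q0 + k : q0 + k + right_len]
    sa_r = sarr[s0 + k : s0 + k + right_len]
    qa_l = qarr[q0 - left_len : q0]
    sa_l = sarr[s0 - left_len : s0]
    matches = (
        k
        + int(np.count_nonzero((qa_r == sa_r) & (qa_r != 4)))
        + int(np.count_nonzero((qa_l == sa_l) & (qa_l != 4)))
    )
    length = k + right_len + left_len
    return _Hsp(
        qstart=q0 - left_len,
        qend=q0 + k + right_len,
        sstart=s0 - left_len,
        send=s0 + k + right_len,
        score=m * k + right_score + left_score,
        matches=matches,
        mismatches=length - matches,
    )


def _extend_seed_prot(qarr, sarr, q0, s0, k, scores, xdrop) -> _Hsp:
    seed_score = float(scores[qarr[q0 : q0 + k], sarr[s0 : s0 + k]].sum())

    def col_right(a, b):
        return scores[qarr[q0 + k + a : q0 + k + b], sarr[s0 + k + a : s0 + k + b]]

    def col_left(a, b):
        return scores[qarr[q0 - b : q0 - a][::-1], sarr[s0 - b : s0 - a][::-1]]

    lim_r = min(qarr.size - (q0 + k), sarr.size - (s0 + k))
    lim_l = min(q0, s0)
    right_len, right_score = _xdrop_scan(col_right, lim_r, xdrop)
    left_len, left_score = _xdrop_scan(col_left, lim_l, xdrop)
    matches = (
        int(np.count_nonzero(qarr[q0 : q0 + k] == sarr[s0 : s0 + k]))
        + int(
            np.count_nonzero(
                qarr[q0 + k : q0 + k + right_len] == sarr[s0 + k : s0 + k + right_len]
            )
        )
        + int(np.count_nonzero(qarr[q0 - left_len : q0] == sarr[s0 - left_len : s0]))
    )
    length = k + right_len + left_len
    return _Hsp(
        qstart=q0 - left_len,
        qend=q0 + k + right_len,
        sstart=s0 - left_len,
        send=s0 + k + right_len,
        score=seed_score + right_score + left_score,
        matches=matches,
        mismatches=length - matches,
    )


def _collect_hsps(seeds_q, seeds_s, extend, two_hit_window: int | None = None) -> list[_Hsp]:
    """Extend seeds, one extension per uncovered seed per diagonal.

    With ``two_hit_window`` set, an extension is only triggered by a second
    seed on the same diagonal within that many positions of the previous one
    (the classic two-hit heuristic); isolated random seeds are skipped."""
    if seeds_q.size == 0:
        return []
    diag = seeds_q - seeds_s
    order = np.lexsort((seeds_q, diag))
    hsps: list[_Hsp] = []
    cur_diag = None
    covered_to = -1
    prev_q = None
    for idx in order:
        d = diag[idx]
        q = seeds_q[idx]
        if d != cur_diag:
            cur_diag = d
            covered_to = -1
            prev_q = None
        if q < covered_to:
            prev_q = q
            continue
        if two_hit_window is not None and (prev_q is None or q - prev_q > two_hit_window):
            prev_q = q
            continue
        hsp = extend(int(q), int(seeds_s[idx]))
        covered_to = hsp.qend
        prev_q = q
        if hsp.score > 0:
            hsps.append(hsp)
    return hsps


def _chain_hsps(hsps: list[_Hsp], params: AlignerParams) -> list[_Hsp]:
    """Greedy colinear chaining of HSPs into gapped alignments.

    HSPs separated by small, consistent gaps on both sequences are merged,
    paying affine gap costs for the larger offset difference; everything else
    is left as-is."""
    if len(hsps) <= 1:
        return hsps
    hsps = sorted(hsps, key=lambda h: (h.qstart, h.sstart))
    out: list[_Hsp] = []
    cur = hsps[0]
    for nxt in hsps[1:]:
        qgap = nxt.qstart - cur.qend
        sgap = nxt.sstart - cur.send
        if 0 <= qgap <= params.max_chain_gap and 0 <= sgap <= params.max_chain_gap:
            gap_diff = abs(qgap - sgap)
            bridge = min(qgap, sgap)
            gap_cost = (params.gap_open + params.gap_extend * gap_diff) if gap_diff else 0.0
            # bases between the HSPs on both sequences count as mismatch columns
            bridge_cost = params.mismatch * bridge
            merged_score = cur.score + nxt.score - gap_cost - bridge_cost
            if merged_score > max(cur.score, nxt.score):
                cur = _Hsp(
                    qstart=cur.qstart,
                    qend=nxt.qend,
                    sstart=cur.sstart,
                    send=nxt.send,
                    score=merged_score,
                    matches=cur.matches + nxt.matches,
                    mismatches=cur.mismatches + nxt.mismatches + bridge,
                    gap_opens=cur.gap_opens + nxt.gap_opens + (1 if gap_diff else 0),
                    gap_cols=cur.gap_cols + nxt.gap_cols + gap_diff,
                )
                continue
        out.append(cur)
        cur = nxt
    out.append(cur)
    return out


def _drop_contained(hsps: list[_Hsp]) -> list[_Hsp]:
    hsps = sorted(hsps, key=lambda h: (-h.score, h.qstart, h.sstart))
    kept: list[_Hsp] = []
    for h in hsps:
        redundant = any(
            h.qstart >= k.qstart and h.qend <= k.qend and h.sstart >= k.sstart and h.send <= k.send
            for k in kept
        )
        if not redundant:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# public aligner entry points
# ---------------------------------------------------------------------------


def _hsp_to_hit(
    hsp: _Hsp,
    query_id: str,
    subject_id: str,
    strand: str,
    subject_len: int,
    mode: str,
    expectation: float,
) -> AlignmentHit:
    if strand == "+" or mode == "translated":
        s_interval = (hsp.sstart + 1, hsp.send)
    else:
        # coords were computed on the reverse complement; map back
        s_interval = (subject_len - hsp.send + 1, subject_len - hsp.sstart)
    length = hsp.length
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        query_interval=(hsp.qstart + 1, hsp.qend),
        subject_interval=s_interval,
        percent_identity=100.0 * hsp.matches / length,
        alignment_length=length,
        score=hsp.score,
        expectation=expectation,
        subject_strand=strand,
        mode=mode,
        matches=hsp.matches,
        mismatches=hsp.mismatches,
        gap_opens=hsp.gap_opens,
    )


def _passes(hit: AlignmentHit, params: AlignerParams) -> bool:
    return (
        hit.percent_identity >= params.min_identity
        and hit.alignment_length >= max(params.min_alignment_length, 0)
        and hit.expectation <= params.max_expectation
    )


def _sort_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    hits.sort(
        key=lambda h: (
            -h.score,
            h.query_interval,
            h.subject_interval,
            h.subject_strand,
        )
    )
    return hits


def align(
    query: NucleotideSequence,
    subject: NucleotideSequence,
    params: AlignerParams | None = None,
) -> list[AlignmentHit]:
    """Nucleotide local alignment of query vs subject over both strands.

    Deterministic: hits are deduplicated and sorted by score descending with a
    positional tie-break.
    """
    if params is None:
        params = AlignerParams.nucleotide()
    qarr = _encode_nt(query.residues)
    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        sres = subject.residues if strand == "+" else reverse_complement(subject.residues)
        sarr = _encode_nt(sres)
        index = _SortedKmerIndex(sarr, params.seed_length, 4, invalid=(4,))
        sq, ss = index.seeds(qarr)
        hsps = _collect_hsps(
            sq, ss, lambda q, s: _extend_seed_nt(qarr, sarr, q, s, params.seed_length, params)
        )
        hsps = _drop_contained(_chain_hsps(hsps, params))
        for hsp in hsps:
            e = expectation_value(hsp.score, len(query), len(subject), params, "nucleotide")
            hit = _hsp_to_hit(hsp, query.id, subject.id, strand, len(subject), "nucleotide", e)
            if _passes(hit, params):
                hits.append(hit)
    return _sort_hits(hits)


def _six_frames(seq: NucleotideSequence) -> list[tuple[int, int, str]]:
    """(frame, nt_offset, protein) for all six frames; frame in {±1,±2,±3}."""
    out = []
    fwd = seq.residues
    rev = reverse_complement(fwd)
    for off in (0, 1, 2):
        for strand, s in ((1, fwd), (-1, rev)):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if len(sub) < 3:
                continue
            prot = str(Seq(sub).translate(table=11))
            out.append((strand * (off + 1), off, prot))
    return out


@lru_cache(maxsize=128)
def _frame_arrays(residues: str) -> tuple[tuple[int, int, np.ndarray], ...]:
    """Encoded six-frame translations, cached per genome so all-vs-all runs
    translate each sequence once."""
    frames = _six_frames(NucleotideSequence("x", residues))
    return tuple((f, off, _encode_aa(p)) for f, off, p in frames)


@lru_cache(maxsize=128)
def _frame_indexes(residues: str, seed_length: int) -> tuple[tuple[int, int, np.ndarray, "_SortedKmerIndex"], ...]:
    stop_code = PROTEIN_ALPHABET.index("*")
    x_code = PROTEIN_ALPHABET.index("X")
    return tuple(
        (f, off, arr, _SortedKmerIndex(arr, seed_length, len(PROTEIN_ALPHABET), (stop_code, x_code)))
        for f, off, arr in _frame_arrays(residues)
    )


def _frame_nt_interval(frame: int, off: int, aa_start: int, aa_end: int, n: int) -> tuple[int, int]:
    """Map an aa interval [aa_start, aa_end) in a frame to 1-based forward
    nucleotide coordinates on the source sequence."""
    nt_start = off + 3 * aa_start  # 0-based on the frame's strand
    nt_end = off + 3 * aa_end  # exclusive
    if frame > 0:
        return (nt_start + 1, nt_end)
    # reverse strand: position p on revcomp maps to n-1-p forward
    return (n - nt_end + 1, n - nt_start)


def translated_align(
    a: NucleotideSequence,
    b: NucleotideSequence,
    params: AlignerParams | None = None,
) -> list[AlignmentHit]:
    """Translated (six-frame vs six-frame) local alignment, tblastx-style.

    Alignment lengths and scores are protein-level; emitted intervals are
    nucleotide coordinates on the forward strands of ``a`` and ``b``.  Hits
    are filtered at ``params.max_expectation`` (default 1e-3).
    """
    if len(a) < 3 or len(b) < 3:
        raise ValueError("translated alignment needs sequences >= 3 bp")
    if params is None:
        params = AlignerParams.translated()
    scores = _protein_scores(params.matrix)
    a_frames = _frame_arrays(a.residues)
    b_frames = _frame_indexes(b.residues, params.seed_length)
    m_aa = max(len(a) // 3, 1)
    n_aa = max(len(b) // 3, 1)
    hits: list[AlignmentHit] = []
    for fb, offb, barr, index in b_frames:
        for fa, offa, aarr in a_frames:
            sq, ss = index.seeds(aarr)
            hsps = _collect_hsps(
                sq,
                ss,
                lambda q, s, _a=aarr, _b=barr: _extend_seed_prot(
                    _a, _b, q, s, params.seed_length, scores, params.xdrop
                ),
                two_hit_window=params.two_hit_window,
            )
            hsps = _drop_contained(hsps)
            for hsp in hsps:
                e = expectation_value(hsp.score, m_aa, n_aa, params, "translated")
                qi = _frame_nt_interval(fa, offa, hsp.qstart, hsp.qend, len(a))
                si = _frame_nt_interval(fb, offb, hsp.sstart, hsp.send, len(b))
                hit = AlignmentHit(
                    query_id=a.id,
                    subject_id=b.id,
                    query_interval=qi,
                    subject_interval=si,
                    percent_identity=100.0 * hsp.matches / hsp.length,
                    alignment_length=hsp.length,
                    score=hsp.score,
                    expectation=e,
                    subject_strand="+" if fb > 0 else "-",
                    mode="translated",
                    matches=hsp.matches,
                    mismatches=hsp.mismatches,
                )
                if _passes(hit, params):
                    hits.append(hit)
    return _sort_hits(hits)


# ---------------------------------------------------------------------------
# reusable reference index for read recruitment
# ---------------------------------------------------------------------------


class ReadBatch:
    """Vectorized k-mer codes for a set of short reads (grouped by length),
    computed once and reused against every reference index in a sample."""

    def __init__(self, seqs: Sequence[str], k: int):
        self.seqs = list(seqs)
        self.k = k
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(self.seqs):
            by_len.setdefault(len(s), []).append(i)
        self.groups: list[tuple[np.ndarray, np.ndarray, int, np.ndarray, np.ndarray]] = []
        for length in sorted(by_len):
            if length < k:
                continue  # unalignable reads stay None
            idxs = np.array(by_len[length])
            mat = np.vstack([_encode_nt(self.seqs[i]) for i in idxs])
            m = length - k + 1
            codes = np.zeros((idxs.size, m), dtype=np.int64)
            a = mat.astype(np.int64)
            for t in range(k):
                codes = codes * 4 + a[:, t : t + m]
            isn = np.cumsum(mat == 4, axis=1)
            isn = np.concatenate([np.zeros((idxs.size, 1), dtype=isn.dtype), isn], axis=1)
            codes[(isn[:, k:] - isn[:, :-k]) > 0] = -1  # N-containing windows
            # flat codes sorted once; every reference then searches its own
            # (much smaller) k-mer set against this array
            flat = codes.ravel()
            order = np.argsort(flat, kind="stable")
            self.groups.append((idxs, mat, m, flat[order], order.astype(np.int64)))


class ReferenceIndex:
    """Prebuilt two-strand k-mer index of one reference, for aligning many
    short queries (fragment recruitment) without rebuilding per query."""

    def __init__(self, reference: NucleotideSequence, params: AlignerParams | None = None):
        self.params = params or AlignerParams.nucleotide()
        self.reference = reference
        self.fwd_arr = _encode_nt(reference.residues)
        self.rev_arr = _encode_nt(reverse_complement(reference.residues))
        k = self.params.seed_length
        self.fwd = _SortedKmerIndex(self.fwd_arr, k, 4, invalid=(4,))
        self.rev = _SortedKmerIndex(self.rev_arr, k, 4, invalid=(4,))

    def best_hit(self, read: str) -> AlignmentHit | None:
        """Best-scoring local alignment of one read against the reference, or
        None when nothing passes the thresholds."""
        params = self.params
        qarr = _encode_nt(read)
        best: AlignmentHit | None = None
        n = len(self.reference)
        for strand, sarr, index in (("+", self.fwd_arr, self.fwd), ("-", self.rev_arr, self.rev)):
            sq, ss = index.seeds(qarr)
            hsps = _collect_hsps(
                sq,
                ss,
                lambda q, s, _s=sarr: _extend_seed_nt(qarr, _s, q, s, params.seed_length, params),
            )
            hsps = _drop_contained(_chain_hsps(hsps, params))
            for hsp in hsps:
                e = expectation_value(hsp.score, len(read), n, params, "nucleotide")
                hit = _hsp_to_hit(hsp, "read", self.reference.id, strand, n, "nucleotide", e)
                if not _passes(hit, params):
                    continue
                if best is None or hit.score > best.score:
                    best = hit
        return best

    def best_hits_batch(self, batch: ReadBatch) -> list[AlignmentHit | None]:
        """Best passing hit per read for a whole batch (None where nothing
        passes).  Seed lookup is vectorized across all reads; only reads with
        at least one seed are extended."""
        params = self.params
        k = params.seed_length
        if batch.k != k:
            raise ValueError("batch seed length does not match index params")
        n = len(self.reference)
        results: list[AlignmentHit | None] = [None] * len(batch.seqs)
        for idxs, mat, m, sorted_flat, order in batch.groups:
            for strand, sarr, index in (
                ("+", self.fwd_arr, self.fwd),
                ("-", self.rev_arr, self.rev),
            ):
                if index.codes.size == 0:
                    continue
                # search the reference k-mers against the (larger) read set
                lo = np.searchsorted(sorted_flat, index.codes, "left")
                hi = np.searchsorted(sorted_flat, index.codes, "right")
                cnt = hi - lo
                nz = np.nonzero(cnt)[0]
                if nz.size == 0:
                    continue
                total = int(cnt[nz].sum())
                spos_all = np.repeat(index.pos[nz], cnt[nz])
                offs = (
                    np.arange(total)
                    - np.repeat(np.cumsum(cnt[nz]) - cnt[nz], cnt[nz])
                    + np.repeat(lo[nz], cnt[nz])
                )
                flatw = order[offs]
                read_rows = flatw // m
                qpos_all = flatw % m
                by_read = np.argsort(read_rows, kind="stable")
                read_rows = read_rows[by_read]
                qpos_all = qpos_all[by_read]
                spos_all = spos_all[by_read]
                splits = np.nonzero(np.diff(read_rows))[0] + 1
                starts = np.concatenate(([0], splits))
                ends = np.concatenate((splits, [read_rows.size]))
                for a, b in zip(starts, ends):
                    r = int(read_rows[a])
                    qarr = mat[r]
                    hsps = _collect_hsps(
                        qpos_all[a:b],
                        spos_all[a:b],
                        lambda q, s, _q=qarr, _s=sarr: _extend_seed_nt(_q, _s, q, s, k, params),
                    )
                    hsps = _drop_contained(_chain_hsps(hsps, params))
                    for hsp in hsps:
                        e = expectation_value(hsp.score, qarr.size, n, params, "nucleotide")
                        hit = _hsp_to_hit(
                            hsp, "read", self.reference.id, strand, n, "nucleotide", e
                        )
                        if not _passes(hit, params):
                            continue
                        ridx = int(idxs[r])
                        if results[ridx] is None or hit.score > results[ridx].score:
                            results[ridx] = hit
        return results
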