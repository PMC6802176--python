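"""Complete-phage discovery: circular contigs become phage genome candidates.

An assembled contig derived from a circular genome carries the assembler's
overlap signature — a direct terminal repeat, the start of the sequence
duplicated at its end.  Detection anchors the contig's leading bases at
candidate end positions and extends the comparison with a small mismatch
allowance; the trailing repeat copy is trimmed so each base is counted once.
Candidates longer than 10 kb (strict) are kept and classified by size:
miniphage below 15 kb, megaphage above 200 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import NucleotideSequence, ProteinSequence, find_orfs, gc_content

MINIPHAGE_MAX_BP = 15_000  # strictly below => miniphage
MEGAPHAGE_MIN_BP = 200_000  # strictly above => megaphage
MIN_CANDIDATE_BP = 10_000  # strictly above => candidate

_ANCHOR_LEN = 16


@dataclass(frozen=True)
class CircularityResult:
    is_circular: bool
    overlap_len: int = 0
    trimmed: NucleotideSequence | None = None


@dataclass
class PhageGenome:
    """A candidate complete phage genome (origin-trimmed, circular)."""

    sequence: NucleotideSequence
    gc: float
    size_class: str
    orfs: list[ProteinSequence] = field(default_factory=list)
    source_sample: str = ""

    def __post_init__(self):
        if self.sequence.topology != "circular":
            raise ValueError(f"{self.id}: phage genome must be circular")
        if self.length_bp <= MIN_CANDIDATE_BP:
            raise ValueError(f"{self.id}: {self.length_bp} bp below candidate length")
        if self.size_class != classify_size(self.length_bp):
            raise ValueError(f"{self.id}: inconsistent size class")

    @property
    def id(self) -> str:
        return self.sequence.id

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


def classify_size(length_bp: int) -> str:
    """Size class: miniphage < 15 kb, megaphage > 200 kb, else regular."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if length_bp < MINIPHAGE_MAX_BP:
        return "miniphage"
    if length_bp > MEGAPHAGE_MIN_BP:
        return "megaphage"
    return "regular"


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_circularity(
    contig: NucleotideSequence,
    min_overlap_bp: int = 20,
    max_mismatch_per_100bp: float = 1.0,
) -> CircularityResult:
    """Terminal direct-repeat test for circularity.

    The contig is circular iff a prefix of length L >= ``min_overlap_bp``
    recurs at the very end of the contig, allowing at most one mismatch per
    100 bp of repeat.  Candidate end positions are located by exact matching
    of the leading 16 bp (or ``min_overlap_bp`` if smaller); the longest
    passing repeat wins.  The trimmed sequence drops the trailing copy and is
    marked circular.
    """
    n = len(contig)
    if n <= min_overlap_bp:
        raise ValueError("contig shorter than the overlap threshold")
    res = contig.residues
    anchor = res[: min(_ANCHOR_LEN, min_overlap_bp)]
    max_repeat = n // 2  # a repeat copy cannot exceed half the contig
    search_from = n - max_repeat
    best: tuple[int, int] | None = None  # (overlap_len, start_of_trailing_copy)
    pos = res.find(anchor, max(search_from, 1))
    while pos != -1:
        overlap = n - pos
        if overlap >= min_overlap_bp:
            allowed = int(overlap * max_mismatch_per_100bp // 100)
            if _mismatches(res[:overlap], res[pos:]) <= allowed:
                if best is None or overlap > best[0]:
                    best = (overlap, pos)
        pos = res.find(anchor, pos + 1)
    if best is None:
        return CircularityResult(False)
    overlap, pos = best
    trimmed = NucleotideSequence(contig.id, res[:pos], topology="circular")
    return CircularityResult(True, overlap_len=overlap, trimmed=trimmed)


def select_phage_candidates(
    contigs: list[NucleotideSequence],
    min_length_bp: int = MIN_CANDIDATE_BP,
    min_overlap_bp: int = 20,
    min_orf_length_aa: int = 30,
    keep_ids: set[str] | None = None,
    call_orfs: bool = True,
) -> list[PhageGenome]:
    """Select circular contigs with trimmed length strictly above
    ``min_length_bp`` as complete phage genome candidates.

    ``keep_ids`` optionally emulates an external phage-confirmation filter
    (only listed contigs are retained).  Output is stable: descending trimmed
    length, then id.
    """
    genomes: list[PhageGenome] = []
    for contig in contigs:
        if keep_ids is not None and contig.id not in keep_ids:
            continue
        if len(contig) <= min_overlap_bp:
            continue
        result = detect_circularity(contig, min_overlap_bp=min_overlap_bp)
        if not result.is_circular:
            continue
        trimmed = result.trimmed
        if len(trimmed) <= min_length_bp:
            continue
        genomes.append(
            PhageGenome(
                sequence=trimmed,
                gc=gc_content(trimmed),
                size_class=classify_size(len(trimmed)),
                orfs=find_orfs(trimmed, min_orf_length_aa) if call_orfs else [],
            )
        )
    genomes.sort(key=lambda g: (-g.length_bp, g.id))
    return genomes


def genome_manifest_rows(genomes: list[PhageGenome], raw_lengths: dict[str, int] | None = None):
    """Rows for the discovery TSV manifest."""
    rows = []
    for g in genomes:
        raw = raw_lengths.get(g.id, g.length_bp) if raw_lengths else g.length_bp
        rows.append(
            {
                "id": g.id,
                "raw_len": raw,
                "trimmed_len": g.length_bp,
                "overlap_len": raw - g.length_bp,
                "gc": round(g.gc, 4),
                "size_class": g.size_class,
                "n_orfs": len(g.orfs),
            }
        )
    return rows
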