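# Methods

This note documents the models and procedures implemented in `lakephage`,
the parameter choices that matter, what the synthetic data generator does and
does not emulate, and the package's known limitations.

## Sequence primitives (`seqcore`)

**Aligner.** All nucleotide comparisons run through one seed-and-extend
local aligner: exact k-mer seeding (word size 13 nt), ungapped X-drop
extension along each seeded diagonal (match +1, mismatch −2, X = 50), and
colinear chaining of the resulting segments with affine gap costs
(open 5, extend 2; gaps only arise between chained segments). The translated
mode compares all six reading frames of both sequences at the protein level
(word size 4 aa, BLOSUM45, X-drop 40) with classic two-hit gating — an
extension is triggered only by two seeds on one diagonal within 40
positions — which suppresses the large population of single random 4-mer
matches. Every downstream threshold in the pipeline sits at ≥ 95–97%
nucleotide identity or at strong protein similarity, where exact seeding at
these word sizes is essentially lossless: a 30 bp window at 97% identity
always contains an exact 13-mer (worst-case mismatch placement leaves a
14 bp run). Because the read/substitution model used throughout is
substitution-only, within-segment gapped dynamic programming would not
change any reported quantity; chained segments still account for small
indels in real data.

**Expectation values.** Karlin–Altschul E = K·m·n·e^(−λS) with fixed,
documented ungapped constants per scoring scheme (+1/−2: λ = 1.28,
K = 0.46; BLOSUM45: λ = 0.2291, K = 0.0924; BLOSUM62: λ = 0.3176,
K = 0.134). All uses are threshold comparisons (10⁻³, 10⁻⁵) at generous
margins; calibration-grade accuracy is neither needed nor claimed. E-values
are strictly decreasing in score and linear in the m·n search space.

**ORF caller.** A deliberately simple six-frame scanner stands in for a
dedicated gene predictor: translation table 11, start codons
ATG/GTG/TTG (initiator always reported as M), maximal ORFs from the first
start after the previous in-frame stop, minimum 30 aa. On circular genomes
the scan runs over the doubled sequence so ORFs may span the origin (capped
at one full circle). This is adequate for synthetic data whose coding
content is planted; it makes no claim to the accuracy of a trained
metagenomic gene finder on real genomes.

**Coordinates.** 0-based half-open internally; every emitted record is
1-based inclusive, matching the common 12-column alignment-report dialect.
Subject strand is recorded on the hit; the query is always +.

## Discovery (`discovery`)

A contig assembled from a circular template carries a direct terminal
repeat. Detection anchors the contig's first 16 bp at candidate positions in
the trailing half, extends the prefix/suffix comparison, and accepts a
repeat of ≥ 20 bp with at most one mismatch per 100 bp; the longest passing
repeat wins and its trailing copy is trimmed so each base is counted once.
The anchor is exact, so a repeat whose leading 16 bp are themselves mutated
would be missed — a sensitivity limit we accept because assembler-produced
repeats are near-exact copies. Candidates must be strictly longer than
10,000 bp after trimming ("longer than 10 kb" is read strictly: a 10,000 bp
genome is excluded). Size classes: miniphage < 15 kb, megaphage > 200 kb.
An optional keep-list hook emulates an external phage-confirmation filter;
on synthetic data provenance is known, so no confirmation step is built in.

## Dereplication (`derep`)

Hits are filtered at expectation < 10⁻³ and identity > 95% (identity is
enforced per hit, since filtering precedes coverage computation); coverage
of each genome is the merged-interval union of its hit footprints, so
repeated hits are not double-counted and coverage cannot exceed 100%. Two
genomes are linked when both coverages are ≥ 0.95; clusters are connected
components (single linkage, computed with networkx); the representative is
the longest member, ties broken by lexicographically smallest id so outputs
are deterministic. A length prefilter skips pairs whose length ratio makes
mutual 95% coverage arithmetically impossible. Clustering is invariant to
input order and idempotent on the representative set.

## Proteomic tree (`prottree`)

The comparison score S(A,B) is the sum of the scores of *all* significant
translated hits (e ≤ 10⁻³), including off-diagonal paralogous self-hits in
S(A,A) — exactly what the summation rule implies. Distance is
1 − 2·S(A,B)/(S(A,A)+S(B,B)), clamped to [0, 1]; symmetry is by
construction (each unordered pair aligned once). The triangle inequality is
not claimed.

Neighbor joining is canonical (O(n³), Q-criterion, negative branch lengths
clamped to zero). Alternative topologies come from ε-tolerance randomized
tie-breaking (ε = 10⁻⁹·max d): at each step the join is drawn uniformly
among pairs whose Q lies within ε of the minimum, after a seeded random
permutation of the leaf order. This emulates the behavior of relaxed-NJ
tools that emit many equally valid topologies, without reimplementing one
verbatim. The default is 100 alternative topologies (configurable; large
published analyses use 10⁴ — the consensus support estimates here simply
have a coarser granularity of 0.01).

The consensus is strict-majority rule (> 50%): strict-majority bipartitions
are mutually compatible, so the retained clades form a laminar family and
assemble directly into a tree. Support is the fraction of input trees
containing the bipartition; internal branch lengths average over those
trees, terminal branch lengths over all trees.

## Host prediction (`hostlink`)

Four channels, in decreasing order of precedence:

| channel | cutoffs | resolution |
|---|---|---|
| CRISPR spacer | ≥ 30 bp, ≥ 97% id, ≥ 97% spacer coverage, e ≤ 10⁻⁵ | strain |
| tRNA/attB | same per-hit cutoffs + ≥ 20 bp overlap with an annotated tRNA locus | strain |
| shared sequence | ≥ 30 bp, ≥ 97% id, e ≤ 10⁻⁵ | strain |
| marker gene | ≥ 30% id over ≥ 70% of the marker, e ≤ 10⁻⁵ | phylum |

The query-coverage requirement applies to the spacer channel (the spacer is
the query); for the whole-genome shared-sequence comparison a query-coverage
requirement would contradict its purpose (a prophage-sized region inside a
longer phage), so evidence there is per-hit. A hit already explained as an
attB match is not double-reported as shared sequence.

CRISPR arrays are found CRT-style: an exact 16-mer recurring at spacings
compatible with repeat-plus-spacer seeds a candidate; repeat boundaries are
extended across all copies while every copy stays within one mismatch of the
column consensus, then non-unanimous boundary columns are trimmed (the
tolerance otherwise lets boundaries creep into the random spacers). Arrays
need ≥ 3 repeats of 23–47 bp separated by spacers of 26–50 bp — standard
CRT-family bounds, since only the tool, not its parameters, is specified for
this step. tRNA loci are consumed from annotations (GFF3/BED), not detected
de novo.

Marker detection aligns phage ORFs against labelled marker proteins with a
substitution-matrix local aligner (Biopython's PairwiseAligner, BLOSUM62,
−11/−1): at a 30% identity floor, seed-and-extend word matching is
unreliable and full local DP is the right tool. Multi-copy markers yield
one evidence record per copy.

Integration: within the highest-precedence non-empty channel the host with
the most evidence records is assigned; an exact tie yields *ambiguous*, no
evidence *unassigned*. The precedence order (spacer > attB > shared >
marker) reflects decreasing specificity of the evidence and is
configurable in spirit — it is a plain argument-free pure function of the
evidence multiset, so callers can re-rank as they wish.

## Abundance (`abundance`)

"Coverage per gigabase" is mean per-base depth over unmasked positions
divided by sample size in Gb — the only reading that makes values
comparable across samples of different sizes. Breadth is the fraction of
unmasked positions covered at least once; presence requires breadth
strictly > 0.80. rRNA intervals (for microbial genomes) are masked to N
before recruitment and excluded from both numerator and denominator.
Read mates are recruited independently (no proper-pair constraint); a read
counts when its best hit exceeds 95% identity over ≥ 50 aligned bp. Across
genomes, each read counts only for its best-scoring genome; exact ties go
to the first-encountered genome with a logged warning (a count-all mode is
available). Microbial genomes are profiled from at most 20 million reads
(seeded uniform subsample without replacement); phage genomes use full read
sets.

Z-score normalization is per genome across samples with the population
standard deviation; constant rows map to zeros. Profile clustering is
average linkage on 1 − Spearman ρ (average ranks for ties; a constant
profile has undefined correlation and is treated as ρ = 0), computed with
scipy's hierarchical clustering; leaf order is deterministic (rows taken in
id order).

**Known limitation.** Under best-hit assignment with first-encountered tie
resolution, two near-identical genomes sharing a long *identical* segment
(e.g. replicate-group copies whose planted evidence region is protected
from mutation) compete for that segment's reads: the losing copy's breadth
is capped by the shared fraction and a genuinely abundant genome can fall
under the 80% presence threshold. This is a property of best-hit fragment
recruitment generally, not of this implementation; the count-all mode
avoids it at the cost of double counting.

## Synthetic communities (`synth`)

The generator's defaults define the study conditions; every constant is
configurable but the defaults are chosen once:

- **Phage genomes**: 20 per community, lengths from a two-mode log-normal
  mixture (weights 0.45/0.55, medians 14.5 kb and 40 kb, log-sd 0.05/0.30)
  truncated to [13,500, 446,000] bp — reproducing the bimodal freshwater
  length distribution with its miniphage peak and long megaphage tail —
  with per-genome GC drawn uniformly from [0.35, 0.60] (habitat-matched
  range). Contigs are emitted with a 127 bp terminal repeat.
- **Replicate groups**: sizes (3, 3, 2, 2) plus singletons; copies carry
  1% random substitutions (configurable 0–5%), sparing planted evidence
  intervals so links survive replication verbatim. Substitution-only is
  deliberate: every downstream stage is threshold-driven and indel realism
  would not change any decision boundary.
- **Hosts**: 5 genomes of 100 kb at GC 0.45 with a fixed non-overlapping
  feature layout (tRNA loci from 10 kb, a 5-repeat CRISPR array at 20 kb,
  prophage-like insertions from 30 kb), one taxon label each.
- **Planted links**: channels cycle spacer/attB/shared/marker across
  replicate-group founders, each tied to host i mod n_hosts; a spacer is a
  verbatim 32 bp phage substring placed in the host array, an attB site is
  the 3′ 45 bp of a host tRNA copied into the phage, a shared region is a
  5 kb phage substring copied into the host, a marker link plants the
  reverse-translated marker CDS of the host's taxon in the phage.
- **Reads**: paired 2 × 151 bp, fragments ~N(400, 50) drawn uniformly from
  the circular template (origin-spanning allowed), substitution errors at
  0.5%, constant quality. Three regimes drive per-sample depths over an
  8-sample season (4 epilimnion of which 2 are mixis, 3 hypolimnion):
  boom-bust peaks at 20× in 1–2 epilimnion samples (background 0.05×),
  persistence holds 8× across all hypolimnion samples (0.3× epilimnion),
  and mixis-shared peaks at 10× in both mixis samples. Replicate-group
  members share one profile so near-identical genomes co-vary.

Everything is generated from a single seeded RNG; regenerating with the
same spec yields byte-identical files.

What the generator does **not** emulate: assembly fragmentation and
chimerism, indels and quality-dependent errors, strain microdiversity
below the replicate-group level, compositional biases (real coding
statistics, codon usage, k-mer structure), and inter-host homology. Tests
passing on this data therefore validate the decision logic and arithmetic
of each stage at the stated thresholds, not robustness to assembly noise
or to divergent real-world homology structure.

## Problem sizes and determinism

The test suite and the acceptance script run the complete pipeline on the
default 20-phage / 5-host community with 8 samples (~10⁵ read pairs),
dereplicate a 50-genome / 12-group cohort against a brute-force oracle,
recover 100 seeded 8-taxon additive topologies, and score circularity on
100 planted plus 100 linear contigs — sizes chosen so a full run completes
in minutes on one CPU while every decision rule is exercised at its
boundary. All randomness flows from explicit seeds; reruns are bitwise
reproducible.
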