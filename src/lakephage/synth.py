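"""Synthetic freshwater viral community generator.

Produces every input the pipeline consumes — circular phage genomes emitted
as contigs with assembler-style terminal repeats, host genomes carrying
planted CRISPR arrays / tRNA loci / prophage-like shared regions, a marker
protein reference set, and multi-sample paired-read sets — together with a
machine-readable ground-truth ledger that fully determines the expected
pipeline outputs at saturating depth.

The defaults emulate the printed characteristics of deep freshwater
viromes: a bimodal genome-length distribution with modes near 15 kb and
40 kb truncated to 13.5-446 kb, habitat-matched GC%, repeated capture of
near-identical genomes (replicate groups for dereplication), 2 x 151 bp
paired reads, and three abundance regimes — epilimnion boom-bust, hypolimnion
persistence, and mixis-associated presence in both layers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .discovery import classify_size
from .io import write_fasta, write_fastq, write_gff3
from .seqcore import NucleotideSequence, ProteinSequence, gc_content, reverse_complement

READ_LENGTH = 151  # 2 x 151 bp paired-end chemistry

_CODON_FOR_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_TAXA = (
    "Actinobacteria",
    "Betaproteobacterales",
    "Alphaproteobacteria",
    "Bacteroidetes",
    "Chloroflexi",
)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class CommunitySpec:
    """Parameters of the synthetic community.

    ``replicate_groups`` lists the sizes of groups of near-identical genomes
    (mutated copies of one founder); remaining phages up to ``n_phages`` are
    singletons.  ``links`` optionally overrides the planted evidence channel
    per phage index; by default channels cycle spacer / attb / shared /
    marker across phages, each tied to host ``i % n_hosts``.
    """

    n_phages: int = 20
    n_hosts: int = 5
    seed: int = 0
    # bimodal length mixture: (weight, log-space median, log-sd) per mode
    length_modes: tuple = ((0.45, 14_500.0, 0.05), (0.55, 40_000.0, 0.30))
    length_bounds: tuple[int, int] = (13_500, 446_000)
    gc_range: tuple[float, float] = (0.35, 0.60)
    host_length_bp: int = 100_000
    host_gc: float = 0.45
    replicate_groups: tuple[int, ...] = (3, 3, 2, 2)
    mutation_rate: float = 0.01
    terminal_repeat_bp: int = 127
    links: dict | None = None
    channels: tuple[str, ...] = ("crispr_spacer", "trna_attb", "shared_sequence", "marker_gene")
    spacer_length_bp: int = 32
    crispr_repeat_bp: int = 30
    crispr_n_repeats: int = 5
    trna_length_bp: int = 76
    trna_per_host: int = 3
    attb_length_bp: int = 45
    shared_region_bp: int = 5_000
    marker_length_aa: int = 180
    taxa: tuple[str, ...] = DEFAULT_TAXA

    def __post_init__(self):
        if not 0.0 <= self.mutation_rate <= 0.05:
            raise ValueError("mutation_rate must be in [0, 0.05]")
        if sum(self.replicate_groups) > self.n_phages:
            raise ValueError("replicate groups exceed n_phages")
        if self.spacer_length_bp >= self.length_bounds[0]:
            raise ValueError("spacer longer than the shortest possible phage")


@dataclass
class SampleSpec:
    id: str
    date: str
    depth_label: str  # epi | hypo
    temperature: float
    mixis: bool = False


def default_time_series() -> list[SampleSpec]:
    """A stratification/mixis cycle: two mixis samples bracket a stratified
    season with epilimnion and hypolimnion sampling."""
    return [
        SampleSpec("M1_epi", "2016-04-05", "epi", 5.0, mixis=True),
        SampleSpec("E1", "2016-06-14", "epi", 18.0),
        SampleSpec("E2", "2016-08-09", "epi", 24.0),
        SampleSpec("E3", "2016-10-04", "epi", 12.0),
        SampleSpec("H1", "2016-06-14", "hypo", 5.5),
        SampleSpec("H2", "2016-08-09", "hypo", 6.0),
        SampleSpec("H3", "2016-10-04", "hypo", 5.0),
        SampleSpec("M2_epi", "2016-12-06", "epi", 4.0, mixis=True),
    ]


@dataclass
class TimeSeriesSpec:
    samples: list[SampleSpec] = field(default_factory=default_time_series)
    read_length: int = READ_LENGTH
    error_rate: float = 0.005
    fragment_mean_bp: int = 400
    fragment_sd_bp: int = 50
    seed: int = 0
    # regime -> (depth at peak samples, background depth)
    boom_bust_depth: tuple[float, float] = (20.0, 0.05)
    persistent_depth: tuple[float, float] = (8.0, 0.3)
    mixis_depth: tuple[float, float] = (10.0, 0.05)


# ---------------------------------------------------------------------------
# ground truth ledger
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthLedger:
    genomes: list[dict] = field(default_factory=list)
    links: list[dict] = field(default_factory=list)
    hosts: list[dict] = field(default_factory=list)
    samples: list[dict] = field(default_factory=list)
    expected_depth: dict = field(default_factory=dict)  # genome -> sample -> depth

    def replicate_partition(self) -> list[set[str]]:
        groups: dict[str, set[str]] = {}
        for g in self.genomes:
            groups.setdefault(g["replicate_group"], set()).add(g["id"])
        return sorted(groups.values(), key=lambda s: sorted(s)[0])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruthLedger":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(
        np.array(list(_AA_LETTERS))[rng.integers(0, len(_AA_LETTERS), size=length - 1)]
    )


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON_FOR_AA[a] for a in protein) + "TAA"


def _draw_length(rng: np.random.Generator, spec: CommunitySpec) -> int:
    weights = np.array([m[0] for m in spec.length_modes])
    weights = weights / weights.sum()
    while True:
        _w, median, sigma = spec.length_modes[rng.choice(len(weights), p=weights)]
        length = int(np.exp(rng.normal(np.log(median), sigma)))
        lo, hi = spec.length_bounds
        if lo <= length <= hi:
            return length


def _mutate(rng: np.random.Generator, residues: str, rate: float, protected) -> str:
    """Substitution-only mutation sparing protected 1-based intervals (planted
    evidence must survive replication verbatim)."""
    arr = np.array(list(residues))
    n = arr.size
    allowed = np.ones(n, dtype=bool)
    for start, end in protected:
        allowed[start - 1 : end] = False
    draws = rng.random(n) < rate
    sites = np.nonzero(draws & allowed)[0]
    bases = np.array(list("ACGT"))
    for i in sites:
        choices = [b for b in bases if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


@dataclass
class PlantedPhage:
    id: str
    residues: str  # trimmed (one origin copy)
    gc: float
    replicate_group: str
    founder: bool
    protected: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Community:
    spec: CommunitySpec
    contigs: list[NucleotideSequence]  # phage genomes + terminal repeat copy
    phages: list[NucleotideSequence]  # ground-truth trimmed genomes
    hosts: list[NucleotideSequence]
    markers: list[ProteinSequence]
    trna_loci: dict[str, list[tuple[int, int]]]
    host_taxa: dict[str, str]
    ledger: GroundTruthLedger

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "contigs.fasta", self.contigs)
        write_fasta(outdir / "phages_truth.fasta", self.phages)
        write_fasta(outdir / "hosts.fasta", self.hosts)
        write_fasta(outdir / "markers.faa", self.markers)
        features = []
        for host_id in sorted(self.trna_loci):
            for i, (start, end) in enumerate(self.trna_loci[host_id], 1):
                features.append((host_id, "tRNA", start, end, "+", f"ID=trna_{host_id}_{i}"))
        write_gff3(outdir / "host_annotations.gff3", features)
        self.ledger.to_json(outdir / "ground_truth.json")


def generate_community(spec: CommunitySpec | None = None) -> Community:
    """Deterministically build the synthetic community for ``spec.seed``."""
    spec = spec or CommunitySpec()
    rng = np.random.default_rng(spec.seed)
    ledger = GroundTruthLedger()

    # --- phage genome scaffolds: founders per replicate group, then singletons
    planted: list[PlantedPhage] = []
    group_sizes = list(spec.replicate_groups)
    n_singletons = spec.n_phages - sum(group_sizes)
    group_defs = [(f"group_{i+1}", size) for i, size in enumerate(group_sizes)]
    group_defs += [(f"singleton_{i+1}", 1) for i in range(n_singletons)]
    idx = 0
    founders: list[tuple[PlantedPhage, str, int]] = []
    for group_name, size in group_defs:
        length = _draw_length(rng, spec)
        gc = float(rng.uniform(*spec.gc_range))
        founder = PlantedPhage(
            id=f"phage_{idx+1:03d}",
            residues=_random_dna(rng, length, gc),
            gc=gc,
            replicate_group=group_name,
            founder=True,
        )
        planted.append(founder)
        founders.append((founder, group_name, size))
        idx += size

    # --- hosts with taxa, tRNA loci, and a CRISPR array scaffold
    hosts: list[NucleotideSequence] = []
    host_taxa: dict[str, str] = {}
    trna_loci: dict[str, list[tuple[int, int]]] = {}
    host_arrays: dict[str, dict] = {}
    # fixed non-overlapping feature layout: tRNA loci from 10 kb, the CRISPR
    # array at 20 kb, prophage-like shared regions from 30 kb onwards
    if spec.host_length_bp < 40_000:
        raise ValueError("host genomes must be at least 40 kb for the feature layout")
    for h in range(spec.n_hosts):
        host_id = f"host_{h+1:02d}"
        residues = _random_dna(rng, spec.host_length_bp, spec.host_gc)
        taxon = spec.taxa[h % len(spec.taxa)]
        host_taxa[host_id] = taxon
        loci = []
        for t in range(spec.trna_per_host):
            start = 10_000 + t * (spec.trna_length_bp + 2_000)
            loci.append((start + 1, start + spec.trna_length_bp))
        trna_loci[host_id] = loci
        # CRISPR array scaffold: repeats + placeholder spacers
        repeat = _random_dna(rng, spec.crispr_repeat_bp, 0.5)
        spacers = [
            _random_dna(rng, spec.spacer_length_bp, 0.5)
            for _ in range(spec.crispr_n_repeats - 1)
        ]
        host_arrays[host_id] = {"repeat": repeat, "spacers": spacers, "pos": 20_000}
        hosts.append(NucleotideSequence(host_id, residues))
        ledger.hosts.append({"id": host_id, "taxon": taxon, "length": spec.host_length_bp})

    # --- markers: one taxon-restricted protein per taxon
    markers = [
        ProteinSequence(
            f"marker_{taxon}|{taxon}", _random_protein(rng, spec.marker_length_aa)
        )
        for taxon in spec.taxa
    ]
    marker_by_taxon = {spec.taxa[i]: markers[i] for i in range(len(spec.taxa))}

    # --- plant evidence links on founders (channel cycles across founders)
    links_spec = spec.links or {}
    host_edits: dict[str, list[tuple[str, str]]] = {h.id: [] for h in hosts}
    for f_idx, (founder, group_name, size) in enumerate(founders):
        host = hosts[f_idx % spec.n_hosts]
        channel = links_spec.get(founder.id, spec.channels[f_idx % len(spec.channels)])
        res = founder.residues
        n = len(res)
        if channel == "crispr_spacer":
            start = int(rng.integers(1000, n - 1000))
            spacer = res[start : start + spec.spacer_length_bp]
            host_arrays[host.id]["spacers"][0] = spacer
            founder.protected.append((start + 1, start + spec.spacer_length_bp))
            coords = {"phage_interval": [start + 1, start + spec.spacer_length_bp]}
        elif channel == "trna_attb":
            t_start, t_end = trna_loci[host.id][0]
            att = hosts[f_idx % spec.n_hosts].residues[t_end - spec.attb_length_bp : t_end]
            pos = int(rng.integers(1000, n - 1000))
            res = res[:pos] + att + res[pos + len(att) :]
            founder.protected.append((pos + 1, pos + len(att)))
            coords = {
                "phage_interval": [pos + 1, pos + len(att)],
                "host_interval": [t_end - spec.attb_length_bp + 1, t_end],
            }
        elif channel == "shared_sequence":
            if n < spec.shared_region_bp + 2000:
                raise ValueError("phage too short for the shared region")
            start = int(rng.integers(1000, n - spec.shared_region_bp - 1000))
            region = res[start : start + spec.shared_region_bp]
            host_edits[host.id].append(("shared", region))
            founder.protected.append((start + 1, start + spec.shared_region_bp))
            coords = {"phage_interval": [start + 1, start + spec.shared_region_bp]}
        elif channel == "marker_gene":
            marker = marker_by_taxon[host_taxa[host.id]]
            cds = _reverse_translate(marker.residues)
            pos = int(rng.integers(1000, n - len(cds) - 1000))
            res = res[:pos] + cds + res[pos + len(cds) :]
            founder.protected.append((pos + 1, pos + len(cds)))
            coords = {"phage_interval": [pos + 1, pos + len(cds)]}
        else:
            raise ValueError(f"unknown channel {channel!r}")
        founder.residues = res
        # the link applies to every member of the replicate group
        member_ids = [f"phage_{i+1:03d}" for i in range(
            int(founder.id.split("_")[1]) - 1, int(founder.id.split("_")[1]) - 1 + size
        )]
        for member_id in member_ids:
            ledger.links.append(
                {
                    "phage": member_id,
                    "host": host.id,
                    "channel": channel,
                    "taxon": host_taxa[host.id],
                    "coords": coords,
                }
            )

    # --- apply host edits: CRISPR arrays and shared regions
    final_hosts: list[NucleotideSequence] = []
    for host in hosts:
        res = host.residues
        info = host_arrays[host.id]
        repeat = info["repeat"]
        array = repeat + "".join(s + repeat for s in info["spacers"])
        pos = info["pos"]
        res = res[:pos] + array + res[pos + len(array) :]
        insert_at = 30_000
        for kind, region in host_edits[host.id]:
            if insert_at + len(region) > len(res) - 1_000:
                raise ValueError(f"{host.id}: too many shared regions for host length")
            res = res[:insert_at] + region + res[insert_at + len(region) :]
            insert_at += len(region) + 500
        final_hosts.append(NucleotideSequence(host.id, res))
    hosts = final_hosts

    # --- replicate copies (mutations spare planted intervals)
    all_phages: list[PlantedPhage] = []
    for founder, group_name, size in founders:
        all_phages.append(founder)
        founder_num = int(founder.id.split("_")[1])
        for c in range(1, size):
            copy_res = _mutate(rng, founder.residues, spec.mutation_rate, founder.protected)
            all_phages.append(
                PlantedPhage(
                    id=f"phage_{founder_num + c:03d}",
                    residues=copy_res,
                    gc=founder.gc,
                    replicate_group=group_name,
                    founder=False,
                    protected=list(founder.protected),
                )
            )
    all_phages.sort(key=lambda p: p.id)

    phages = [NucleotideSequence(p.id, p.residues, topology="circular") for p in all_phages]
    contigs = [
        NucleotideSequence(p.id, p.residues + p.residues[: spec.terminal_repeat_bp])
        for p in all_phages
    ]
    for p in all_phages:
        ledger.genomes.append(
            {
                "id": p.id,
                "length": len(p.residues),
                "gc": round(gc_content(NucleotideSequence(p.id, p.residues)), 4),
                "replicate_group": p.replicate_group,
                "founder": p.founder,
                "size_class": classify_size(len(p.residues)),
                "regime": None,
            }
        )
    return Community(
        spec=spec,
        contigs=contigs,
        phages=phages,
        hosts=hosts,
        markers=markers,
        trna_loci=trna_loci,
        host_taxa=host_taxa,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _assign_regimes(community: Community, ts: TimeSeriesSpec) -> dict[str, str]:
    """Regime per replicate group, cycling boom_bust / persistent /
    mixis_shared so every regime is represented."""
    regimes = {}
    cycle = ("boom_bust", "persistent", "mixis_shared")
    groups = sorted({g["replicate_group"] for g in community.ledger.genomes})
    for i, group in enumerate(groups):
        regimes[group] = cycle[i % len(cycle)]
    return {
        g["id"]: regimes[g["replicate_group"]] for g in community.ledger.genomes
    }


def _depth_profile(
    regime: str, samples: list[SampleSpec], ts: TimeSeriesSpec, rng: np.random.Generator
) -> dict[str, float]:
    epi = [s for s in samples if s.depth_label == "epi" and not s.mixis]
    hypo = [s for s in samples if s.depth_label == "hypo"]
    mixis = [s for s in samples if s.mixis]
    profile = {s.id: 0.0 for s in samples}
    if regime == "boom_bust":
        peak, bg = ts.boom_bust_depth
        n_peaks = int(rng.integers(1, 3))  # 1 or 2 epilimnion peaks
        peaks = rng.choice(len(epi), size=min(n_peaks, len(epi)), replace=False)
        for s in samples:
            profile[s.id] = bg
        for i in peaks:
            profile[epi[i].id] = peak
    elif regime == "persistent":
        peak, bg = ts.persistent_depth
        for s in samples:
            profile[s.id] = peak if s.depth_label == "hypo" else bg
    elif regime == "mixis_shared":
        peak, bg = ts.mixis_depth
        for s in samples:
            profile[s.id] = peak if s.mixis else bg
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return profile


def _simulate_pairs(
    rng: np.random.Generator,
    genome: str,
    n_pairs: int,
    ts: TimeSeriesSpec,
    read_prefix: str,
) -> list[tuple[str, str]]:
    """Paired reads from a circular template (origin-spanning allowed),
    substitution errors at ``ts.error_rate``."""
    n = len(genome)
    doubled = genome + genome  # wrap-around fragments read off the doubled copy
    reads: list[tuple[str, str]] = []
    bases = np.array(list("ACGT"))
    rl = ts.read_length
    for p in range(n_pairs):
        frag = int(np.clip(rng.normal(ts.fragment_mean_bp, ts.fragment_sd_bp), 2 * rl, n))
        start = int(rng.integers(0, n))
        fragment = doubled[start : start + frag]
        r1 = fragment[:rl]
        r2 = reverse_complement(fragment[-rl:])
        out = []
        for mate, seq in ((1, r1), (2, r2)):
            arr = np.array(list(seq))
            err = np.nonzero(rng.random(rl) < ts.error_rate)[0]
            for i in err:
                choices = [b for b in bases if b != arr[i]]
                arr[i] = choices[rng.integers(3)]
            out.append((f"{read_prefix}_{p}/{mate}", "".join(arr)))
        reads.extend(out)
    return reads


def generate_reads(
    community: Community, ts: TimeSeriesSpec | None = None
) -> list["Sample"]:
    """Per-sample paired 151 bp read sets realizing the regime depth
    profiles; updates the community ledger with per-sample expected depths
    and metadata.  Deterministic for a fixed ``ts.seed``."""
    from .abundance import Sample

    ts = ts or TimeSeriesSpec()
    rng = np.random.default_rng(ts.seed)
    regimes = _assign_regimes(community, ts)
    for g in community.ledger.genomes:
        g["regime"] = regimes[g["id"]]
    profiles = {}
    # one profile per replicate group so near-identical genomes co-vary
    group_profiles: dict[str, dict[str, float]] = {}
    for g in community.ledger.genomes:
        group = g["replicate_group"]
        if group not in group_profiles:
            group_profiles[group] = _depth_profile(regimes[g["id"]], ts.samples, ts, rng)
        profiles[g["id"]] = group_profiles[group]
    genome_by_id = {p.id: p for p in community.phages}
    samples: list[Sample] = []
    community.ledger.samples = []
    community.ledger.expected_depth = {}
    for sspec in ts.samples:
        reads: list[tuple[str, str]] = []
        for gid in sorted(profiles):
            depth = profiles[gid][sspec.id]
            n = len(genome_by_id[gid])
            n_pairs = int(round(depth * n / (2 * ts.read_length)))
            community.ledger.expected_depth.setdefault(gid, {})[sspec.id] = depth
            if n_pairs == 0:
                continue
            reads.extend(
                _simulate_pairs(
                    rng, genome_by_id[gid].residues, n_pairs, ts, f"{sspec.id}_{gid}"
                )
            )
        sample = Sample(
            id=sspec.id,
            reads=reads,
            date=sspec.date,
            depth_m=0.5 if sspec.depth_label == "epi" else 30.0,
            temperature_C=sspec.temperature,
        )
        samples.append(sample)
        community.ledger.samples.append(
            {
                "id": sspec.id,
                "date": sspec.date,
                "depth_label": sspec.depth_label,
                "temperature": sspec.temperature,
                "mixis": sspec.mixis,
                "total_bases": sample.total_bases,
            }
        )
    return samples


def write_samples(samples, outdir) -> None:
    """FASTQ per sample plus a metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["sample\tfastq\tdate\tdepth_m\ttemperature_C\ttotal_bases"]
    for sample in samples:
        fq = outdir / f"{sample.id}.fastq"
        write_fastq(fq, sample.reads)
        rows.append(
            f"{sample.id}\t{fq.name}\t{sample.date}\t{sample.depth_m}\t"
            f"{sample.temperature_C}\t{sample.total_bases}"
        )
    (outdir / "samples.tsv").write_text("\n".join(rows) + "\n")
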