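"""Host prediction: CRISPR arrays, spacer/attB/shared channels, markers,
and evidence integration."""

import numpy as np
import pytest

from lakephage.discovery import PhageGenome, classify_size
from lakephage.hostlink import (
    CrisprArray,
    CrisprParams,
    HostEvidence,
    assign_host,
    detect_crispr_arrays,
    detect_marker_genes,
    match_spacers,
    match_trna_attb,
    shared_sequence_evidence,
)
from lakephage.seqcore import NucleotideSequence, ProteinSequence, find_orfs, gc_content
from lakephage.synth import _reverse_translate

from .conftest import mutate_dna, random_dna


def _phage(gid, residues, orfs=False):
    seq = NucleotideSequence(gid, residues, topology="circular")
    return PhageGenome(
        sequence=seq,
        gc=gc_content(seq),
        size_class=classify_size(len(seq)),
        orfs=find_orfs(seq, 30) if orfs else [],
    )


class TestDetectCrisprArrays:
    def test_planted_array_recovered_exactly(self):
        rng = np.random.default_rng(40)
        repeat = random_dna(rng, 30)
        spacers = [random_dna(rng, 32) for _ in range(4)]
        array = repeat + "".join(s + repeat for s in spacers)
        host = NucleotideSequence(
            "h", random_dna(rng, 20_000) + array + random_dna(rng, 20_000)
        )
        found = detect_crispr_arrays(host)
        assert len(found) == 1
        assert found[0].n_repeats == 5
        assert [s for s, _iv in found[0].spacers] == spacers
        assert found[0].repeat_consensus == repeat

    def test_two_repeats_insufficient(self):
        rng = np.random.default_rng(41)
        repeat = random_dna(rng, 30)
        array = repeat + random_dna(rng, 32) + repeat
        host = NucleotideSequence("h", random_dna(rng, 5_000) + array + random_dna(rng, 5_000))
        assert detect_crispr_arrays(host) == []

    def test_random_sequence_null(self):
        rng = np.random.default_rng(42)
        false_positives = 0
        for _ in range(100):
            host = NucleotideSequence("h", random_dna(rng, 100_000))
            if detect_crispr_arrays(host):
                false_positives += 1
        assert false_positives <= 5


def _array_with_spacers(host_id, spacers, rng):
    repeat = random_dna(rng, 30)
    while len(spacers) < 2:  # an array has >= 3 repeats, so >= 2 spacers
        spacers = spacers + [random_dna(rng, 32)]
    pos = 1
    repeats, spacer_records = [], []
    for i, s in enumerate(spacers + [None]):
        repeats.append((pos, pos + 29))
        pos += 30
        if s is not None:
            spacer_records.append((s, (pos, pos + len(s) - 1)))
            pos += len(s)
    return CrisprArray(
        host_id=host_id,
        repeat_consensus=repeat,
        repeats=tuple(repeats),
        spacers=tuple(spacer_records),
    )


class TestMatchSpacers:
    def test_planted_spacer_links_host_to_phage(self):
        rng = np.random.default_rng(43)
        phage = _phage("p", random_dna(rng, 15_000))
        spacer = phage.sequence.residues[5_000:5_032]
        array = _array_with_spacers("h", [spacer], rng)
        evidence = match_spacers([array], [phage])
        assert len(evidence) == 1
        e = evidence[0]
        assert (e.phage_id, e.host_id, e.channel) == ("p", "h", "crispr_spacer")
        assert e.taxon_resolution == "strain"
        assert e.hit.subject_interval == (5_001, 5_032)

    def test_29bp_exact_match_rejected(self):
        rng = np.random.default_rng(44)
        phage = _phage("p", random_dna(rng, 15_000))
        spacer = phage.sequence.residues[5_000:5_029]  # 29 bp, below min length
        array = _array_with_spacers("h", [spacer], rng)
        assert match_spacers([array], [phage]) == []

    def test_95_percent_identity_rejected(self):
        rng = np.random.default_rng(45)
        phage = _phage("p", random_dna(rng, 15_000))
        spacer = list(phage.sequence.residues[5_000:5_040])  # 40 bp
        for i in (5, 20):  # 2 mismatches: 95% identity < 97%
            spacer[i] = {"A": "C"}.get(spacer[i], "A")
        array = _array_with_spacers("h", ["".join(spacer)], rng)
        assert match_spacers([array], [phage]) == []


class TestTrnaAttb:
    def test_att_site_at_trna_locus(self):
        rng = np.random.default_rng(46)
        host_res = random_dna(rng, 50_000)
        trna = (10_001, 10_076)
        att = host_res[trna[1] - 45 : trna[1]]
        phage = _phage("p", random_dna(rng, 7_000) + att + random_dna(rng, 7_000))
        host = NucleotideSequence("h", host_res)
        evidence = match_trna_attb(phage, host, [trna])
        assert len(evidence) == 1
        assert evidence[0].channel == "trna_attb"

    def test_same_match_outside_locus_is_not_attb(self):
        rng = np.random.default_rng(47)
        host_res = random_dna(rng, 50_000)
        att = host_res[30_000:30_045]  # nowhere near the annotated locus
        phage = _phage("p", random_dna(rng, 7_000) + att + random_dna(rng, 7_000))
        host = NucleotideSequence("h", host_res)
        assert match_trna_attb(phage, host, [(10_001, 10_076)]) == []
        # but it is still shared-sequence evidence
        assert shared_sequence_evidence(phage, host)

    def test_no_loci_supplied_empty(self):
        rng = np.random.default_rng(48)
        phage = _phage("p", random_dna(rng, 12_000))
        host = NucleotideSequence("h", random_dna(rng, 30_000))
        assert match_trna_attb(phage, host, []) == []


class TestSharedSequence:
    def test_prophage_like_region(self):
        rng = np.random.default_rng(49)
        phage = _phage("p", random_dna(rng, 20_000))
        region = phage.sequence.residues[2_000:7_000]
        host = NucleotideSequence(
            "h", random_dna(rng, 30_000) + region + random_dna(rng, 30_000)
        )
        evidence = shared_sequence_evidence(phage, host)
        assert evidence
        top = evidence[0].hit
        assert top.alignment_length >= 4_990
        # flanking coincidental matches may extend slightly past the region
        assert top.percent_identity >= 99.9

    def test_short_high_identity_hit_rejected(self):
        rng = np.random.default_rng(50)
        phage = _phage("p", random_dna(rng, 20_000))
        region = phage.sequence.residues[2_000:2_025]  # 25 bp at 100%
        host = NucleotideSequence(
            "h", random_dna(rng, 30_000) + region + random_dna(rng, 30_000)
        )
        assert all(
            e.hit.alignment_length >= 30 for e in shared_sequence_evidence(phage, host)
        )

    def test_unrelated_pair_null(self):
        rng = np.random.default_rng(51)
        hits = 0
        for _ in range(30):
            phage = _phage("p", random_dna(rng, 12_000))
            host = NucleotideSequence("h", random_dna(rng, 20_000))
            if shared_sequence_evidence(phage, host):
                hits += 1
        assert hits <= 1


@pytest.fixture(scope="module")
def marker():
    rng = np.random.default_rng(52)
    protein = "M" + "".join(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), 179))
    return ProteinSequence("whiB_like|Actinobacteria", protein)


class TestMarkerGenes:
    def test_planted_marker_copy_detected(self, marker):
        rng = np.random.default_rng(53)
        cds = _reverse_translate(marker.residues)
        phage = _phage(
            "p", random_dna(rng, 6_000) + cds + random_dna(rng, 6_000), orfs=True
        )
        evidence = detect_marker_genes(phage, [marker])
        assert evidence
        assert evidence[0].host_id == "Actinobacteria"
        assert evidence[0].taxon_resolution == "phylum"

    def test_two_copies_give_two_records(self, marker):
        rng = np.random.default_rng(54)
        cds = _reverse_translate(marker.residues)
        phage = _phage(
            "p",
            random_dna(rng, 4_000) + cds + random_dna(rng, 4_000) + cds + random_dna(rng, 4_000),
            orfs=True,
        )
        evidence = detect_marker_genes(phage, [marker])
        assert len(evidence) == 2

    def test_random_orfs_null(self, marker):
        rng = np.random.default_rng(55)
        hits = 0
        for _ in range(100):
            orfs = [
                ProteinSequence(
                    f"o{i}", "M" + "".join(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), 200))
                )
                for i in range(3)
            ]
            phage = _phage("p", random_dna(rng, 12_000))
            phage.orfs = orfs
            if detect_marker_genes(phage, [marker]):
                hits += 1
        assert hits <= 5


def _ev(phage, host, channel, resolution="strain"):
    return HostEvidence(phage_id=phage, host_id=host, channel=channel, taxon_resolution=resolution)


class TestAssignHost:
    def test_channel_precedence(self):
        evidence = [
            _ev("p", "H1", "crispr_spacer"),
            _ev("p", "PhylumX", "marker_gene", "phylum"),
        ]
        call = assign_host(evidence)
        assert call.status == "assigned"
        assert call.host_id == "H1"
        assert call.winning_channel == "crispr_spacer"

    def test_marker_only_assigns_at_phylum(self):
        call = assign_host([_ev("p", "Actinobacteria", "marker_gene", "phylum")])
        assert call.status == "assigned"
        assert call.host_id == "Actinobacteria"
        assert call.winning_channel == "marker_gene"

    def test_tied_hosts_ambiguous(self):
        evidence = [_ev("p", "H1", "crispr_spacer"), _ev("p", "H2", "crispr_spacer")]
        call = assign_host(evidence)
        assert call.status == "ambiguous"
        assert call.host_id is None

    def test_empty_unassigned(self):
        call = assign_host([], phage_id="p")
        assert call.status == "unassigned"

    def test_order_invariance(self):
        evidence = [
            _ev("p", "H1", "shared_sequence"),
            _ev("p", "H1", "trna_attb"),
            _ev("p", "H2", "shared_sequence"),
            _ev("p", "X", "marker_gene", "phylum"),
        ]
        calls = {str(assign_host(list(perm))) for perm in _permutations(evidence)}
        assert len(calls) == 1

    def test_majority_within_channel_wins(self):
        evidence = [
            _ev("p", "H1", "shared_sequence"),
            _ev("p", "H1", "shared_sequence"),
            _ev("p", "H2", "shared_sequence"),
        ]
        call = assign_host(evidence)
        assert call.host_id == "H1"


def _permutations(items):
    import itertools

    return itertools.permutations(items)
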