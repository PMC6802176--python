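"""Fragment recruitment, coverage normalization, presence calls, and
profile clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from lakephage.abundance import (
    Sample,
    cluster_profiles,
    coverage_per_gb,
    mask_rrna,
    presence_call,
    recruit,
    spearman_distance_matrix,
    subsample_reads,
    zscore_rows,
)
from lakephage.seqcore import NucleotideSequence
from lakephage.synth import CommunitySpec, TimeSeriesSpec, generate_community, generate_reads

from .conftest import random_dna


class TestMaskRrna:
    def test_interval_masked_length_kept(self):
        rng = np.random.default_rng(60)
        g = NucleotideSequence("g", random_dna(rng, 10_000))
        masked = mask_rrna(g, [(1, 1500)])
        assert len(masked) == 10_000
        assert masked.residues[:1500] == "N" * 1500
        assert masked.residues[1500:] == g.residues[1500:]

    def test_empty_intervals_identity(self):
        rng = np.random.default_rng(61)
        g = NucleotideSequence("g", random_dna(rng, 500))
        assert mask_rrna(g, []).residues == g.residues

    def test_overlapping_intervals_union(self):
        rng = np.random.default_rng(62)
        g = NucleotideSequence("g", random_dna(rng, 500))
        masked = mask_rrna(g, [(1, 100), (50, 150)])
        assert masked.residues.count("N") == 150

    def test_out_of_bounds_rejected(self):
        g = NucleotideSequence("g", "ACGT" * 100)
        with pytest.raises(ValueError):
            mask_rrna(g, [(1, 1000)])


class TestSubsampleReads:
    def _sample(self, n):
        return Sample(id="s", reads=[(f"r{i}", "ACGT" * 38) for i in range(n)])

    def test_fewer_reads_unchanged(self):
        s = self._sample(10)
        assert subsample_reads(s, 20, seed=1) is s

    def test_deterministic(self):
        s = self._sample(1000)
        a = subsample_reads(s, 100, seed=5)
        b = subsample_reads(s, 100, seed=5)
        assert [r for r, _ in a.reads] == [r for r, _ in b.reads]
        assert len(a.reads) == 100
        assert a.total_bases == 100 * 152

    def test_different_seeds_differ(self):
        s = self._sample(1000)
        a = subsample_reads(s, 100, seed=5)
        b = subsample_reads(s, 100, seed=6)
        assert [r for r, _ in a.reads] != [r for r, _ in b.reads]


def _reads_from(rng, genome: str, depth: float, read_len=151, prefix="r"):
    n_reads = int(round(depth * len(genome) / read_len))
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, len(genome) - read_len))
        reads.append((f"{prefix}{i}", genome[start : start + read_len]))
    return reads


class TestRecruit:
    def test_error_free_reads_all_recruited(self):
        rng = np.random.default_rng(63)
        g = NucleotideSequence("g", random_dna(rng, 15_000))
        reads = _reads_from(rng, g.residues, depth=10)
        sample = Sample(id="s", reads=reads)
        result = recruit(g, sample)
        assert result.mapped_reads == len(reads)
        assert result.breadth > 0.99

    def test_unrelated_reads_not_recruited(self):
        rng = np.random.default_rng(64)
        g = NucleotideSequence("g", random_dna(rng, 15_000))
        other = random_dna(rng, 15_000)
        sample = Sample(id="s", reads=_reads_from(rng, other, depth=5))
        result = recruit(g, sample)
        assert result.mapped_reads == 0

    def test_short_alignments_rejected(self):
        rng = np.random.default_rng(65)
        g = NucleotideSequence("g", random_dna(rng, 15_000))
        # 40 bp of genome sequence embedded in foreign sequence
        reads = []
        for i in range(50):
            start = int(rng.integers(0, 14_000))
            reads.append((f"r{i}", g.residues[start : start + 40] + random_dna(rng, 111)))
        result = recruit(g, Sample(id="s", reads=reads))
        assert result.mapped_reads == 0


class TestCoveragePerGb:
    def test_arithmetic(self):
        # 1000 recruited 150 bp reads on a 10 kb genome in a 1 Gb sample
        mean_depth = 1000 * 150 / 10_000
        assert coverage_per_gb(mean_depth, 1_000_000_000) == pytest.approx(15.0)

    def test_zero_depth(self):
        assert coverage_per_gb(0.0, 10**9) == 0.0

    def test_halves_when_sample_doubles(self):
        assert coverage_per_gb(10.0, 2 * 10**9) == pytest.approx(
            coverage_per_gb(10.0, 10**9) / 2
        )

    def test_invalid_sample_size(self):
        with pytest.raises(ValueError):
            coverage_per_gb(1.0, 0)


class TestPresenceCall:
    @pytest.mark.parametrize(
        "breadth,expected", [(0.79, False), (0.80, False), (0.8001, True), (0.90, True)]
    )
    def test_strict_threshold(self, breadth, expected):
        assert presence_call(breadth) is expected


class TestZscoreRows:
    def test_arithmetic_row(self):
        out = zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        assert out[0] == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_constant_row_zeroed(self):
        out = zscore_rows(np.array([[5.0, 5.0, 5.0]]))
        assert (out == 0).all()

    @given(
        st.lists(
            st.lists(st.floats(min_value=-100, max_value=100), min_size=4, max_size=4),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_standardized(self, rows):
        out = zscore_rows(np.array(rows, dtype=float))
        for row in out:
            if np.any(row != 0):
                assert abs(row.mean()) < 1e-9
                assert abs(row.std() - 1.0) < 1e-9

    def test_dataframe_round_trip(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        out = zscore_rows(df)
        assert list(out.index) == ["g"]
        assert out.loc["g", "b"] == 0.0


def _avg_linkage_oracle(dist):
    """O(n^3) average-linkage agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestClusterProfiles:
    def test_identical_profiles_joined_first_at_zero(self):
        profiles = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]], dtype=float)
        linkage, order = cluster_profiles(profiles, ids=["a", "b", "c"])
        # rows a and b are rank-identical: distance 0, first merge
        assert linkage[0, 2] == pytest.approx(0.0)
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}

    def test_anticorrelated_distance_two(self):
        profiles = np.array([[1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        dist = spearman_distance_matrix(profiles)
        assert dist[0, 1] == pytest.approx(2.0)

    def test_planted_blocks_and_merge_heights_match_oracle(self):
        rng = np.random.default_rng(66)
        # enough samples and noise that no two profiles share exact ranks
        # (exact distance ties make the dendrogram order-dependent)
        base1 = rng.normal(size=24)
        base2 = -base1 + rng.normal(scale=0.2, size=24)
        profiles = np.vstack(
            [base1 + rng.normal(scale=0.4, size=24) for _ in range(5)]
            + [base2 + rng.normal(scale=0.4, size=24) for _ in range(5)]
        )
        linkage, order = cluster_profiles(profiles, ids=[f"g{i}" for i in range(10)])
        # top split separates the two correlation blocks
        cut = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
        assert len(set(cut[:5])) == 1 and len(set(cut[5:])) == 1
        assert set(cut) == {1, 2}
        oracle = _avg_linkage_oracle(spearman_distance_matrix(profiles))
        assert sorted(linkage[:, 2]) == pytest.approx(oracle, abs=1e-9)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(np.array([[1.0, 2.0]]))


class TestSimulatedDepthRecovery:
    def test_depth_ratio_recovery(self):
        """Genomes simulated at relative depths (1, 2, 4) recover
        coverage-per-Gb ratios within 10% (base depth 5x)."""
        rng = np.random.default_rng(67)
        spec = CommunitySpec(
            n_phages=3, n_hosts=1, replicate_groups=(), seed=67,
            length_modes=((1.0, 15_000.0, 0.02),),
        )
        community = generate_community(spec)
        ts = TimeSeriesSpec(seed=67, error_rate=0.0)
        genomes = community.phages
        reads = []
        for g, depth in zip(genomes, (5.0, 10.0, 20.0)):
            n_pairs = int(round(depth * len(g) / 302))
            from lakephage.synth import _simulate_pairs

            reads.extend(_simulate_pairs(rng, g.residues, n_pairs, ts, g.id))
        sample = Sample(id="s", reads=reads)
        cov = []
        for g in genomes:
            result = recruit(g, sample)
            cov.append(coverage_per_gb(result, sample.total_bases))
        assert cov[1] / cov[0] == pytest.approx(2.0, rel=0.1)
        assert cov[2] / cov[0] == pytest.approx(4.0, rel=0.1)
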