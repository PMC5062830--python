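import numpy as np
import pytest

from phylodemo.diversity import (
    AmovaResult,
    PopulationMap,
    UndefinedStatisticError,
    amova_phist,
    haplotype_counts,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_difference_matrix,
    pairwise_phist,
    population_stats_table,
    segregating_sites,
)
from phylodemo.seqevo import Alignment


def brute_force_amova(d, assign):
    """Textbook sums-of-squares variance components from a distance matrix."""
    n = len(assign)
    pops = sorted(set(assign))
    P = len(pops)
    ssd_total = sum(d[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ssd_within = 0.0
    sum_np2 = 0.0
    for p in pops:
        idx = [i for i in range(n) if assign[i] == p]
        n_p = len(idx)
        sum_np2 += n_p**2
        ssd_within += sum(
            d[i][j] for k, i in enumerate(idx) for j in idx[k + 1:]
        ) / n_p
    sigma_w = ssd_within / (n - P)
    n_bar = (n - sum_np2 / n) / (P - 1)
    sigma_a = ((ssd_total - ssd_within) / (P - 1) - sigma_w) / n_bar
    return sigma_a / (sigma_a + sigma_w)


class TestHaplotypeCounts:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["AAT"] * 4, [4]),
            (["AAT", "ACT", "GGG", "TTT"], [1, 1, 1, 1]),
            (["AAT", "AAT", "ACT"], [2, 1]),
        ],
    )
    def test_identity_classes(self, seqs, expected):
        aln = Alignment.from_strings(
            [f"s{i}" for i in range(len(seqs))], seqs
        )
        assert haplotype_counts(aln).tolist() == expected

    def test_ambiguous_columns_excluded_alignment_wide(self):
        # the N column is dropped for every sequence, making all identical
        aln = Alignment.from_strings(["a", "b"], ["ANT", "AGT"])
        assert haplotype_counts(aln).tolist() == [2]


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1], 1.0),          # two singletons, n = 2
            ([5], 0.0),             # monomorphic
            ([2, 2], 4 / 3 * 0.5),  # direct Nei formula
            ([19, 1], (20 / 19) * (1 - (361 + 1) / 400)),
        ],
    )
    def test_nei_formula(self, counts, expected):
        assert haplotype_diversity(np.array(counts)) == pytest.approx(expected)

    def test_single_sequence_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            haplotype_diversity(np.array([1]))

    def test_zero_iff_single_haplotype(self, rng):
        for _ in range(20):
            k = rng.integers(1, 5)
            counts = rng.integers(1, 10, size=k)
            if counts.sum() < 2:
                continue
            h = haplotype_diversity(counts)
            assert (h == 0.0) == (k == 1)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = Alignment.from_strings(["a", "b"], ["ACGT", "ACGT"])
        assert nucleotide_diversity(aln) == 0.0

    def test_two_sequences_one_of_ten_sites(self):
        aln = Alignment.from_strings(
            ["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAT"]
        )
        assert nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_three_sequence_hand_enumeration(self):
        # pairwise differences {1, 2, 3} over 100 bp -> mean 2 per pair
        s1 = "A" * 100
        s2 = "T" + "A" * 99
        s3 = "A" + "GG" + "A" * 97
        aln = Alignment.from_strings(["a", "b", "c"], [s1, s2, s3])
        assert nucleotide_diversity(aln) == pytest.approx(0.02)

    def test_bounded_by_segregating_fraction(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            data = r.integers(0, 4, size=(6, 30)).astype(np.uint8)
            aln = Alignment(
                data=data, labels=tuple(f"s{i}" for i in range(6))
            )
            assert nucleotide_diversity(aln) <= (
                segregating_sites(aln) / aln.length + 1e-12
            )

    def test_invariant_under_row_and_column_permutation(self, rng):
        data = rng.integers(0, 4, size=(8, 40)).astype(np.uint8)
        aln = Alignment(data=data, labels=tuple(f"s{i}" for i in range(8)))
        rows = rng.permutation(8)
        cols = rng.permutation(40)
        shuffled = Alignment(
            data=data[np.ix_(rows, cols)],
            labels=tuple(f"t{i}" for i in range(8)),
        )
        assert nucleotide_diversity(shuffled) == pytest.approx(
            nucleotide_diversity(aln)
        )
        assert haplotype_diversity(
            haplotype_counts(shuffled)
        ) == pytest.approx(haplotype_diversity(haplotype_counts(aln)))


class TestSegregatingSites:
    @pytest.mark.parametrize(
        "seqs,expected",
        [(["AAT", "AAT"], 0), (["AAT", "ACT"], 1), (["AAT", "ACT", "GCT"], 2)],
    )
    def test_counts(self, seqs, expected):
        aln = Alignment.from_strings(
            [f"s{i}" for i in range(len(seqs))], seqs
        )
        assert segregating_sites(aln) == expected


class TestAmova:
    def test_fixed_private_haplotypes_give_phi_one(self, rng):
        aln = Alignment.from_strings(
            ["a1", "a2", "b1", "b2"], ["AAA", "AAA", "AAT", "AAT"]
        )
        pops = PopulationMap(
            assignments={"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        res = amova_phist(aln, pops, n_perm=100, rng=rng)
        assert res.phi_st == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, toy_alignment, toy_popmap, rng):
        res = amova_phist(toy_alignment, toy_popmap, n_perm=10, rng=rng)
        d = pairwise_difference_matrix(toy_alignment)
        assign = [toy_popmap.assignments[l] for l in toy_alignment.labels]
        assert res.phi_st == pytest.approx(
            brute_force_amova(d, assign), abs=1e-10
        )

    def test_null_labels_give_small_phi_and_moderate_p(self):
        r = np.random.default_rng(0)
        data = r.integers(0, 4, size=(24, 60)).astype(np.uint8)
        labels = tuple(f"s{i}" for i in range(24))
        aln = Alignment(data=data, labels=labels)
        pops = PopulationMap(
            assignments={l: ("P1" if i % 2 else "P2")
                         for i, l in enumerate(labels)}
        )
        res = amova_phist(aln, pops, n_perm=500,
                          rng=np.random.default_rng(1))
        assert abs(res.phi_st) < 0.1
        assert 0.05 < res.p_value <= 1.0

    def test_single_population_undefined(self, toy_alignment, rng):
        pops = PopulationMap(
            assignments={l: "P1" for l in toy_alignment.labels}
        )
        with pytest.raises(UndefinedStatisticError):
            amova_phist(toy_alignment, pops, n_perm=10, rng=rng)


class TestPairwisePhist:
    def test_symmetric_zero_diagonal(self, toy_alignment, toy_popmap, rng):
        phi, p = pairwise_phist(toy_alignment, toy_popmap, n_perm=20, rng=rng)
        m = phi.to_numpy()
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_two_population_case_equals_global_amova(
        self, toy_alignment, toy_popmap, rng
    ):
        phi, _ = pairwise_phist(toy_alignment, toy_popmap, n_perm=10, rng=rng)
        res = amova_phist(toy_alignment, toy_popmap, n_perm=10, rng=rng)
        assert phi.loc["P1", "P2"] == pytest.approx(res.phi_st, abs=1e-12)

    def test_identical_populations_give_near_zero(self, rng):
        aln = Alignment.from_strings(
            ["a1", "a2", "b1", "b2"], ["AAT", "ACT", "AAT", "ACT"]
        )
        pops = PopulationMap(
            assignments={"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        phi, _ = pairwise_phist(aln, pops, n_perm=10, rng=rng)
        assert phi.loc["A", "B"] <= 0.0 + 1e-12


class TestStatsTable:
    def test_table_columns_and_overall_row(self, toy_alignment, toy_popmap):
        table = population_stats_table(toy_alignment, toy_popmap)
        assert set(table.columns) == {"N", "k", "h", "h_sd", "pi", "pi_sd"}
        assert table.loc["Overall", "N"] == 6
        assert table.loc["P1", "k"] == 3
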