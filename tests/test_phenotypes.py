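"""Splice-site ratio phenotypes, PSSM scoring and U5/6rho."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicemap.phenotypes import (
    PSSM,
    PSSM_POSITIONS,
    SpliceSiteMatrix,
    bootstrap_phenotype,
    build_pssm,
    default_ratio_definitions,
    nucleotide_fractions,
    phenotype_vector,
    ratio_phenotype,
    ratio_sd_scan,
    u5u6_rho,
    u5u6_scores,
)


def sites_from(plus4_letters, species="sp"):
    """Windows identical except at +4."""
    return SpliceSiteMatrix.from_windows(
        species, [f"CAGGTA{nt}GTAT" for nt in plus4_letters]
    )


def mixture_sites(exon, intron, species="sp"):
    """Windows assembled from explicit exon (-3..-1) and intron (+3..+8) parts."""
    return SpliceSiteMatrix.from_windows(
        species, [e + "GT" + i for e, i in zip(exon, intron)]
    )


class TestFractionsAndRatios:
    def test_all_a(self):
        assert np.allclose(nucleotide_fractions(sites_from("A" * 10), 4), [1, 0, 0, 0])

    def test_half_half_and_order_invariance(self):
        f1 = nucleotide_fractions(sites_from("AAAAATTTTT"), 4)
        f2 = nucleotide_fractions(sites_from("ATATATATAT"), 4)
        assert np.allclose(f1, [0.5, 0, 0, 0.5]) and np.allclose(f1, f2)

    def test_all_n_rejected(self):
        s = SpliceSiteMatrix.from_windows("sp", ["CAGGTANGTAT"] * 3)
        with pytest.raises(ValueError):
            nucleotide_fractions(s, 4)

    def test_symmetric_counts_give_zero(self):
        assert ratio_phenotype(sites_from("A" * 10 + "T" * 10), 4) == 0.0

    def test_hand_computed_value(self):
        # 20 A, 5 T, pseudocount 0.5 -> log2(20.5/5.5)
        val = ratio_phenotype(sites_from("A" * 20 + "T" * 5), 4)
        assert val == pytest.approx(np.log2(20.5 / 5.5))

    def test_zero_counts_both_sets(self):
        assert ratio_phenotype(sites_from("G" * 4), 4) == 0.0

    def test_acceptor_column_reuses_ratio(self):
        s = SpliceSiteMatrix.from_windows(
            "sp", ["CAGGTAAGTAT"] * 4, ["TTTCAGG", "TTTTAGG", "TTTCAGG", "TTTTAGG"]
        )
        val = ratio_phenotype(s, 0, num_set="C", den_set="T", acceptor=True)
        assert val == pytest.approx(np.log2(2.5 / 2.5))

    @given(
        st.lists(st.sampled_from("ACGT"), min_size=1, max_size=60),
        st.integers(0, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_property(self, letters, pos_choice):
        pos = [-3, -1, 4, 7][pos_choice]
        s = SpliceSiteMatrix.from_windows("sp", [f"CAGGTA{nt}GTAT" for nt in letters])
        ab = ratio_phenotype(s, pos, "A", "T")
        ba = ratio_phenotype(s, pos, "T", "A")
        assert ab == -ba


class TestBootstrap:
    def test_degenerate_sites_zero_width_ci(self):
        point, reps = bootstrap_phenotype(sites_from("A" * 8), 4, B=50, seed=0)
        assert np.all(reps == point)

    def test_deterministic(self):
        s = sites_from("AATTAT" * 5)
        _, r1 = bootstrap_phenotype(s, 4, B=40, seed=3)
        _, r2 = bootstrap_phenotype(s, 4, B=40, seed=3)
        assert np.array_equal(r1, r2)

    def test_replicate_mean_approaches_point(self):
        s = sites_from("A" * 30 + "T" * 20)
        point, reps = bootstrap_phenotype(s, 4, B=10_000, seed=1)
        assert abs(reps.mean() - point) < 0.02

    def test_ci_coverage_near_nominal(self):
        # true +4 log2 A:T ratio for p=0.6 is log2(0.6/0.4); with 500
        # introns per draw the 95% bootstrap CI should cover it >= 90%
        rng = np.random.default_rng(42)
        true = np.log2(0.6 / 0.4)
        n, hits, sims = 500, 0, 200
        for _ in range(sims):
            letters = np.where(rng.random(n) < 0.6, "A", "T")
            s = sites_from(letters)
            _, reps = bootstrap_phenotype(s, 4, B=200, seed=rng)
            lo, hi = np.percentile(reps, [2.5, 97.5])
            hits += lo <= true <= hi
        assert hits / sims >= 0.90

    def test_phenotype_vector_species_sorted(self):
        mats = {"b": sites_from("AATT"), "a": sites_from("ATTT")}
        pv = phenotype_vector(mats, B=10, seed=0)
        assert pv.species == ["a", "b"]
        ci = pv.ci()
        assert np.all(ci[:, 0] <= pv.estimate + 1e-12)


class TestSDScan:
    def test_identical_species_zero_sd(self):
        mats = {f"s{i}": sites_from("AATT") for i in range(4)}
        table = ratio_sd_scan(mats)
        assert np.allclose(table["sd"], 0.0)

    def test_two_species_hand_value(self):
        # +4 log2 ratios +1 and -1 -> sample SD sqrt(2)
        mats = {
            "s1": sites_from("A" * 25 + "T" * 12),  # log2(25.5/12.5)
            "s2": sites_from("T" * 25 + "A" * 12),
        }
        table = ratio_sd_scan(mats, positions=(4,))
        row = table[(table.position == 4) & (table.ratio == "A:T")]
        expected = np.sqrt(2) * np.log2(25.5 / 12.5)
        assert row.sd.iloc[0] == pytest.approx(expected)

    def test_invariant_gt_positions_zero_sd(self):
        rng = np.random.default_rng(0)
        mats = {
            f"s{i}": sites_from(rng.choice(list("ACGT"), 30)) for i in range(5)
        }
        table = ratio_sd_scan(mats)
        gt = table[table.position.isin([1, 2])]
        assert np.allclose(gt.sd, 0.0)

    def test_ratio_definitions_cover_pairs_and_degenerate(self):
        defs = default_ratio_definitions()
        assert len(defs) == 6 + 4 + 2


class TestPSSM:
    def test_uniform_composition_equal_entries(self):
        s = sites_from("ACGT" * 5)
        # +4 cycles ACGT evenly; other positions constant
        m = build_pssm(s)
        row = m.matrix[m.positions.index(4)]
        assert np.allclose(row, row[0])

    def test_dominant_nucleotide_maximal(self):
        s = sites_from("A" * 9 + "C")
        m = build_pssm(s)
        row = m.matrix[m.positions.index(4)]
        assert np.argmax(row) == 0

    def test_counts_formula(self):
        s = sites_from("AAAT")
        m = build_pssm(s)
        assert m.score(4, "A") == pytest.approx(np.log2(3.5 / 6))
        assert m.score(4, "G") == pytest.approx(np.log2(0.5 / 6))


class TestU5U6:
    def test_scores_additive_and_hand_computed(self):
        toy = PSSM(
            PSSM_POSITIONS,
            np.tile(np.array([[0.0, -1.0, -2.0, -3.0]]), (8, 1)),
        )
        s = SpliceSiteMatrix.from_windows("sp", ["ACGGTAAGTAT"])
        u5, u6 = u5u6_scores(s, toy)
        # exon A,C,G -> 0 + -1 + -2; intron +3..+7 = A,A,G,T,A
        assert u5[0] == pytest.approx(-3.0)
        assert u6[0] == pytest.approx(0 + 0 - 2 - 3 + 0)

    def test_consensus_site_maximal(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGT"), 3)) + "GT" + "".join(rng.choice(list("ACGT"), 6)) for _ in range(40)]
        windows.append("AAGGTAAGTAT")  # will also be the modal site below
        windows += ["AAGGTAAGTAT"] * 30
        s = SpliceSiteMatrix.from_windows("sp", windows)
        pssm = build_pssm(s)
        u5, u6 = u5u6_scores(s, pssm)
        best = np.argmax(u5 + u6)
        assert s.donors[best].tolist() == list("AAGGTAAGTAT")

    def test_perfect_anticorrelation(self):
        # exon-majority sites (3x AAA) carry singleton intron letters, so
        # their U6 scores sit below the intron-majority pair: U5 and U6
        # ranks are exact mirrors and Spearman rho is -1
        exon = ["AAA"] * 3 + ["CCC"] * 2
        intron = ["GGGGGG", "TTTTTT", "CCCCCC", "AAAAAA", "AAAAAA"]
        rho, _ = u5u6_rho(mixture_sites(exon, intron), B=20, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        # exon-majority sites also share the intron-majority letter: ranks agree
        exon = ["AAA"] * 3 + ["CCC"] * 2
        intron = ["GGGGGG"] * 3 + ["AAAAAA", "TTTTTT"]
        rho, _ = u5u6_rho(mixture_sites(exon, intron), B=20, seed=0)
        assert rho == pytest.approx(1.0)

    def test_constant_scores_nan_with_warning(self):
        s = SpliceSiteMatrix.from_windows("sp", ["CAGGTAAGTAT"] * 5)
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = u5u6_rho(s, B=5, seed=0)
        assert np.isnan(rho)

    def test_additive_shift_invariance_exact(self):
        # dyadic-rational scores keep sums exact, so the rank correlation
        # is bitwise identical after any per-position shift
        rng = np.random.default_rng(7)
        windows = [
            "".join(rng.choice(list("ACGT"), 3)) + "GT" + "".join(rng.choice(list("ACGT"), 6))
            for _ in range(50)
        ]
        s = SpliceSiteMatrix.from_windows("sp", windows, gt_warn_fraction=0.0)
        pssm = PSSM(PSSM_POSITIONS, rng.integers(-40, 8, size=(8, 4)) / 8.0)
        shifted = PSSM(pssm.positions, pssm.matrix + rng.integers(-8, 8, size=(8, 1)) / 4.0)
        from scipy.stats import spearmanr

        r0 = spearmanr(*u5u6_scores(s, pssm)).statistic
        r1 = spearmanr(*u5u6_scores(s, shifted)).statistic
        assert r0 == pytest.approx(r1, abs=0)

    def test_planted_mixture_negative_rho(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            consensus_e, consensus_i = "AAG", "AAGTTA"
            windows = []
            for _ in range(120):
                u = rng.choice([0.9, 0.1])
                e = "".join(
                    c if rng.random() < u else str(rng.choice(list("ACGT")))
                    for c in consensus_e
                )
                i = "".join(
                    c if rng.random() < 1 - u else str(rng.choice(list("ACGT")))
                    for c in consensus_i
                )
                windows.append(e + "GT" + i)
            s = SpliceSiteMatrix.from_windows("sp", windows, gt_warn_fraction=0.0)
            rho, _ = u5u6_rho(s, B=10, seed=seed)
            wins += rho < 0
        assert wins >= 19
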