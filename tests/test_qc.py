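"""Hardy-Weinberg and linkage exact tests, Bonferroni, and locus retention."""

import itertools
import math

import numpy as np
import pytest

from hybridzone import GenotypeTable, bonferroni, hwe_exact_test, ld_test
from hybridzone.containers import MISSING
from hybridzone.qc import QCReport, flag_loci, hwe_scan
import pandas as pd


# ---------------------------------------------------------------------------
# Independent oracle: exact biallelic HWE distribution (Levene 1949)
# ---------------------------------------------------------------------------

def levene_pmf(n_a: int, n_b: int):
    """P(heterozygote count = H | allele counts) under random re-pairing."""
    n = (n_a + n_b) // 2
    out = {}
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        if n_aa < 0 or n_bb < 0:
            continue
        logp = (
            math.lgamma(n + 1) - math.lgamma(n_aa + 1) - math.lgamma(h + 1)
            - math.lgamma(n_bb + 1) + h * math.log(2)
            + math.lgamma(n_a + 1) + math.lgamma(n_b + 1) - math.lgamma(2 * n + 1)
        )
        out[h] = math.exp(logp)
    assert abs(sum(out.values()) - 1) < 1e-12
    return out


def biallelic_chisq(h: int, n_a: int, n_b: int) -> float:
    """The genotype-table chi-square as a function of the het count,
    derived independently of the implementation."""
    n = (n_a + n_b) // 2
    total = 2 * n
    denom = total * (total - 1)
    obs = {"aa": (n_a - h) / 2, "ab": h, "bb": (n_b - h) / 2}
    exp = {
        "aa": n * n_a * (n_a - 1) / denom,
        "ab": n * 2 * n_a * n_b / denom,
        "bb": n * n_b * (n_b - 1) / denom,
    }
    return sum((obs[g] - exp[g]) ** 2 / exp[g] for g in obs if exp[g] > 0)


def exact_hwe_p(pairs: np.ndarray) -> float:
    """Exhaustive-enumeration p over all distinct re-pairings (biallelic)."""
    h_obs = int((pairs[:, 0] != pairs[:, 1]).sum())
    n_a = int((pairs == 0).sum())
    n_b = int((pairs == 1).sum())
    stat_obs = biallelic_chisq(h_obs, n_a, n_b)
    pmf = levene_pmf(n_a, n_b)
    return sum(p for h, p in pmf.items()
               if biallelic_chisq(h, n_a, n_b) >= stat_obs - 1e-12)


class TestHweExact:
    def test_monomorphic_degenerate(self):
        pairs = np.zeros((10, 2), dtype=int)
        result = hwe_exact_test(pairs, n_permutations=99, seed=0)
        assert result.p_value == 1.0
        assert result.degenerate

    def test_all_missing_rejected(self):
        pairs = np.full((5, 2), MISSING)
        with pytest.raises(ValueError, match="missing"):
            hwe_exact_test(pairs, seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            hwe_exact_test(np.array([[0, 1], [0, 0]]))

    @pytest.mark.parametrize("case", [
        [(0, 1)] * 5 + [(0, 0)] * 3 + [(1, 1)] * 2,      # mild het excess
        [(0, 0)] * 5 + [(1, 1)] * 5,                     # complete het deficit
        [(0, 1)] * 10,                                   # complete het excess
        [(0, 0)] * 4 + [(0, 1)] * 4 + [(1, 1)] * 2,
    ])
    def test_matches_full_enumeration_biallelic(self, case):
        pairs = np.array(case)
        p_exact = exact_hwe_p(pairs)
        p_mc = hwe_exact_test(pairs, n_permutations=20_000, seed=11).p_value
        # Monte-Carlo standard error at B=20k
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert p_mc == pytest.approx(p_exact, abs=max(5 * se, 0.005))

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        pairs = rng.choice(3, size=(30, 2))
        relabeled = np.choose(pairs, [17, 4, 99])
        p1 = hwe_exact_test(pairs, n_permutations=999, seed=5).p_value
        p2 = hwe_exact_test(relabeled, n_permutations=999, seed=5).p_value
        assert p1 == p2

    def test_null_pvalues_roughly_uniform(self):
        # small-scale calibration; the full 5,000-locus check runs elsewhere
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(400):
            freqs = rng.dirichlet(np.full(6, 2.0))
            pairs = rng.choice(6, size=(50, 2), p=freqs)
            pvals.append(hwe_exact_test(pairs, n_permutations=199,
                                        seed=int(rng.integers(2 ** 31))).p_value)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= rate <= 0.09  # generous 400-replicate bound


class TestBonferroni:
    def test_threshold_arithmetic(self):
        result = bonferroni([0.001, 0.04], alpha=0.05, m=2)
        assert list(result["reject"]) == [True, False]

    def test_single_test_uncorrected(self):
        result = bonferroni([0.04], alpha=0.05, m=1)
        assert result["reject"][0]

    def test_never_rejects_p_at_or_above_alpha(self):
        for m in (1, 2, 10, 1000):
            result = bonferroni([0.05, 0.5, 0.999], alpha=0.05, m=m)
            assert not result["reject"].any()

    def test_empty_input(self):
        assert bonferroni([], alpha=0.05)["reject"].size == 0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni([0.01], alpha=1.5)


class TestLdTest:
    def _paired_loci(self, rng, n=20):
        locus = rng.choice(3, size=(n, 2))
        while len(np.unique(locus.min(axis=1) * 10 + locus.max(axis=1))) < 2:
            locus = rng.choice(3, size=(n, 2))
        return locus

    def test_perfect_association_minimal_p(self):
        rng = np.random.default_rng(4)
        locus_a = self._paired_loci(rng)
        result = ld_test(locus_a, locus_a.copy(), n_permutations=999, seed=1)
        assert result.p_value == pytest.approx(1 / 1000)

    def test_matches_enumeration_six_individuals(self):
        a = np.array([[0, 0], [0, 1], [1, 1], [0, 0], [0, 1], [1, 1]])
        b = np.array([[2, 2], [2, 3], [3, 3], [2, 2], [2, 2], [3, 3]])
        ia = np.array([0, 1, 2, 0, 1, 2])
        ib = np.array([0, 1, 2, 0, 0, 2])

        def g_of(perm):
            obs = np.zeros((3, 3))
            for x, y in zip(ia, ib[list(perm)]):
                obs[x, y] += 1
            row, col = obs.sum(1), obs.sum(0)
            exp = np.outer(row, col) / 6
            nz = obs > 0
            return 2 * (obs[nz] * np.log(obs[nz] / exp[nz])).sum()

        g_obs = g_of(range(6))
        exact = np.mean([g_of(p) >= g_obs - 1e-12
                         for p in itertools.permutations(range(6))])
        p_mc = ld_test(a, b, n_permutations=20_000, seed=2).p_value
        assert p_mc == pytest.approx(exact, abs=0.02)

    def test_monomorphic_degenerate(self):
        mono = np.zeros((10, 2), dtype=int)
        poly = np.array([[0, 1]] * 5 + [[0, 0]] * 5)
        assert ld_test(mono, poly, n_permutations=99, seed=0).degenerate

    def test_independent_loci_type_one_error(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_pairs = 250
        for _ in range(n_pairs):
            a = rng.choice(4, size=(40, 2))
            b = rng.choice(4, size=(40, 2))
            p = ld_test(a, b, n_permutations=199,
                        seed=int(rng.integers(2 ** 31))).p_value
            rejections += p < 0.05
        assert 0.02 <= rejections / n_pairs <= 0.09

    def test_joint_reordering_preserves_p_in_distribution(self):
        rng = np.random.default_rng(8)
        a = self._paired_loci(rng, n=40)
        b = self._paired_loci(rng, n=40)
        perm = rng.permutation(40)
        p1 = ld_test(a, b, n_permutations=2_000, seed=3).p_value
        p2 = ld_test(a[perm], b[perm], n_permutations=2_000, seed=3).p_value
        assert abs(p1 - p2) < 0.06  # same exact p, independent MC noise


class TestFlagLoci:
    def _report(self, pvals: pd.DataFrame, alpha=0.05):
        m = pvals.notna().sum().sum()
        return QCReport(hwe_pvalues=pvals, bonferroni_alpha=alpha / m,
                        alpha=alpha, family="all")

    def test_all_in_hwe_all_retained(self):
        pvals = pd.DataFrame(0.5, index=[f"p{i}" for i in range(13)],
                             columns=[f"L{j}" for j in range(14)])
        flags = flag_loci(self._report(pvals))
        assert len(flags["retained"]) == 14
        assert flags["dropped"] == []

    def test_widespread_failures_dropped(self):
        pvals = pd.DataFrame(0.5, index=[f"p{i}" for i in range(13)],
                             columns=[f"L{j}" for j in range(14)])
        pvals.loc[pvals.index[:8], "L0"] = 1e-6   # fails in 8 of 13 populations
        pvals.loc[pvals.index[:2], "L1"] = 1e-6   # fails in only 2: borderline
        flags = flag_loci(self._report(pvals), max_failing_populations=5)
        assert flags["dropped"] == ["L0"]
        assert flags["borderline"] == ["L1"]
        assert len(flags["retained"]) == 13


class TestHweScan:
    def test_planted_deficit_locus_flagged(self):
        # 14 loci x 8 populations; one locus generated with a strong
        # inbreeding-like heterozygote deficit in every population
        rng = np.random.default_rng(9)
        n_pop, n_per, n_loci = 8, 24, 14
        pops = np.repeat([f"pop{i}" for i in range(n_pop)], n_per)
        n_tot = n_pop * n_per
        calls = np.empty((n_tot, n_loci, 2), dtype=np.int64)
        for j in range(n_loci):
            freqs = rng.dirichlet(np.full(6, 2.0))
            if j == 0:  # the defective locus: F = 0.7 inbreeding analogue
                inbred = rng.random(n_tot) < 0.7
                hom = rng.choice(6, size=n_tot, p=freqs)
                pair = rng.choice(6, size=(n_tot, 2), p=freqs)
                calls[:, j, 0] = np.where(inbred, hom, pair[:, 0])
                calls[:, j, 1] = np.where(inbred, hom, pair[:, 1])
            else:
                calls[:, j, :] = rng.choice(6, size=(n_tot, 2), p=freqs)
        table = GenotypeTable(
            individuals=[f"i{i}" for i in range(n_tot)], populations=pops,
            loci=[f"L{j}" for j in range(n_loci)], calls=calls)
        report = hwe_scan(table, n_permutations=9_999, seed=1)
        flags = flag_loci(report, max_failing_populations=5)
        assert flags["dropped"] == ["L0"]
        assert len(flags["retained"]) == n_loci - 1
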