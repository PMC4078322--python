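"""Genotype quality control: Hardy-Weinberg and linkage-disequilibrium tests.

Both tests are conditional Monte-Carlo exact tests: the observed allele pool
is held fixed and the null distribution is generated by randomly re-pairing
alleles into genotypes (HWE) or permuting individuals at one locus (LD), the
exact conditional null under random mating / independent assortment. The
p-value convention is ``(1 + #{permuted >= observed}) / (1 + B)``.

The HWE statistic is the chi-square distance of the genotype-class counts
from their expectation under random re-pairing; for a biallelic locus this is
a monotone reordering of the classical heterozygote-count test, and for
multiallelic loci its near-continuous support keeps the Monte-Carlo p-value
calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, MISSING


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    degenerate: bool = False
    statistic: float = float("nan")
    n_used: int = 0

    def __float__(self) -> float:
        return self.p_value


def _clean_pairs(pairs: np.ndarray) -> np.ndarray:
    """Drop missing genotypes and recode alleles to 0..A-1."""
    pairs = np.asarray(pairs)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("genotypes must be an (n, 2) array of allele pairs")
    keep = ~(pairs == MISSING).any(axis=1)
    pairs = pairs[keep]
    if len(pairs) == 0:
        raise ValueError("all genotypes missing")
    _, coded = np.unique(pairs, return_inverse=True)
    return coded.reshape(pairs.shape)


def _genotype_class_expectations(pool_counts: np.ndarray, n_pairs: int) -> np.ndarray:
    """E[count of unordered genotype {a,b}] under random re-pairing.

    Drawing two alleles without replacement from the fixed pool of ``2n``:
    P{a,b} = 2 c_a c_b / (2n (2n-1)) for a != b, c_a (c_a - 1) / (2n (2n-1))
    for a == b; expectation is n times that. Returned as a flat (A, A) upper
    triangle matrix flattened with a < b indexing via a * A + b.
    """
    A = len(pool_counts)
    total = pool_counts.sum()
    exp = np.zeros(A * A)
    denom = total * (total - 1)
    for a in range(A):
        for b in range(a, A):
            if a == b:
                e = n_pairs * pool_counts[a] * (pool_counts[a] - 1) / denom
            else:
                e = n_pairs * 2 * pool_counts[a] * pool_counts[b] / denom
            exp[a * A + b] = e
    return exp


def _class_codes(pairs: np.ndarray, n_alleles: int) -> np.ndarray:
    lo = pairs.min(axis=-1)
    hi = pairs.max(axis=-1)
    return lo * n_alleles + hi


def _chisq(counts: np.ndarray, expected: np.ndarray) -> np.ndarray:
    mask = expected > 0
    diff = counts[..., mask] - expected[mask]
    return (diff * diff / expected[mask]).sum(axis=-1)


def hwe_exact_test(
    genotypes_at_locus: np.ndarray, n_permutations: int = 9_999, seed: int | None = None
) -> ExactTestResult:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus.

    The observed genotype-table chi-square (against the random-re-pairing
    expectation) is compared to tables formed by shuffling the observed
    allele pool and re-pairing. Requires an explicit seed. Monomorphic data
    give p = 1 with the degenerate flag set.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pairs = _clean_pairs(genotypes_at_locus)
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 non-missing individuals")
    pool = pairs.ravel()
    A = int(pool.max()) + 1
    if A == 1:
        return ExactTestResult(p_value=1.0, degenerate=True, n_used=n)
    pool_counts = np.bincount(pool, minlength=A)
    expected = _genotype_class_expectations(pool_counts, n)

    obs_counts = np.bincount(_class_codes(pairs, A), minlength=A * A)
    obs_stat = float(_chisq(obs_counts, expected))

    rng = np.random.default_rng(seed)
    B = n_permutations
    # shuffle the pool B times via argsort of uniforms, pair consecutive slots
    order = np.argsort(rng.random((B, 2 * n)), axis=1)
    shuffled = pool[order].reshape(B, n, 2)
    codes = _class_codes(shuffled, A) + np.arange(B)[:, None] * (A * A)
    counts = np.bincount(codes.ravel(), minlength=B * A * A).reshape(B, A * A)
    perm_stats = _chisq(counts, expected)

    p = (1 + int((perm_stats >= obs_stat - 1e-12).sum())) / (1 + B)
    return ExactTestResult(p_value=p, statistic=obs_stat, n_used=n)


def bonferroni(pvalues, alpha: float = 0.05, m: int | None = None) -> dict:
    """Bonferroni decisions: reject iff p < alpha / m.

    ``m`` defaults to the number of supplied p-values (the declared family).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return {"reject": np.zeros(0, dtype=bool), "threshold": np.nan, "m": 0}
    m = int(m) if m is not None else pvalues.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    threshold = alpha / m
    return {"reject": pvalues < threshold, "threshold": threshold, "m": m}


def ld_test(
    genotypes_locus_a: np.ndarray,
    genotypes_locus_b: np.ndarray,
    n_permutations: int = 9_999,
    seed: int | None = None,
) -> ExactTestResult:
    """Permutation test of genotypic association between two loci.

    Statistic: G-statistic of the two-locus genotype contingency table; null
    distribution by permuting which individual carries which genotype at the
    second locus. Either locus monomorphic gives p = 1 (degenerate).
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a = np.asarray(genotypes_locus_a)
    b = np.asarray(genotypes_locus_b)
    if a.shape != b.shape:
        raise ValueError("the two loci must cover the same individuals")
    keep = ~((a == MISSING).any(axis=1) | (b == MISSING).any(axis=1))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least 2 jointly non-missing individuals")

    def classes(pairs):
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        _, idx = np.unique(lo * (hi.max() + 1) + hi, return_inverse=True)
        return idx

    ia, ib = classes(a), classes(b)
    na, nb = ia.max() + 1, ib.max() + 1
    if na == 1 or nb == 1:
        return ExactTestResult(p_value=1.0, degenerate=True, n_used=len(a))

    n = len(ia)
    row = np.bincount(ia, minlength=na).astype(float)
    col = np.bincount(ib, minlength=nb).astype(float)
    expected = np.outer(row, col).ravel() / n

    def g_stat(ib_perm: np.ndarray) -> float:
        obs = np.bincount(ia * nb + ib_perm, minlength=na * nb).astype(float)
        nz = obs > 0
        return float(2.0 * (obs[nz] * np.log(obs[nz] / expected[nz])).sum())

    obs_g = g_stat(ib)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if g_stat(rng.permutation(ib)) >= obs_g - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return ExactTestResult(p_value=p, statistic=obs_g, n_used=n)


# ---------------------------------------------------------------------------
# Dataset-level scan and locus retention
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-(population, locus) HWE p-values and pairwise LD p-values."""

    hwe_pvalues: pd.DataFrame       # populations x loci
    bonferroni_alpha: float         # adjusted per-test threshold
    alpha: float
    family: str                     # "all" or "per_locus"
    ld_pvalues: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return self.hwe_pvalues < self.bonferroni_alpha


def hwe_scan(
    genotypes: GenotypeTable,
    n_permutations: int = 9_999,
    seed: int = 0,
    alpha: float = 0.05,
    family: str = "all",
    min_individuals: int = 5,
) -> QCReport:
    """HWE exact tests for every (population, locus) cell.

    The Bonferroni family is, by default, all tests jointly; ``family=
    "per_locus"`` corrects within each locus instead. Cells with fewer than
    ``min_individuals`` non-missing genotypes are skipped (NaN).
    """
    if family not in ("all", "per_locus"):
        raise ValueError("family must be 'all' or 'per_locus'")
    pops = list(dict.fromkeys(genotypes.populations))
    rows = {}
    notes = []
    rng = np.random.default_rng(seed)
    for pop in pops:
        idx = np.nonzero(genotypes.populations == pop)[0]
        row = {}
        for j, locus in enumerate(genotypes.loci):
            pairs = genotypes.calls[idx, j, :]
            n_ok = int((~(pairs == MISSING).any(axis=1)).sum())
            if n_ok < min_individuals:
                row[locus] = np.nan
                notes.append(f"skipped {pop}/{locus}: only {n_ok} genotypes")
                continue
            result = hwe_exact_test(pairs, n_permutations,
                                    seed=int(rng.integers(2 ** 31)))
            row[locus] = result.p_value
        rows[pop] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")[genotypes.loci]
    n_tests = int(frame.notna().sum().sum()) if family == "all" else int(frame.notna().sum().max())
    threshold = alpha / max(n_tests, 1)
    return QCReport(hwe_pvalues=frame, bonferroni_alpha=threshold,
                    alpha=alpha, family=family, notes=notes)


def ld_scan(
    genotypes: GenotypeTable, n_permutations: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Pairwise LD permutation tests across all locus pairs (pooled sample)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(genotypes.n_loci):
        for j in range(i + 1, genotypes.n_loci):
            res = ld_test(genotypes.calls[:, i, :], genotypes.calls[:, j, :],
                          n_permutations, seed=int(rng.integers(2 ** 31)))
            rows.append({"locus_a": genotypes.loci[i], "locus_b": genotypes.loci[j],
                         "p_value": res.p_value, "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def flag_loci(report: QCReport, max_failing_populations: int = 5) -> dict:
    """Partition loci into retained / dropped by HWE failure breadth.

    A locus is dropped when its Bonferroni-significant departures occur in
    more than ``max_failing_populations`` populations ("many"); loci failing
    in at least one but no more than that many populations are returned as
    the borderline set ("some") for sensitivity reruns.
    """
    sig = report.significant()
    failures = sig.sum(axis=0)
    dropped = [locus for locus, f in failures.items() if f > max_failing_populations]
    borderline = [locus for locus, f in failures.items()
                  if 0 < f <= max_failing_populations]
    retained = [locus for locus in report.hwe_pvalues.columns if locus not in dropped]
    return {"retained": retained, "dropped": dropped, "borderline": borderline,
            "failures_per_locus": failures.to_dict()}
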