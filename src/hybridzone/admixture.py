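"""Bayesian admixture inference for multiallelic genotypes.

The model is the standard admixture model used for unsupervised ancestry
estimation: each of an individual's allele copies originates from one of K
latent clusters, cluster k carries per-locus allele frequencies with a
Dirichlet(lambda) prior, and each individual has ancestry proportions q with
a symmetric Dirichlet(alpha) prior. Inference is collapsed-free Gibbs
sampling over (z, p, q); the per-individual posterior-mean Q vector is the
quantity consumed downstream (the "Q-score" at K = 2: the proportion of an
individual's genome assigned to one cluster).

Deliberate simplifications relative to the classic implementation: allele
frequencies are independent across clusters (lambda = 1) rather than the
correlated-frequencies prior, and alpha is fixed rather than sampled. The
default alpha = 0.1 approximates the small admixture parameter that
alpha-sampling implementations converge to for strongly structured
populations; with a flat alpha = 1 the Dirichlet prior alone pulls a pure
individual's posterior-mean Q about 1/(2 alpha + 2 L) away from its vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, MISSING
from scipy.optimize import linear_sum_assignment


@dataclass
class AdmixtureConfig:
    K: int = 2
    alpha: float = 0.1
    lam: float = 1.0
    burn_in: int = 5_000
    n_iter: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("alpha and lambda must be > 0")
        if self.burn_in < 0 or self.n_iter < 1:
            raise ValueError("burn_in must be >= 0 and n_iter >= 1")


@dataclass
class AdmixtureFit:
    """Posterior means from one admixture run."""

    q: np.ndarray                       # (n, K) posterior-mean ancestry
    allele_freqs: list[np.ndarray]      # per locus (K, A_l) posterior means
    loglik_trace: np.ndarray
    config: AdmixtureConfig
    individuals: list[str]
    loci: list[str]
    allele_labels: list[np.ndarray]     # original allele labels per locus

    def q_frame(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.q.shape[1])]
        return pd.DataFrame(self.q, index=self.individuals, columns=cols)


def _flatten_genotypes(genotypes: GenotypeTable):
    """Stack all non-missing allele copies into flat index arrays."""
    ind_idx, allele_flat, offsets, labels = [], [], [0], []
    for j in range(genotypes.n_loci):
        pairs = genotypes.calls[:, j, :]
        ok = ~(pairs == MISSING).any(axis=1)
        if ok.sum() == 0:
            raise ValueError(f"locus {genotypes.loci[j]} has zero observed alleles")
        uniq, coded = np.unique(pairs[ok], return_inverse=True)
        coded = coded.reshape(-1, 2)
        rows = np.nonzero(ok)[0]
        for copy in range(2):
            ind_idx.append(rows)
            allele_flat.append(coded[:, copy] + offsets[-1])
        offsets.append(offsets[-1] + len(uniq))
        labels.append(uniq)
    return (np.concatenate(ind_idx), np.concatenate(allele_flat),
            np.asarray(offsets), labels)


def fit_admixture(genotypes: GenotypeTable, config: AdmixtureConfig) -> AdmixtureFit:
    """Gibbs sampler for the admixture model; deterministic given the seed."""
    n = genotypes.n_individuals
    if n < 2:
        raise ValueError("need at least 2 individuals")
    K = config.K
    rng = np.random.default_rng(config.seed)
    ind_idx, allele_flat, offsets, labels = _flatten_genotypes(genotypes)
    M = len(ind_idx)               # total observed allele copies
    n_allele_slots = offsets[-1]
    locus_sizes = np.diff(offsets)

    if K == 1:
        q = np.ones((n, 1))
        freqs = []
        for j, A in enumerate(locus_sizes):
            counts = np.bincount(allele_flat[(allele_flat >= offsets[j])
                                             & (allele_flat < offsets[j + 1])] - offsets[j],
                                 minlength=A)
            post = (counts + config.lam)
            freqs.append((post / post.sum())[None, :])
        return AdmixtureFit(q=q, allele_freqs=freqs, loglik_trace=np.zeros(0),
                            config=config, individuals=list(genotypes.individuals),
                            loci=list(genotypes.loci), allele_labels=labels)

    # working state
    q = np.full((n, K), 1.0 / K)
    pf = np.full((K, n_allele_slots), 1.0)
    for j in range(genotypes.n_loci):
        pf[:, offsets[j]:offsets[j + 1]] = 1.0 / locus_sizes[j]

    copies_per_ind = np.bincount(ind_idx, minlength=n).astype(float)
    q_sum = np.zeros((n, K))
    pf_sum = np.zeros((K, n_allele_slots))
    ll_trace = np.empty(config.burn_in + config.n_iter)
    kept = 0

    for it in range(config.burn_in + config.n_iter):
        # -- z | q, p : responsibility of each cluster for each copy
        resp = q[ind_idx, :] * pf[:, allele_flat].T          # (M, K)
        norm = resp.sum(axis=1)
        ll_trace[it] = float(np.log(norm).sum())
        resp /= norm[:, None]
        u = rng.random(M)
        z = (u[:, None] > np.cumsum(resp, axis=1)).sum(axis=1)

        # -- p | z : Dirichlet(lam + counts) per (cluster, locus)
        counts_pf = np.bincount(z * n_allele_slots + allele_flat,
                                minlength=K * n_allele_slots).reshape(K, n_allele_slots)
        gam = rng.gamma(counts_pf + config.lam)
        for j in range(genotypes.n_loci):
            block = gam[:, offsets[j]:offsets[j + 1]]
            pf[:, offsets[j]:offsets[j + 1]] = block / block.sum(axis=1, keepdims=True)

        # -- q | z : Dirichlet(alpha + per-individual cluster counts)
        counts_q = np.bincount(ind_idx * K + z, minlength=n * K).reshape(n, K)
        gam_q = rng.gamma(counts_q + config.alpha)
        q = gam_q / gam_q.sum(axis=1, keepdims=True)

        if it >= config.burn_in:
            q_sum += q
            pf_sum += pf
            kept += 1

    q_mean = q_sum / kept
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    pf_mean = pf_sum / kept
    freqs = [pf_mean[:, offsets[j]:offsets[j + 1]].copy()
             for j in range(genotypes.n_loci)]
    return AdmixtureFit(q=q_mean, allele_freqs=freqs, loglik_trace=ll_trace,
                        config=config, individuals=list(genotypes.individuals),
                        loci=list(genotypes.loci), allele_labels=labels)


def align_labels(runs: list[np.ndarray | AdmixtureFit]) -> list[np.ndarray]:
    """Repair label switching across runs against the first run.

    Finds, per run, the cluster permutation minimising the summed |deltaQ| to
    the first run (optimal assignment; for K = 2 this is the exhaustive
    two-permutation check). Returns relabeled Q matrices.
    """
    mats = [run.q if isinstance(run, AdmixtureFit) else np.asarray(run) for run in runs]
    if not mats:
        return []
    ref = mats[0]
    out = [ref.copy()]
    for m in mats[1:]:
        if m.shape != ref.shape:
            raise ValueError("all runs must share the same individuals and K")
        cost = np.abs(ref[:, :, None] - m[:, None, :]).sum(axis=0)  # (K_ref, K_run)
        _, cols = linear_sum_assignment(cost)
        out.append(m[:, cols])
    return out


def site_mean_q(
    q: np.ndarray, site_labels, focal_cluster: int = 1,
    site_order: list | None = None,
) -> pd.DataFrame:
    """Per-site arithmetic mean (and variance) of the focal-cluster Q-score."""
    q = np.asarray(q)
    site_labels = np.asarray(site_labels)
    if len(site_labels) != len(q):
        raise ValueError("site labels must cover all individuals")
    frame = pd.DataFrame({"site": site_labels, "q": q[:, focal_cluster]})
    agg = frame.groupby("site", sort=True)["q"].agg(
        mean_q="mean", var_q=lambda s: s.var(ddof=1) if len(s) > 1 else 0.0, n="size")
    agg = agg.reset_index()
    if site_order is not None:
        present = [s for s in site_order if s in set(agg["site"])]
        empty = [s for s in site_order if s not in set(agg["site"])]
        if empty:
            import warnings

            warnings.warn(f"excluding empty site(s): {empty}", stacklevel=2)
        agg = agg.set_index("site").loc[present].reset_index()
    return agg


@dataclass
class ClusterNode:
    """One node of the successive-splitting hierarchy."""

    individuals: list[str]
    q: pd.DataFrame | None = None
    children: list["ClusterNode"] = field(default_factory=list)
    admixed: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_partition(self) -> dict[str, int]:
        return {ind: i for i, leaf in enumerate(self.leaves()) for ind in leaf.individuals}


def successive_split(
    genotypes: GenotypeTable,
    config: AdmixtureConfig,
    split_threshold: float = 0.80,
    min_assigned: float = 0.50,
    split_alpha: float | None = 1.0,
    _depth: int = 0,
    _max_depth: int = 8,
) -> ClusterNode:
    """Recursive K = 2 clustering until no further structure is found.

    At each node a K = 2 admixture fit is run; individuals with max-Q below
    ``split_threshold`` are set aside as admixed (they join neither child).
    The node splits only if, within each cluster, at least ``min_assigned`` of
    its members are confidently assigned, and both clusters are non-empty;
    otherwise it is a leaf. Nodes with fewer than 4 individuals are leaves.

    The split decision uses a flat ancestry prior (``split_alpha``, default
    1.0) regardless of ``config.alpha``: a vertex-seeking small alpha
    polarises even homogeneous groups into confident noise clusters, which
    would make the stopping rule fire never. Pass ``split_alpha=None`` to use
    ``config.alpha`` as-is.
    """
    node = ClusterNode(individuals=list(genotypes.individuals))
    if genotypes.n_individuals < 4 or _depth >= _max_depth:
        return node
    alpha = config.alpha if split_alpha is None else split_alpha
    cfg = AdmixtureConfig(K=2, alpha=alpha, lam=config.lam,
                          burn_in=config.burn_in, n_iter=config.n_iter,
                          seed=config.seed + _depth * 1_000)
    try:
        fit = fit_admixture(genotypes, cfg)
    except ValueError:
        return node  # e.g. a locus with zero observed alleles in this subset
    node.q = fit.q_frame()

    max_q = fit.q.max(axis=1)
    hard = fit.q.argmax(axis=1)
    confident = max_q >= split_threshold
    groups = []
    for k in (0, 1):
        members = hard == k
        if members.sum() == 0 or confident[members].mean() < min_assigned:
            return node  # no convincing split: stop here
        groups.append(np.nonzero(members & confident)[0])
    node.admixed = [genotypes.individuals[i] for i in np.nonzero(~confident)[0]]
    if any(len(g) == genotypes.n_individuals for g in groups):
        return node
    for g in groups:
        child_geno = genotypes.subset(g)
        node.children.append(successive_split(
            child_geno, config, split_threshold, min_assigned,
            split_alpha=split_alpha, _depth=_depth + 1, _max_depth=_max_depth))
    return node
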