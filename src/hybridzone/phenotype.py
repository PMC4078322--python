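"""Phenotype-ancestry association: correlation-matrix PCA and trait-on-Q OLS.

Reproduces the analysis design of the emulated study: morphometric traits are
summarised by principal components of their correlation matrix, and every
trait (univariate and PC) is regressed on the admixture Q-score at three
nested spatial extents (full sample, hybrid transect, core hybrid zone).
Plumage scores are ordinal 1-6 but treated as numeric, as in the original
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MORPHOMETRIC_TRAITS, PLUMAGE_TRAITS

EXTENT_FLAGS = {"all": "in_all", "transect": "in_transect", "core": "in_core"}


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # traits x components
    scores: pd.DataFrame            # rows x components (complete cases)
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    complete_index: pd.Index


def pca_correlation(traits: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of continuous traits.

    Traits are standardised (z-scored); components are eigenvectors of the
    correlation matrix ordered by decreasing eigenvalue, with the sign
    convention that each component's largest-magnitude loading is positive.
    """
    if traits.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    complete = traits.dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 complete rows")
    sd = complete.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant trait(s) with zero variance: {constant}")
    z = (complete - complete.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i_max = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    comp_names = [f"PC{j + 1}" for j in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=traits.columns, columns=comp_names)
    scores = pd.DataFrame(z.to_numpy() @ eigvecs, index=complete.index, columns=comp_names)
    return PCAResult(
        loadings=loadings, scores=scores, eigenvalues=eigvals,
        explained_variance_ratio=eigvals / eigvals.sum(),
        complete_index=complete.index,
    )


def significance_stars(p: float) -> str:
    """The conventional notation: * <0.05, ** <0.01, *** <0.001, else ns."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def regress_traits_on_q(
    table: pd.DataFrame, extent: str = "all", traits: list[str] | None = None
) -> pd.DataFrame:
    """OLS of each trait on the Q-score within one spatial extent.

    Returns per trait the R-squared, the two-sided slope p-value, the star
    notation, and n (complete cases per trait, not listwise). A subset with
    no Q variance yields "ns" rows flagged degenerate.
    """
    if extent not in EXTENT_FLAGS:
        raise ValueError(f"extent must be one of {sorted(EXTENT_FLAGS)}")
    flag = EXTENT_FLAGS[extent]
    sub = table[table[flag]] if flag in table.columns else table
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 rows in extent {extent!r}")
    if traits is None:
        traits = [t for t in (*MORPHOMETRIC_TRAITS, *PLUMAGE_TRAITS) if t in sub.columns]
    rows = []
    for trait in traits:
        pair = sub[[trait, "q_score"]].dropna()
        degenerate = len(pair) < 3 or pair["q_score"].nunique() < 2 or pair[trait].nunique() < 2
        if degenerate:
            rows.append({"trait": trait, "extent": extent, "r2": np.nan,
                         "p_value": np.nan, "stars": "ns", "n": len(pair),
                         "degenerate": True})
            continue
        fit = stats.linregress(pair["q_score"], pair[trait])
        rows.append({"trait": trait, "extent": extent, "r2": fit.rvalue ** 2,
                     "p_value": fit.pvalue, "stars": significance_stars(fit.pvalue),
                     "n": len(pair), "degenerate": False})
    return pd.DataFrame(rows)


def association_report(table: pd.DataFrame, n_morph_pcs: int = 3) -> pd.DataFrame:
    """Trait x extent R-squared report (the Table-1-shaped summary).

    Adds the first ``n_morph_pcs`` morphometric principal components as
    derived traits, then regresses every trait on Q at each spatial extent.
    """
    morph = table[list(MORPHOMETRIC_TRAITS)]
    work = table.copy()
    pc_names = []
    try:
        pca = pca_correlation(morph)
        for j in range(min(n_morph_pcs, pca.scores.shape[1])):
            name = f"morph_PC{j + 1}"
            work[name] = pca.scores[f"PC{j + 1}"].reindex(work.index)
            pc_names.append(name)
    except ValueError:
        pass  # not enough complete morphometric rows; report univariate only
    traits = [*MORPHOMETRIC_TRAITS, *pc_names, *PLUMAGE_TRAITS]
    pieces = [regress_traits_on_q(work, extent, traits) for extent in ("all", "transect", "core")]
    long = pd.concat(pieces, ignore_index=True)
    wide = long.pivot(index="trait", columns="extent", values=["r2", "stars"])
    return wide.reindex(traits)
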