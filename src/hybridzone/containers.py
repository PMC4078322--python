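"""Core in-memory containers shared across the pipeline stages.

The three tabular containers mirror the field's de-facto file dialects:
genotypes follow the Structure two-columns-per-locus convention with ``-9``
for missing data, transect sites carry per-site haplotype counts and ancestry
summaries, and phenotypes are a plain one-row-per-specimen table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call in the Structure dialect.
MISSING = -9


@dataclass
class GenotypeTable:
    """Diploid multiallelic calls for ``n`` individuals at ``L`` loci.

    Parameters
    ----------
    individuals
        Individual identifiers, length ``n``.
    populations
        Per-individual population/site label, length ``n``.
    loci
        Locus identifiers, length ``L``.
    calls
        Integer allele labels, shape ``(n, L, 2)``. Missing data are encoded
        as :data:`MISSING` in both slots of the pair; allele labels are
        arbitrary non-negative integers (e.g. fragment sizes).
    """

    individuals: list[str]
    populations: np.ndarray
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({n} individuals, {L} loci, 2)"
            )
        if len(self.populations) != n:
            raise ValueError("populations length does not match individuals")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing genotype pair; encode both alleles as -9")
        if ((self.calls < 0) & (self.calls != MISSING)).any():
            raise ValueError("negative allele label other than the -9 missing code")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask, True where the genotype is missing."""
        return (self.calls == MISSING).all(axis=2)

    def locus_calls(self, locus: int | str) -> np.ndarray:
        """Allele pairs ``(n, 2)`` at one locus (missing rows included)."""
        j = self.loci.index(locus) if isinstance(locus, str) else locus
        return self.calls[:, j, :]

    def subset(self, index: Sequence[int] | np.ndarray) -> "GenotypeTable":
        """New table restricted to the given individual indices."""
        index = np.asarray(index)
        return GenotypeTable(
            individuals=[self.individuals[i] for i in index],
            populations=self.populations[index],
            loci=list(self.loci),
            calls=self.calls[index],
        )

    def drop_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        keep = [j for j, name in enumerate(self.loci) if name not in set(loci)]
        return GenotypeTable(
            individuals=list(self.individuals),
            populations=self.populations.copy(),
            loci=[self.loci[j] for j in keep],
            calls=self.calls[:, keep, :],
        )


@dataclass
class TransectSites:
    """Ordered sampling sites along a one-dimensional transect.

    ``k_interior`` / ``n`` summarise the mtDNA restriction-typing counts per
    site; ``mean_q`` / ``var_q`` summarise per-site nuclear ancestry. Either
    summary may be absent (NaN) for a given analysis.
    """

    site_id: list[str]
    latitude: np.ndarray
    longitude: np.ndarray
    distance: np.ndarray
    n: np.ndarray
    k_interior: np.ndarray | None = None
    mean_q: np.ndarray | None = None
    var_q: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        self.n = np.asarray(self.n, dtype=np.int64)
        if np.any(np.diff(self.distance) < 0):
            raise ValueError("transect distances must be nondecreasing")
        if self.k_interior is not None:
            self.k_interior = np.asarray(self.k_interior, dtype=np.int64)
            if np.any(self.k_interior < 0) or np.any(self.k_interior > self.n):
                raise ValueError("k_interior must satisfy 0 <= k <= n")
        if self.mean_q is not None:
            self.mean_q = np.asarray(self.mean_q, dtype=float)
        if self.var_q is not None:
            self.var_q = np.asarray(self.var_q, dtype=float)

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    @property
    def span(self) -> float:
        return float(self.distance.max() - self.distance.min())

    def frequencies(self, data_kind: str) -> np.ndarray:
        """Observed per-site frequency of the interior class."""
        if data_kind == "mt_frequency":
            if self.k_interior is None:
                raise ValueError("site table has no mtDNA counts")
            return self.k_interior / np.maximum(self.n, 1)
        if data_kind == "q_mean":
            if self.mean_q is None:
                raise ValueError("site table has no mean Q-scores")
            return np.asarray(self.mean_q, dtype=float)
        raise ValueError(f"unknown data_kind {data_kind!r}")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "site_id": self.site_id,
            "latitude": self.latitude,
            "longitude": self.longitude,
            "distance": self.distance,
            "n": self.n,
        }
        for name in ("k_interior", "mean_q", "var_q"):
            value = getattr(self, name)
            if value is not None:
                data[name] = value
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransectSites":
        def col(name):
            return frame[name].to_numpy() if name in frame.columns else None

        return cls(
            site_id=[str(s) for s in frame["site_id"]],
            latitude=frame["latitude"].to_numpy(),
            longitude=frame["longitude"].to_numpy(),
            distance=frame["distance"].to_numpy(),
            n=frame["n"].to_numpy(),
            k_interior=col("k_interior"),
            mean_q=col("mean_q"),
            var_q=col("var_q"),
        )


#: Continuous morphometric traits (mm) and ordinal plumage scores (1-6).
MORPHOMETRIC_TRAITS = ("wing", "tail", "tarsus", "bill_length", "bill_depth", "bill_width")
PLUMAGE_TRAITS = ("collar", "vent", "eyestripe")
ALL_TRAITS = MORPHOMETRIC_TRAITS + PLUMAGE_TRAITS


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table contract and return the table unchanged.

    Expected columns: ``specimen_id``, the six morphometrics (positive, mm),
    the three 1-6 plumage scores, ``q_score`` in [0, 1], and boolean extent
    flags ``in_all`` / ``in_transect`` / ``in_core``.
    """
    required = {"specimen_id", "q_score", *ALL_TRAITS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    for trait in PLUMAGE_TRAITS:
        scores = table[trait].dropna()
        if not scores.isin(range(1, 7)).all():
            raise ValueError(f"plumage trait {trait!r} must be an integer score in 1-6")
    for trait in MORPHOMETRIC_TRAITS:
        vals = table[trait].dropna()
        if (vals <= 0).any():
            raise ValueError(f"morphometric trait {trait!r} must be positive")
    q = table["q_score"].dropna()
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q_score must lie in [0, 1]")
    return table
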