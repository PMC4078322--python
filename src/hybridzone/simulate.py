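"""Synthetic secondary-contact zones with known truth.

The generator imposes marker-specific cline widths directly (no forward-time
dynamics): expected nuclear ancestry follows one cline along the transect and
the maternally inherited haplotype frequency follows another, typically
narrower, one — the mito-nuclear discordance expected when hybrid females are
less fertile than hybrid males (Haldane's rule in a female-heterogametic
taxon). Individual ancestry is Beta-distributed around the local cline value,
genotypes are drawn from a mixture of two divergent parental allele pools,
and phenotypes are linear in ancestry plus noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .clines import ClineParams, cline_eval, EARTH_RADIUS_KM
from .containers import (
    ALL_TRAITS, GenotypeTable, MORPHOMETRIC_TRAITS, PLUMAGE_TRAITS, TransectSites,
)
from .rflp import DEFAULT_MOTIF, digest

#: Expected ancestry closer than this to 0 or 1 is clamped to exactly 0/1:
#: sites that far outside the zone are treated as fixed parental populations.
PARENTAL_CLAMP = 1e-3

#: Default per-trait (intercept, slope, residual sd). Plumage scores span the
#: 1-6 scale across the ancestry gradient with sub-category noise; the
#: morphometrics are ancestry-independent by default, matching the observed
#: pattern that plumage, not morphology, tracks ancestry inside the zone.
DEFAULT_PHENOTYPE_EFFECTS: dict[str, tuple[float, float]] = {
    "wing": (123.0, 0.0), "tail": (128.0, 0.0), "tarsus": (40.0, 0.0),
    "bill_length": (22.0, 0.0), "bill_depth": (10.5, 0.0), "bill_width": (8.5, 0.0),
    "collar": (1.0, 5.0), "vent": (1.0, 5.0), "eyestripe": (1.0, 5.0),
}
DEFAULT_PHENOTYPE_SD: dict[str, float] = {
    "wing": 3.5, "tail": 4.0, "tarsus": 1.2,
    "bill_length": 0.8, "bill_depth": 0.5, "bill_width": 0.4,
    "collar": 0.8, "vent": 0.8, "eyestripe": 0.8,
}


def default_cline_mt() -> ClineParams:
    return ClineParams(c=300.0, w=131.0)


def default_cline_nuc() -> ClineParams:
    return ClineParams(c=300.0, w=331.0)


@dataclass
class ZoneConfig:
    """Full specification of a synthetic secondary-contact dataset.

    Defaults mirror the emulated transect: 13 sites spanning 0-600 km, 13
    unlinked multiallelic loci, a ~131 km mtDNA cline and a ~331 km nuclear
    cline sharing a centre at 300 km, and strongly divergent parental allele
    pools. ``n_per_site`` may be an integer (applied to every site), an
    explicit per-site sequence, or the string ``"table-range"`` to draw site
    sizes uniformly from 1-28 as in the emulated sampling design.
    """

    n_sites: int = 13
    site_positions: np.ndarray | None = None
    n_per_site: int | str | Sequence[int] = 20
    n_loci: int = 13
    n_alleles_per_locus: int = 8
    divergence: float = 0.8
    cline_mt: ClineParams = field(default_factory=default_cline_mt)
    cline_nuc: ClineParams = field(default_factory=default_cline_nuc)
    nu: float = 10.0  # Beta concentration of within-site ancestry
    phenotype_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_EFFECTS))
    phenotype_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHENOTYPE_SD))
    core_window: tuple[float, float] = (200.0, 400.0)
    origin: tuple[float, float] = (41.55, -120.67)  # transect origin lat/lon
    bearing_deg: float = 135.0                      # NW -> SE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("configuration error: n_sites must be >= 1")
        if self.site_positions is None:
            self.site_positions = np.linspace(0.0, 600.0, self.n_sites)
        self.site_positions = np.asarray(self.site_positions, dtype=float)
        if len(self.site_positions) != self.n_sites:
            raise ValueError("configuration error: site_positions length != n_sites")
        if np.any(np.diff(self.site_positions) < 0):
            raise ValueError("configuration error: site_positions must be nondecreasing")
        if self.n_loci < 1:
            raise ValueError("configuration error: n_loci must be >= 1")
        if self.n_alleles_per_locus < 2:
            raise ValueError("configuration error: n_alleles_per_locus must be >= 2")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("configuration error: divergence must lie in [0, 1]")
        if not (self.nu > 0 or math.isinf(self.nu)):
            raise ValueError("configuration error: nu must be > 0 (or inf)")
        if isinstance(self.n_per_site, str) and self.n_per_site != "table-range":
            raise ValueError("configuration error: n_per_site string must be 'table-range'")
        if not isinstance(self.n_per_site, (int, str)):
            self.n_per_site = np.asarray(self.n_per_site, dtype=int)
            if len(self.n_per_site) != self.n_sites:
                raise ValueError("configuration error: n_per_site length != n_sites")
            if np.any(self.n_per_site < 1):
                raise ValueError("configuration error: n_per_site must be positive")
        elif isinstance(self.n_per_site, int) and self.n_per_site < 1:
            raise ValueError("configuration error: n_per_site must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["site_positions"] = list(map(float, self.site_positions))
        if isinstance(self.n_per_site, np.ndarray):
            d["n_per_site"] = list(map(int, self.n_per_site))
        for key in ("cline_mt", "cline_nuc"):
            d[key] = asdict(getattr(self, key))
        return d


@dataclass
class SyntheticDataset:
    """A simulated zone: genotypes, sites, truth, and derived tables."""

    genotypes: GenotypeTable
    sites: TransectSites
    mt_types: np.ndarray          # "coastal"/"interior" per individual
    q_true: np.ndarray            # true interior ancestry per individual
    phenotypes: pd.DataFrame
    truth: ZoneConfig
    parental_freqs: tuple[np.ndarray, np.ndarray]  # (coastal, interior), (L, A)
    sequences: dict[str, str] | None = None

    @property
    def site_labels(self) -> np.ndarray:
        return self.genotypes.populations


def _destination(lat: float, lon: float, bearing_deg: float, distance_km: float) -> tuple[float, float]:
    """Destination point along a constant bearing on a sphere."""
    delta = distance_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1, lmb1 = math.radians(lat), math.radians(lon)
    phi2 = math.asin(math.sin(phi1) * math.cos(delta)
                     + math.cos(phi1) * math.sin(delta) * math.cos(theta))
    lmb2 = lmb1 + math.atan2(math.sin(theta) * math.sin(delta) * math.cos(phi1),
                             math.cos(delta) - math.sin(phi1) * math.sin(phi2))
    return math.degrees(phi2), (math.degrees(lmb2) + 540) % 360 - 180


def parental_allele_frequencies(
    n_loci: int, n_alleles: int, divergence: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two parental allele-frequency pools with a controlled differential.

    Per locus a Dirichlet(1,...,1) base vector is drawn, plus two private
    components supported on disjoint allele halves; each pool mixes the base
    with its private component, ``pool = (1 - d) * base + d * private``. The
    total-variation distance between the pools is then exactly ``d`` in
    expectation structure (the private supports are disjoint), and ``d = 1``
    gives fully private alleles.
    """
    coastal = np.zeros((n_loci, n_alleles))
    interior = np.zeros((n_loci, n_alleles))
    half = n_alleles // 2
    for l in range(n_loci):
        base = rng.dirichlet(np.ones(n_alleles))
        e_coastal = np.zeros(n_alleles)
        e_interior = np.zeros(n_alleles)
        e_coastal[:half] = rng.dirichlet(np.ones(half)) if half > 1 else 1.0
        rest = n_alleles - half
        e_interior[half:] = rng.dirichlet(np.ones(rest)) if rest > 1 else 1.0
        coastal[l] = (1 - divergence) * base + divergence * e_coastal
        interior[l] = (1 - divergence) * base + divergence * e_interior
    return coastal, interior


def _draw_alleles(probs: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draws; probs (size, A) row-wise."""
    cdf = np.cumsum(probs, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random((size, 1))
    return (u > cdf).sum(axis=1)


def simulate_zone(config: ZoneConfig) -> SyntheticDataset:
    """Generate one synthetic secondary-contact dataset (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    positions = config.site_positions
    if isinstance(config.n_per_site, str):  # "table-range"
        site_n = rng.integers(1, 29, size=config.n_sites)
    elif isinstance(config.n_per_site, int):
        site_n = np.full(config.n_sites, config.n_per_site)
    else:
        site_n = np.asarray(config.n_per_site)

    site_ids = [f"site{str(i + 1).zfill(2)}" for i in range(config.n_sites)]
    site_index = np.repeat(np.arange(config.n_sites), site_n)
    n_total = int(site_n.sum())
    x_ind = positions[site_index]

    # --- true ancestry -----------------------------------------------------
    m = np.asarray(cline_eval(config.cline_nuc, x_ind))
    m = np.where(m < PARENTAL_CLAMP, 0.0, np.where(m > 1 - PARENTAL_CLAMP, 1.0, m))
    if math.isinf(config.nu):
        q_true = m.copy()
    else:
        q_true = np.empty(n_total)
        mid = (m > 0) & (m < 1)
        q_true[~mid] = m[~mid]
        q_true[mid] = rng.beta(m[mid] * config.nu, (1 - m[mid]) * config.nu)

    # --- genotypes ---------------------------------------------------------
    coastal, interior = parental_allele_frequencies(
        config.n_loci, config.n_alleles_per_locus, config.divergence, rng)
    calls = np.empty((n_total, config.n_loci, 2), dtype=np.int64)
    for l in range(config.n_loci):
        mix = q_true[:, None] * interior[l] + (1 - q_true)[:, None] * coastal[l]
        for copy in range(2):
            calls[:, l, copy] = _draw_alleles(mix, n_total, rng)
    loci = [f"L{str(l + 1).zfill(2)}" for l in range(config.n_loci)]
    individuals = [f"ind{str(i + 1).zfill(4)}" for i in range(n_total)]
    genotypes = GenotypeTable(
        individuals=individuals,
        populations=np.array([site_ids[s] for s in site_index]),
        loci=loci,
        calls=calls,
    )

    # --- mtDNA class -------------------------------------------------------
    p_mt = np.asarray(cline_eval(config.cline_mt, x_ind))
    is_interior = rng.random(n_total) < p_mt
    mt_types = np.where(is_interior, "interior", "coastal")

    # --- site table --------------------------------------------------------
    k_interior = np.bincount(site_index[is_interior], minlength=config.n_sites)
    mean_q = np.array([q_true[site_index == s].mean() for s in range(config.n_sites)])
    var_q = np.array([
        q_true[site_index == s].var(ddof=1) if site_n[s] > 1 else 0.0
        for s in range(config.n_sites)
    ])
    lats, lons = zip(*(
        _destination(*config.origin, config.bearing_deg, d) for d in positions
    ))
    sites = TransectSites(
        site_id=site_ids, latitude=np.array(lats), longitude=np.array(lons),
        distance=positions.copy(), n=site_n,
        k_interior=k_interior, mean_q=mean_q, var_q=var_q,
    )

    # --- phenotypes --------------------------------------------------------
    pheno = {"specimen_id": individuals, "site": genotypes.populations}
    for trait in ALL_TRAITS:
        intercept, slope = config.phenotype_effects[trait]
        sd = config.phenotype_sd[trait]
        value = intercept + slope * q_true + rng.normal(0, sd, n_total)
        if trait in PLUMAGE_TRAITS:
            value = np.clip(np.round(value), 1, 6).astype(int)
        pheno[trait] = value
    pheno["q_score"] = q_true
    pheno["in_all"] = np.ones(n_total, dtype=bool)
    pheno["in_transect"] = np.ones(n_total, dtype=bool)
    lo, hi = config.core_window
    pheno["in_core"] = (x_ind >= lo) & (x_ind <= hi)
    phenotypes = pd.DataFrame(pheno)

    return SyntheticDataset(
        genotypes=genotypes, sites=sites, mt_types=mt_types, q_true=q_true,
        phenotypes=phenotypes, truth=config, parental_freqs=(coastal, interior),
    )


# ---------------------------------------------------------------------------
# Amplicon sequences for the in-silico digest
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_clean_sequence(length: int, motif: str, rng: np.random.Generator,
                           max_tries: int = 1000) -> str:
    """Random sequence with zero motif occurrences on either strand."""
    for _ in range(max_tries):
        seq = "".join(rng.choice(_BASES, size=length))
        if digest(seq, motif).n_cut_sites == 0:
            return seq
    raise RuntimeError("could not generate a motif-free sequence; motif too short?")


def simulate_sequences(
    dataset: SyntheticDataset,
    motif: str = DEFAULT_MOTIF,
    length: int = 500,
    seed: int | None = None,
) -> SyntheticDataset:
    """Attach diagnostic amplicon sequences consistent with the mtDNA classes.

    Coastal individuals receive a sequence containing exactly one occurrence
    of ``motif`` (counting both strands); interior individuals receive a
    motif-free sequence. Deterministic given ``seed`` (defaults to the zone
    seed + 1).
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    if length <= len(motif):
        raise ValueError("length must exceed the motif length")
    rng = np.random.default_rng(dataset.truth.seed + 1 if seed is None else seed)
    sequences: dict[str, str] = {}
    for name, mt in zip(dataset.genotypes.individuals, dataset.mt_types):
        if mt == "interior":
            sequences[name] = _random_clean_sequence(length, motif, rng)
            continue
        for _ in range(1000):
            backbone = _random_clean_sequence(length - len(motif), motif, rng)
            pos = int(rng.integers(0, len(backbone) + 1))
            seq = backbone[:pos] + motif + backbone[pos:]
            if digest(seq, motif).n_cut_sites == 1:  # insertion junctions checked
                sequences[name] = seq
                break
        else:
            raise RuntimeError("could not place exactly one cut site")
    dataset.sequences = sequences
    return dataset
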