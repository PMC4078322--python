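"""Geographic cline models, likelihoods, MCMC fitting and model selection.

The cline family is the sigmoid-with-exponential-tails model standard in
hybrid-zone analysis: a central sigmoid of width ``w`` (inverse of the
maximum slope) and centre ``c``, optionally replaced beyond distances
``delta`` from the centre by exponential tails whose slope at the junction is
a fraction ``tau`` of the sigmoid slope, the whole shape scaled between
``p_min`` and ``p_max``. Fitting is by Metropolis-Hastings with a pilot-tuned
multivariate-normal proposal, model selection by AICc, and parameter support
by two-log-likelihood intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import TransectSites

TAIL_CONFIGS = ("none", "left", "right", "mirror", "both")
SCALINGS = ("fixed_none", "fixed_observed", "free")

EARTH_RADIUS_KM = 6371.0088
_EPS = 1e-9  # clamp for binomial probabilities


# ---------------------------------------------------------------------------
# Parameters and evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClineParams:
    """One point in the cline parameter space.

    ``tail_config`` selects which tails are active; ``scaling`` records how
    ``p_min``/``p_max`` were determined (irrelevant for evaluation, used for
    bookkeeping in model selection).
    """

    c: float
    w: float
    delta_l: float = 0.0
    delta_r: float = 0.0
    tau_l: float = 1.0
    tau_r: float = 1.0
    p_min: float = 0.0
    p_max: float = 1.0
    tail_config: str = "none"
    scaling: str = "fixed_none"

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("cline width w must be > 0")
        if self.tail_config not in TAIL_CONFIGS:
            raise ValueError(f"tail_config must be one of {TAIL_CONFIGS}")
        if self.scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}")
        if self.delta_l < 0 or self.delta_r < 0:
            raise ValueError("tail distances delta must be >= 0")
        if not (0 <= self.tau_l <= 1 and 0 <= self.tau_r <= 1):
            raise ValueError("tail slope ratios tau must lie in [0, 1]")
        if not (0 <= self.p_min <= self.p_max <= 1):
            raise ValueError("require 0 <= p_min <= p_max <= 1")
        if self.tail_config == "mirror" and (
            self.delta_l != self.delta_r or self.tau_l != self.tau_r
        ):
            raise ValueError("mirror tails require delta_l == delta_r and tau_l == tau_r")


def _sigmoid(u: np.ndarray) -> np.ndarray:
    # 1 / (1 + exp(-u)) without overflow warnings for large |u|
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def cline_eval(params: ClineParams, x) -> np.ndarray | float:
    """Expected interior-class frequency at transect position(s) ``x`` (km).

    Central sigmoid ``f(x) = 1 / (1 + exp(-4 (x - c) / w))``; an active left
    tail replaces it for ``x < c - delta_l`` by an exponential matched in
    value at the junction, with rate ``theta = (4 tau / w) / (1 + exp(-4
    delta / w))`` so the junction slope is exactly ``tau`` times the sigmoid
    slope there; the right tail is the mirror image. The composite shape is
    scaled to ``p_min + (p_max - p_min) * f``.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    c, w = params.c, params.w
    f = _sigmoid(4.0 * (x_arr - c) / w)

    cfg = params.tail_config
    if cfg in ("left", "mirror", "both"):
        d, tau = params.delta_l, params.tau_l
        left = x_arr < c - d
        if left.any():
            f_junction = float(_sigmoid(np.array([-4.0 * d / w]))[0])
            theta = (4.0 * tau / w) / (1.0 + math.exp(-min(4.0 * d / w, 700.0)))
            f[left] = f_junction * np.exp(theta * (x_arr[left] - c + d))
    if cfg in ("right", "mirror", "both"):
        d, tau = params.delta_r, params.tau_r
        right = x_arr > c + d
        if right.any():
            f_junction = float(_sigmoid(np.array([4.0 * d / w]))[0])
            theta = (4.0 * tau / w) / (1.0 + math.exp(-min(4.0 * d / w, 700.0)))
            f[right] = 1.0 - (1.0 - f_junction) * np.exp(-theta * (x_arr[right] - c - d))

    p = params.p_min + (params.p_max - params.p_min) * f
    return p if np.ndim(x) else float(p[0])


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _site_counts(sites: TransectSites, data_kind: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x, k, n) with zero-n sites excluded (with a warning)."""
    x = sites.distance
    n = sites.n
    if data_kind == "mt_frequency":
        if sites.k_interior is None:
            raise ValueError("mt_frequency likelihood needs k_interior counts")
        k = sites.k_interior.astype(float)
    elif data_kind == "q_mean":
        if sites.mean_q is None:
            raise ValueError("q_mean likelihood needs mean_q per site")
        # Mean Q-scores are fit with the same binomial machinery as haplotype
        # frequencies, via an effective success count.
        k = np.round(n * sites.mean_q)
    else:
        raise ValueError(f"unknown data_kind {data_kind!r}")
    keep = n > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} site(s) with n=0", stacklevel=3)
    if keep.sum() == 0:
        raise ValueError("no sites with n > 0")
    return x[keep].astype(float), k[keep], n[keep].astype(float)


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(const + k * np.log(p) + (n - k) * np.log1p(-p)))


def loglik(params: ClineParams, sites: TransectSites, data_kind: str) -> float:
    """Binomial log-likelihood of the site data under a cline.

    mtDNA data use the interior haplotype counts directly; mean Q-scores use
    an effective success count ``round(n * mean_q)`` so both marker classes
    share one likelihood.
    """
    x, k, n = _site_counts(sites, data_kind)
    return _binom_loglik(k, n, cline_eval(params, x))


def aicc(max_ll: float, k_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC: ``-2 ln L + 2k + 2k(k+1)/(n-k-1)``."""
    if n_obs <= k_params + 1:
        raise ValueError("AICc undefined: need n_obs > k_params + 1")
    return -2.0 * max_ll + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)


# ---------------------------------------------------------------------------
# Model templates: free-parameter packing and bounds
# ---------------------------------------------------------------------------

class ClineModel:
    """A cline model template: which parameters are free, and their bounds.

    Flat priors on the hard bounds below (span = transect extent):
    ``c`` in [min - span/2, max + span/2], ``w`` in (0, 2 span],
    ``delta`` in [0, span], ``tau`` in [0, 1], ``p_min``/``p_max`` in [0, 1]
    with ``p_min <= p_max`` enforced by rejection.
    """

    def __init__(self, tail_config: str, scaling: str, sites: TransectSites, data_kind: str):
        if tail_config not in TAIL_CONFIGS:
            raise ValueError(f"tail_config must be one of {TAIL_CONFIGS}")
        if scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}")
        self.tail_config = tail_config
        self.scaling = scaling
        self.data_kind = data_kind
        self._x, self._k, self._n = _site_counts(sites, data_kind)
        self._ll_const = float(
            np.sum(gammaln(self._n + 1) - gammaln(self._k + 1) - gammaln(self._n - self._k + 1))
        )

        lo, hi = float(self._x.min()), float(self._x.max())
        span = hi - lo
        names: list[str] = ["c", "w"]
        bounds: list[tuple[float, float]] = [(lo - span / 2, hi + span / 2), (1e-6, 2 * span)]
        if tail_config in ("left", "mirror", "both"):
            names += ["delta_l", "tau_l"]
            bounds += [(0.0, span), (0.0, 1.0)]
        if tail_config in ("right", "both"):
            names += ["delta_r", "tau_r"]
            bounds += [(0.0, span), (0.0, 1.0)]
        freqs = self._k / self._n
        if scaling == "free":
            names += ["p_min", "p_max"]
            bounds += [(0.0, 1.0), (0.0, 1.0)]
            self._fixed_pmin = self._fixed_pmax = None
        elif scaling == "fixed_observed":
            self._fixed_pmin = float(freqs.min())
            self._fixed_pmax = float(freqs.max())
        else:
            self._fixed_pmin, self._fixed_pmax = 0.0, 1.0
        self.param_names = names
        self.bounds = np.asarray(bounds, dtype=float)

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    @property
    def n_obs(self) -> int:
        return len(self._x)

    def unpack(self, theta: np.ndarray) -> ClineParams:
        kw = dict(zip(self.param_names, (float(t) for t in theta)))
        if self.tail_config == "mirror":
            kw["delta_r"] = kw["delta_l"]
            kw["tau_r"] = kw["tau_l"]
        if self.scaling != "free":
            kw["p_min"], kw["p_max"] = self._fixed_pmin, self._fixed_pmax
        return ClineParams(tail_config=self.tail_config, scaling=self.scaling, **kw)

    def in_bounds(self, theta: np.ndarray) -> bool:
        if np.any(theta < self.bounds[:, 0]) or np.any(theta > self.bounds[:, 1]):
            return False
        if self.scaling == "free":
            i, j = self.param_names.index("p_min"), self.param_names.index("p_max")
            if theta[i] > theta[j]:
                return False
        return True

    def loglik(self, theta: np.ndarray) -> float:
        """Fast path used inside MCMC; equals :func:`loglik` on unpacked params."""
        if not self.in_bounds(theta):
            return -np.inf
        p = np.clip(cline_eval(self.unpack(theta), self._x), _EPS, 1.0 - _EPS)
        return self._ll_const + float(
            np.sum(self._k * np.log(p) + (self._n - self._k) * np.log1p(-p))
        )

    def start_point(self, rng: np.random.Generator | None = None, jitter: float = 0.0) -> np.ndarray:
        """Heuristic start: centre at the 0.5-crossing, width span/4."""
        freqs = self._k / self._n
        # position where the empirical frequency first crosses its midrange
        mid = 0.5 * (freqs.min() + freqs.max())
        above = np.nonzero(freqs >= mid)[0]
        c0 = float(self._x[above[0]]) if len(above) else float(np.median(self._x))
        span = float(self._x.max() - self._x.min())
        defaults = {"c": c0, "w": span / 4, "delta_l": span / 8, "tau_l": 0.5,
                    "delta_r": span / 8, "tau_r": 0.5,
                    "p_min": max(float(freqs.min()), 0.0),
                    "p_max": min(float(freqs.max()), 1.0)}
        theta = np.array([defaults[name] for name in self.param_names])
        if rng is not None and jitter > 0:
            widths = self.bounds[:, 1] - self.bounds[:, 0]
            theta = theta + rng.normal(0, jitter, size=len(theta)) * widths
            theta = np.clip(theta, self.bounds[:, 0], self.bounds[:, 1])
            if self.scaling == "free":
                i, j = self.param_names.index("p_min"), self.param_names.index("p_max")
                if theta[i] > theta[j]:
                    theta[i], theta[j] = theta[j], theta[i]
        return theta


# ---------------------------------------------------------------------------
# Metropolis-Hastings fitting
# ---------------------------------------------------------------------------

@dataclass
class ClineFit:
    """Result of an MCMC cline fit."""

    model: ClineModel
    samples: pd.DataFrame           # one column per free parameter plus "ll"
    max_ll: float
    aicc: float
    point_estimate: ClineParams
    ci_2ll: dict[str, tuple[float, float]]
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def point(self) -> dict[str, float]:
        theta = self.samples.loc[self.samples["ll"].idxmax(), self.model.param_names]
        return {k: float(v) for k, v in theta.items()}


def _mh_chain(model: ClineModel, theta0: np.ndarray, chol: np.ndarray,
              n_iters: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    """One MH chain; returns (samples, lls, acceptance_rate)."""
    d = len(theta0)
    steps = rng.standard_normal((n_iters, d)) @ chol.T
    log_u = np.log(rng.random(n_iters))
    out = np.empty((n_iters, d))
    lls = np.empty(n_iters)
    theta, ll = theta0.copy(), model.loglik(theta0)
    accepted = 0
    for i in range(n_iters):
        prop = theta + steps[i]
        ll_prop = model.loglik(prop)
        if ll_prop - ll > log_u[i]:
            theta, ll = prop, ll_prop
            accepted += 1
        out[i] = theta
        lls[i] = ll
    return out, lls, accepted / n_iters


def _diagnostics(chains: list[np.ndarray], names: Sequence[str]) -> dict[str, dict[str, float]]:
    import arviz as az

    diag: dict[str, dict[str, float]] = {}
    min_len = min(len(ch) for ch in chains)
    stacked = np.stack([ch[:min_len] for ch in chains])  # (chain, draw, dim)
    for j, name in enumerate(names):
        arr = stacked[:, :, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag[name] = {
                "rhat": float(az.rhat(arr)),
                "ess": float(az.ess(arr)),
            }
    return diag


def fit_mh(
    sites: TransectSites,
    model_template: ClineModel | ClineParams | tuple[str, str],
    data_kind: str = "mt_frequency",
    tuning_iters: int = 10_000,
    chain_iters: int = 50_000,
    n_chains: int = 3,
    seed: int = 0,
    burn_fraction: float = 0.2,
    check_convergence: bool = True,
) -> ClineFit:
    """Fit one cline model by Metropolis-Hastings.

    A pilot run with an identity-scaled diagonal proposal estimates the
    proposal covariance; the main phase runs ``n_chains`` chains from
    overdispersed starts, discards ``burn_fraction`` of each and pools the
    rest. Flat priors on the hard bounds of :class:`ClineModel`. Deterministic
    given ``seed``.
    """
    if isinstance(model_template, ClineModel):
        model = model_template
    elif isinstance(model_template, ClineParams):
        model = ClineModel(model_template.tail_config, model_template.scaling, sites, data_kind)
    else:
        tail_config, scaling = model_template
        model = ClineModel(tail_config, scaling, sites, data_kind)
    if len(np.unique(model._x)) < 3:
        raise ValueError("need at least 3 distinct transect positions")
    if tuning_iters < 1 or chain_iters < 1 or n_chains < 1:
        raise ValueError("iteration and chain counts must be >= 1")

    rng = np.random.default_rng(seed)
    d = model.k_params
    widths = model.bounds[:, 1] - model.bounds[:, 0]

    theta0 = model.start_point()
    tries = 0
    while not np.isfinite(model.loglik(theta0)):
        tries += 1
        if tries > 100:
            raise RuntimeError("could not find a finite-likelihood start point")
        theta0 = model.start_point(rng, jitter=0.1)

    # Pilot: diagonal (identity-scaled) proposal with coarse scale adaptation.
    scale = 0.05
    pilot = np.empty((tuning_iters, d))
    block = max(tuning_iters // 10, 1)
    theta, done = theta0, 0
    total_acc = 0.0
    while done < tuning_iters:
        m = min(block, tuning_iters - done)
        chol = np.diag(scale * widths)
        seg, _, acc = _mh_chain(model, theta, chol, m, rng)
        pilot[done:done + m] = seg
        theta = seg[-1]
        total_acc += acc * m
        done += m
        # steer acceptance toward ~25% during the pilot only
        scale *= math.exp((acc - 0.25))
        scale = min(max(scale, 1e-4), 1.0)
    if total_acc == 0:
        raise RuntimeError(
            "all pilot proposals rejected; widen the parameter bounds or rescale the data"
        )
    keep = pilot[tuning_iters // 2:]
    cov = np.cov(keep, rowvar=False).reshape(d, d)
    cov = cov * (2.38 ** 2 / d) + np.diag((1e-6 * widths) ** 2)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.diag(cov)))

    # Main phase: overdispersed starts around the pilot's best point.
    best_pilot = keep[np.argmax([model.loglik(t) for t in keep[:: max(len(keep) // 200, 1)]])]
    chains, ll_chains = [], []
    burn = int(burn_fraction * chain_iters)
    for j in range(n_chains):
        start = best_pilot if j == 0 else model.start_point(rng, jitter=0.05)
        if not np.isfinite(model.loglik(start)):
            start = best_pilot
        samples, lls, _ = _mh_chain(model, start, chol, chain_iters, rng)
        chains.append(samples[burn:])
        ll_chains.append(lls[burn:])

    pooled = np.concatenate(chains)
    pooled_ll = np.concatenate(ll_chains)
    i_max = int(np.argmax(pooled_ll))
    max_ll = float(pooled_ll[i_max])
    point = model.unpack(pooled[i_max])

    frame = pd.DataFrame(pooled, columns=model.param_names)
    frame["ll"] = pooled_ll

    ci = {
        name: _ci_from_samples(pooled[:, j], pooled_ll, max_ll)
        for j, name in enumerate(model.param_names)
    }

    warns: list[str] = []
    diag: dict[str, dict[str, float]] = {}
    if check_convergence and n_chains >= 2:
        diag = _diagnostics(chains, model.param_names)
        for name, st in diag.items():
            if st["rhat"] > 1.05 or st["ess"] < 200:
                warns.append(
                    f"parameter {name}: rhat={st['rhat']:.3f} ess={st['ess']:.0f}"
                )
    if warns:
        warnings.warn("MCMC convergence check failed: " + "; ".join(warns), stacklevel=2)

    return ClineFit(
        model=model,
        samples=frame,
        max_ll=max_ll,
        aicc=aicc(max_ll, model.k_params, model.n_obs),
        point_estimate=point,
        ci_2ll=ci,
        diagnostics=diag,
        warnings=warns,
    )


def _ci_from_samples(values: np.ndarray, lls: np.ndarray, max_ll: float) -> tuple[float, float]:
    keep = lls >= max_ll - 2.0
    return float(values[keep].min()), float(values[keep].max())


def ci_2ll(fit: ClineFit, parameter: str) -> tuple[float, float]:
    """Two-log-likelihood support interval for one parameter.

    Min and max of the parameter over all retained samples whose
    log-likelihood is within 2 units of the maximum.
    """
    if parameter not in fit.model.param_names:
        raise KeyError(f"parameter {parameter!r} not in model ({fit.model.param_names})")
    return fit.ci_2ll[parameter]


# ---------------------------------------------------------------------------
# Null model and model selection
# ---------------------------------------------------------------------------

def fit_null(sites: TransectSites, data_kind: str) -> dict:
    """Closed-form ML fit of the no-cline (constant frequency) null model."""
    x, k, n = _site_counts(sites, data_kind)
    p_hat = float(k.sum() / n.sum())
    max_ll = _binom_loglik(k, n, np.full_like(x, p_hat))
    return {
        "tail_config": "null",
        "scaling": "null",
        "k_params": 1,
        "max_ll": max_ll,
        "aicc": aicc(max_ll, 1, len(x)),
        "p_hat": p_hat,
    }


#: Deterministic complexity order used for parsimony tie-breaking.
_MODEL_ORDER = [
    (scaling, tail)
    for scaling in SCALINGS
    for tail in TAIL_CONFIGS
]


@dataclass
class ModelSelection:
    table: pd.DataFrame
    fits: dict[tuple[str, str], ClineFit]
    null: dict
    winner: tuple[str, str] | str
    preferred: tuple[str, str] | str

    def best_fit(self, which: str = "preferred") -> ClineFit | None:
        key = self.preferred if which == "preferred" else self.winner
        return None if key == "null" else self.fits[key]


def model_select(
    sites: TransectSites,
    data_kind: str,
    seed: int = 0,
    tuning_iters: int = 10_000,
    chain_iters: int = 50_000,
    n_chains: int = 3,
    check_convergence: bool = False,
) -> ModelSelection:
    """Fit all 15 cline models (3 scaling sets x 5 tail configs) plus the null.

    Returns the AICc-ranked table, the raw AICc winner, and a
    "preferred-parsimony" model: the simplest model (fewest parameters,
    simplest scaling, simplest tails) whose AICc is within 2 units of the
    minimum. Individual model failures are recorded, not fatal.
    """
    rows = []
    fits: dict[tuple[str, str], ClineFit] = {}
    null = fit_null(sites, data_kind)
    rows.append({"scaling": "null", "tail_config": "null", "k_params": 1,
                 "max_ll": null["max_ll"], "aicc": null["aicc"], "error": ""})
    for i, (scaling, tail) in enumerate(_MODEL_ORDER):
        try:
            fit = fit_mh(
                sites, (tail, scaling), data_kind,
                tuning_iters=tuning_iters, chain_iters=chain_iters,
                n_chains=n_chains, seed=seed + 1 + i,
                check_convergence=check_convergence,
            )
        except Exception as exc:  # a failed model is recorded, not fatal
            rows.append({"scaling": scaling, "tail_config": tail, "k_params": np.nan,
                         "max_ll": np.nan, "aicc": np.nan, "error": str(exc)})
            continue
        fits[(scaling, tail)] = fit
        rows.append({"scaling": scaling, "tail_config": tail,
                     "k_params": fit.model.k_params, "max_ll": fit.max_ll,
                     "aicc": fit.aicc, "error": ""})
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()

    best = table.iloc[0]
    winner = "null" if best["scaling"] == "null" else (best["scaling"], best["tail_config"])

    # Parsimony rule: simplest model within 2 AICc of the minimum. Complexity
    # order: parameter count, then scaling set, then tail configuration.
    within = table[table["delta_aicc"] < 2.0]

    def complexity(row) -> tuple:
        if row["scaling"] == "null":
            return (row["k_params"], -1, -1)
        return (row["k_params"], SCALINGS.index(row["scaling"]),
                TAIL_CONFIGS.index(row["tail_config"]))

    simplest = min(within.to_dict("records"), key=complexity)
    preferred = ("null" if simplest["scaling"] == "null"
                 else (simplest["scaling"], simplest["tail_config"]))
    return ModelSelection(table=table, fits=fits, null=null, winner=winner, preferred=preferred)


# ---------------------------------------------------------------------------
# Cross-dataset comparison and transect projection
# ---------------------------------------------------------------------------

def reciprocal_nonoverlap(
    point_a: float, ci_a: tuple[float, float],
    point_b: float, ci_b: tuple[float, float],
) -> dict:
    """Reciprocal CI-exclusion significance rule.

    Two estimates differ significantly iff each point estimate falls outside
    the other's support interval (both directions must hold).
    """
    a_outside_b = not (ci_b[0] <= point_a <= ci_b[1])
    b_outside_a = not (ci_a[0] <= point_b <= ci_a[1])
    return {
        "significantly_different": a_outside_b and b_outside_a,
        "a_outside_ci_b": a_outside_b,
        "b_outside_ci_a": b_outside_a,
        "point_a": point_a, "ci_a": tuple(ci_a),
        "point_b": point_b, "ci_b": tuple(ci_b),
    }


def compare_clines(fit_a: ClineFit, fit_b: ClineFit, parameter: str) -> dict:
    """Apply the reciprocal CI rule to one parameter of two fitted clines."""
    point_a = getattr(fit_a.point_estimate, parameter)
    point_b = getattr(fit_b.point_estimate, parameter)
    return reciprocal_nonoverlap(point_a, ci_2ll(fit_a, parameter),
                                 point_b, ci_2ll(fit_b, parameter))


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points, km (Earth radius 6371.0088)."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def project_transect(
    latitudes: Sequence[float], longitudes: Sequence[float],
    anchor_order: Sequence[int] | None = None,
) -> np.ndarray:
    """Cumulative great-circle distance along an ordered chain of sites.

    ``anchor_order`` gives the site visiting order starting at the transect
    origin; by default sites are taken in the given order. Returned distances
    are in the *original* site order, with the origin at 0.
    """
    lats = np.asarray(latitudes, dtype=float)
    lons = np.asarray(longitudes, dtype=float)
    if len(lats) < 2:
        raise ValueError("need at least two sites to project a transect")
    order = np.arange(len(lats)) if anchor_order is None else np.asarray(anchor_order)
    cum = np.zeros(len(order))
    for i in range(1, len(order)):
        a, b = order[i - 1], order[i]
        cum[i] = cum[i - 1] + haversine_km(lats[a], lons[a], lats[b], lons[b])
    out = np.empty(len(lats))
    out[order] = cum
    return out
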