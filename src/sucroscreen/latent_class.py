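"""Bayesian two-population, three-test latent class model.

The Hui-Walter paradigm estimates the sensitivity and specificity of
several diagnostic tests applied to two (or more) populations with
different disease prevalence, without assuming any test is a gold
standard: the true disease state is a latent Bernoulli variable and the
observed binary test pattern is generated conditionally on it.

Here the three tests are blood sucrose at 45 min (T1), blood sucrose at
90 min (T2) and gastroscopy (T3), applied pre- and post-weaning. Because
T1 and T2 are the same assay sampled twice, they cannot be assumed
conditionally independent: the model carries one covariance term between
T1 and T2 among the diseased (``cov_se``) and one among the non-diseased
(``cov_sp``). Gastroscopy is taken as conditionally independent of the
sucrose pair given the latent state.

For population ``p`` with prevalence ``pi_p`` the probability of pattern
``(i, j, k)`` (1 = positive) is::

    P = pi_p * [se1^i (1-se1)^(1-i) se2^j (1-se2)^(1-j) + d(i,j) cov_se]
             * se3^k (1-se3)^(1-k)
      + (1-pi_p) * [(1-sp1)^i sp1^(1-i) (1-sp2)^j sp2^(1-j) + d(i,j) cov_sp]
             * (1-sp3)^k sp3^(1-k)

with ``d(i,j) = +1`` if ``i == j`` else ``-1``.  The covariances are
constrained to the rectangle on which all four joint two-test cells are
non-negative (:func:`cov_bounds`).

Inference is by random-walk Metropolis-within-Gibbs on the 10-parameter
vector, with Beta priors on the eight probabilities, uniform priors on the
covariances over their admissible range, and the identifiability anchor
``se3 + sp3 > 1`` (the latent class labelled "diseased" is the one
gastroscopy detects better than chance).  Convergence is assessed with
the Gelman-Rubin potential scale reduction factor; point estimates are
posterior medians with 2.5th-97.5th percentile probability intervals.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .priors import BetaPrior, PriorSet, elicited_priors

POPULATIONS = ("pre", "post")

#: Parameter order used throughout: prevalences, then (Se, Sp) per test
#: (sucrose 45, sucrose 90, gastroscopy), then the two covariances.
PARAM_NAMES = (
    "pi_pre", "pi_post",
    "se_s45", "sp_s45",
    "se_s90", "sp_s90",
    "se_endo", "sp_endo",
    "cov_se", "cov_sp",
)
_PROB_NAMES = PARAM_NAMES[:8]

# Test patterns (t1, t2, t3), t1 most significant: index = 4*t1 + 2*t2 + t3.
_PATTERNS = np.array([((i >> 2) & 1, (i >> 1) & 1, i & 1) for i in range(8)])
_B1 = _PATTERNS[:, 0].astype(bool)
_B2 = _PATTERNS[:, 1].astype(bool)
_B3 = _PATTERNS[:, 2].astype(bool)
_DELTA = np.where(_PATTERNS[:, 0] == _PATTERNS[:, 1], 1.0, -1.0)


def pattern_index(t1: int, t2: int, t3: int) -> int:
    """Cell index of pattern (t1, t2, t3) in the 8-cell table."""
    return 4 * int(t1) + 2 * int(t2) + int(t3)


def cov_bounds(p: float, q: float) -> tuple[float, float]:
    """Admissible range of the covariance between two Bernoulli indicators
    with marginal success probabilities ``p`` and ``q``.

    The bounds follow from non-negativity of the four joint cells:
    lower = max(-pq, -(1-p)(1-q)), upper = min(p(1-q), (1-p)q).  Zero is
    always interior, so conditional independence is always admissible.
    """
    if not (0.0 < p < 1.0 and 0.0 < q < 1.0):
        raise ValueError(f"marginals must be in (0, 1), got ({p}, {q})")
    lower = max(-p * q, -(1.0 - p) * (1.0 - q))
    upper = min(p * (1.0 - q), (1.0 - p) * q)
    return lower, upper


@dataclasses.dataclass(frozen=True)
class LCParameters:
    """Parameter vector of the two-population, three-test model."""

    pi_pre: float
    pi_post: float
    se_s45: float
    sp_s45: float
    se_s90: float
    sp_s90: float
    se_endo: float
    sp_endo: float
    cov_se: float = 0.0
    cov_sp: float = 0.0

    def __post_init__(self) -> None:
        for name in _PROB_NAMES:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        lo, hi = cov_bounds(self.se_s45, self.se_s90)
        if not (lo <= self.cov_se <= hi):
            raise ValueError(
                f"cov_se={self.cov_se} outside admissible [{lo:.4g}, {hi:.4g}]"
            )
        lo, hi = cov_bounds(self.sp_s45, self.sp_s90)
        if not (lo <= self.cov_sp <= hi):
            raise ValueError(
                f"cov_sp={self.cov_sp} outside admissible [{lo:.4g}, {hi:.4g}]"
            )
        if not self.se_endo + self.sp_endo > 1.0:
            raise ValueError("gastroscopy must be informative: se_endo + sp_endo > 1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "LCParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, theta))))


@dataclasses.dataclass(frozen=True)
class CrossClassifiedCounts:
    """2 populations x 8 test-pattern counts; the model's sufficient statistic.

    Row 0 is the pre-weaning population, row 1 post-weaning; columns are
    patterns (t1, t2, t3) in lexicographic order with t1 most significant.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 8):
            raise ValueError(f"counts must be 2x8, got shape {arr.shape}")
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, pop in enumerate(POPULATIONS):
            for c in range(8):
                t1, t2, t3 = _PATTERNS[c]
                rows.append({"population": pop, "t1": int(t1), "t2": int(t2),
                             "t3": int(t3), "count": int(self.counts[p, c])})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CrossClassifiedCounts":
        arr = np.zeros((2, 8), dtype=np.int64)
        for _, row in df.iterrows():
            p = POPULATIONS.index(str(row["population"]))
            arr[p, pattern_index(row["t1"], row["t2"], row["t3"])] += int(row["count"])
        return cls(arr)


def _cell_probs_raw(pi_pre, pi_post, se1, sp1, se2, sp2, se3, sp3,
                    cov_se, cov_sp) -> np.ndarray:
    """Unvalidated 2x8 cell probabilities; the sampler's hot path."""
    d = (np.where(_B1, se1, 1.0 - se1) * np.where(_B2, se2, 1.0 - se2)
         + _DELTA * cov_se) * np.where(_B3, se3, 1.0 - se3)
    h = (np.where(_B1, 1.0 - sp1, sp1) * np.where(_B2, 1.0 - sp2, sp2)
         + _DELTA * cov_sp) * np.where(_B3, 1.0 - sp3, sp3)
    out = np.empty((2, 8))
    out[0] = pi_pre * d + (1.0 - pi_pre) * h
    out[1] = pi_post * d + (1.0 - pi_post) * h
    return out


def cell_probabilities(params: LCParameters) -> np.ndarray:
    """2x8 table of pattern probabilities, one row per population.

    Each row sums to 1 and every cell is non-negative for any admissible
    parameter vector (the covariance bounds guarantee this).
    """
    theta = params.as_array()
    return _cell_probs_raw(*theta)


def log_likelihood(params: LCParameters, counts: CrossClassifiedCounts) -> float:
    """Multinomial log-likelihood of the cross-classified counts."""
    p = cell_probabilities(params)
    n = counts.counts
    mask = n > 0
    if np.any(p[mask] <= 0.0):
        return -math.inf
    return float(n[mask] @ np.log(p[mask]))


def _prior_arrays(priors: PriorSet) -> tuple[np.ndarray, np.ndarray]:
    """(alpha, beta) arrays aligned with the eight probability parameters."""
    d = priors.as_dict()
    order = ("prev_pre", "prev_post", "se_s45", "sp_s45",
             "se_s90", "sp_s90", "se_endo", "sp_endo")
    a = np.array([d[k].alpha for k in order], dtype=float)
    b = np.array([d[k].beta for k in order], dtype=float)
    return a, b


def log_posterior(params: LCParameters, counts: CrossClassifiedCounts,
                  priors: PriorSet) -> float:
    """Unnormalised log-posterior density.

    Beta log-densities on the eight probabilities plus uniform densities on
    the two covariances over their (parameter-dependent) admissible range;
    -inf outside the support, including when gastroscopy would be
    uninformative (se_endo + sp_endo <= 1).
    """
    theta = params.as_array()
    a, b = _prior_arrays(priors)
    lp = _log_post_raw(theta, counts.counts, a, b)
    return lp


def _log_post_raw(theta: np.ndarray, counts: np.ndarray,
                  a: np.ndarray, b: np.ndarray) -> float:
    pi1, pi2, se1, sp1, se2, sp2, se3, sp3, cse, csp = theta
    if se3 + sp3 <= 1.0:
        return -math.inf
    lo_se = max(-se1 * se2, -(1.0 - se1) * (1.0 - se2))
    hi_se = min(se1 * (1.0 - se2), (1.0 - se1) * se2)
    if not (lo_se <= cse <= hi_se):
        return -math.inf
    lo_sp = max(-sp1 * sp2, -(1.0 - sp1) * (1.0 - sp2))
    hi_sp = min(sp1 * (1.0 - sp2), (1.0 - sp1) * sp2)
    if not (lo_sp <= csp <= hi_sp):
        return -math.inf

    p = _cell_probs_raw(pi1, pi2, se1, sp1, se2, sp2, se3, sp3, cse, csp)
    mask = counts > 0
    pm = p[mask]
    if np.any(pm <= 0.0):
        return -math.inf
    ll = float(counts[mask] @ np.log(pm))

    p8 = theta[:8]
    lprior = float(np.sum((a - 1.0) * np.log(p8) + (b - 1.0) * np.log1p(-p8)
                          - betaln(a, b)))
    lprior -= math.log(hi_se - lo_se) + math.log(hi_sp - lo_sp)
    return ll + lprior


# ---------------------------------------------------------------------------
# MCMC


@dataclasses.dataclass(frozen=True)
class MCMCSchedule:
    """Sampling schedule: chains, burn-in, thinning, retained iterates.

    The full-length schedule (:func:`full_schedule`) discards 200,000
    burn-in iterations, retains every 10th iterate and keeps 40,000
    post-thinning iterates per chain.  The desk schedule
    (:func:`desk_schedule`) is a shorter profile (burn-in 20,000, keep
    4,000, thin 10, 3 chains) suitable for routine runs and testing.
    """

    n_chains: int = 3
    burn_in: int = 20_000
    thin: int = 10
    n_keep: int = 4_000
    seed: int = 0
    proposal_scales: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1 or self.burn_in < 0 or self.n_keep < 1:
            raise ValueError("invalid schedule")

    def replace(self, **kw) -> "MCMCSchedule":
        return dataclasses.replace(self, **kw)


def desk_schedule(seed: int = 0, n_chains: int = 3) -> MCMCSchedule:
    """Short profile: burn-in 20k, thin 10, 4k retained iterates per chain."""
    return MCMCSchedule(n_chains=n_chains, burn_in=20_000, thin=10,
                        n_keep=4_000, seed=seed)


def full_schedule(seed: int = 0, n_chains: int = 3) -> MCMCSchedule:
    """Full-length profile: burn-in 200k, thin 10, 40k retained per chain."""
    return MCMCSchedule(n_chains=n_chains, burn_in=200_000, thin=10,
                        n_keep=40_000, seed=seed)


@dataclasses.dataclass(frozen=True)
class PosteriorChains:
    """Retained MCMC iterates: per free parameter, an (n_chains, n_keep) array."""

    draws: Mapping[str, np.ndarray]
    schedule: MCMCSchedule
    acceptance: Mapping[str, np.ndarray]
    fixed: Mapping[str, float]

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.draws.keys())

    def pooled(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).ravel()


class InitializationError(RuntimeError):
    """All attempts to find a starting point with finite posterior failed."""


_DEFAULT_SCALES = {**{n: 0.35 for n in _PROB_NAMES},
                   "cov_se": 0.02, "cov_sp": 0.02}


def run_mcmc(counts: CrossClassifiedCounts, priors: PriorSet | None = None,
             schedule: MCMCSchedule | None = None,
             fixed: Mapping[str, float] | None = None) -> PosteriorChains:
    """Sample the posterior by random-walk Metropolis-within-Gibbs.

    Each of the 10 parameters is updated in turn with a Gaussian random
    walk: probabilities on the logit scale (with the change-of-variable
    Jacobian), covariances on the natural scale with proposals outside the
    admissible rectangle rejected through the prior support.  Proposal
    scales adapt toward ~44% acceptance during burn-in only and are frozen
    afterwards, so the post-burn-in kernel satisfies detailed balance.

    Chains start from independent draws from the priors (over-dispersed
    across chains); covariances start at 0.  ``fixed`` maps parameter
    names to values held constant (useful for reduced models and oracle
    checks).  Fully reproducible from ``schedule.seed``.
    """
    priors = priors if priors is not None else elicited_priors()
    schedule = schedule if schedule is not None else desk_schedule()
    fixed = dict(fixed or {})
    for k in fixed:
        if k not in PARAM_NAMES:
            raise ValueError(f"unknown fixed parameter {k!r}")
    free = [i for i, n in enumerate(PARAM_NAMES) if n not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")

    a, b = _prior_arrays(priors)
    n_arr = counts.counts
    scales0 = dict(_DEFAULT_SCALES)
    if schedule.proposal_scales:
        scales0.update(schedule.proposal_scales)

    n_iter = schedule.burn_in + schedule.thin * schedule.n_keep
    draws = {PARAM_NAMES[i]: np.empty((schedule.n_chains, schedule.n_keep))
             for i in free}
    acc_out = {PARAM_NAMES[i]: np.zeros(schedule.n_chains) for i in free}

    for c in range(schedule.n_chains):
        rng = np.random.default_rng([int(schedule.seed) % 2**31, c])
        theta = _initialize(rng, a, b, fixed, n_arr)
        x = np.array([logit(theta[i]) if i < 8 else theta[i] for i in range(10)])
        lp = _log_post_raw(theta, n_arr, a, b)
        # per-coordinate logit Jacobian term log(p(1-p)) for probabilities
        jac = np.array([math.log(theta[i] * (1 - theta[i])) if i < 8 else 0.0
                        for i in range(10)])
        ls = np.array([math.log(scales0[PARAM_NAMES[i]]) for i in range(10)])
        acc_total = np.zeros(10)
        acc_batch = np.zeros(10)
        batch = 0
        kept = 0
        normals = None
        for it in range(n_iter):
            # one batch of proposal innovations per iteration
            eps = rng.standard_normal(10)
            logu = np.log(rng.random(10))
            for i in free:
                xi_new = x[i] + math.exp(ls[i]) * eps[i]
                theta_new = theta.copy()
                if i < 8:
                    p_new = expit(xi_new)
                    if p_new <= 0.0 or p_new >= 1.0:
                        continue
                    theta_new[i] = p_new
                    jac_new = math.log(p_new * (1.0 - p_new))
                else:
                    theta_new[i] = xi_new
                    jac_new = 0.0
                lp_new = _log_post_raw(theta_new, n_arr, a, b)
                if lp_new == -math.inf:
                    continue
                if logu[i] < (lp_new + jac_new) - (lp + jac[i]):
                    theta = theta_new
                    x[i] = xi_new
                    jac[i] = jac_new
                    lp = lp_new
                    acc_total[i] += 1
                    acc_batch[i] += 1
            batch += 1
            if it < schedule.burn_in and batch == 50:
                # Robbins-Monro style scale adaptation, burn-in only
                step = min(0.1, 5.0 / math.sqrt(it + 1.0))
                for i in free:
                    ls[i] += step * (acc_batch[i] / 50.0 - 0.44)
                acc_batch[:] = 0.0
                batch = 0
            if it >= schedule.burn_in and (it - schedule.burn_in) % schedule.thin == 0:
                if kept < schedule.n_keep:
                    for i in free:
                        draws[PARAM_NAMES[i]][c, kept] = theta[i]
                    kept += 1
        for i in free:
            acc_out[PARAM_NAMES[i]][c] = acc_total[i] / n_iter

    return PosteriorChains(draws=draws, schedule=schedule,
                           acceptance=acc_out, fixed=fixed)


def _initialize(rng: np.random.Generator, a: np.ndarray, b: np.ndarray,
                fixed: Mapping[str, float], counts: np.ndarray,
                max_attempts: int = 100) -> np.ndarray:
    for _ in range(max_attempts):
        theta = np.empty(10)
        for i in range(8):
            name = PARAM_NAMES[i]
            theta[i] = fixed.get(name, rng.beta(a[i], b[i]))
            theta[i] = min(max(theta[i], 1e-6), 1.0 - 1e-6)
        theta[8] = fixed.get("cov_se", 0.0)
        theta[9] = fixed.get("cov_sp", 0.0)
        if math.isfinite(_log_post_raw(theta, counts, a, b)):
            return theta
    raise InitializationError(
        f"no finite starting point found in {max_attempts} prior draws"
    )


# ---------------------------------------------------------------------------
# Diagnostics and summaries


def gelman_rubin(chains, parameter: str | None = None):
    """Gelman-Rubin potential scale reduction factor.

    Accepts either a 2-D array (chains x iterations) or a
    :class:`PosteriorChains` (returning a dict keyed by parameter).  Values
    near 1 indicate the chains have mixed; NaN flags a degenerate input
    (zero within-chain variance).
    """
    if isinstance(chains, PosteriorChains):
        return {name: gelman_rubin(np.asarray(arr))
                for name, arr in chains.draws.items()}
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2) x n_iterations array")
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    means = arr.mean(axis=1)
    w = float(arr.var(axis=1, ddof=1).mean())
    if w == 0.0:
        return float("nan")
    bn = float(np.var(means, ddof=1))  # B/n
    v = (n - 1) / n * w + bn
    return math.sqrt(v / w)


@dataclasses.dataclass(frozen=True)
class ParameterSummary:
    median: float
    lower: float
    upper: float
    rhat: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.median <= self.upper):
            raise ValueError("interval must bracket the median")


@dataclasses.dataclass(frozen=True)
class PosteriorSummary:
    """Posterior medians, 95% probability intervals and R-hat per parameter."""

    parameters: Mapping[str, ParameterSummary]

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        rows = []
        for name, s in self.parameters.items():
            if percent and not name.startswith("cov"):
                rows.append({"parameter": name,
                             "median": round(100 * s.median),
                             "lower": round(100 * s.lower),
                             "upper": round(100 * s.upper),
                             "rhat": s.rhat})
            else:
                rows.append({"parameter": name, "median": s.median,
                             "lower": s.lower, "upper": s.upper,
                             "rhat": s.rhat})
        return pd.DataFrame(rows)

    def __getitem__(self, name: str) -> ParameterSummary:
        return self.parameters[name]


def summarize_posterior(chains: PosteriorChains) -> PosteriorSummary:
    """Pool retained iterates across chains; median and 2.5/97.5 percentiles.

    Percentiles use linear interpolation between order statistics.  The
    Gelman-Rubin statistic is attached per parameter (NaN with one chain).
    """
    if not chains.draws:
        raise ValueError("empty chains")
    out = {}
    for name, arr in chains.draws.items():
        arr = np.asarray(arr, dtype=float)
        pooled = arr.ravel()
        if pooled.size == 0:
            raise ValueError("empty chains")
        med = float(np.percentile(pooled, 50.0))
        lo = float(np.percentile(pooled, 2.5))
        hi = float(np.percentile(pooled, 97.5))
        if arr.ndim == 2 and arr.shape[0] >= 2:
            rh = gelman_rubin(arr)
        else:
            rh = float("nan")
        out[name] = ParameterSummary(median=med, lower=lo, upper=hi, rhat=rh)
    return PosteriorSummary(parameters=out)
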