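"""Bayesian posterior evaluation and sampling.

The posterior over the free parameters θ combines

* a Gaussian whole-trace likelihood,
  log L = -n/2·log(2πσ²) - Σᵢ (yᵢ - ŷᵢ(θ))² / (2σ²),
  with ŷ the simulated IKr at the bound sample times and σ either fixed
  (Point prior on ``obj:std``) or a free parameter;
* independent box-uniform priors; and
* a physiological *rate constraint* assigning zero probability to
  parameter sets whose transition rates leave a plausible window anywhere
  over the clamp voltage range.

Sampling follows the two-stage strategy of the adaptive-covariance MCMC
literature: a multi-start CMA-ES global optimisation picks the chain's
starting point, then an adaptive-covariance Metropolis sampler (the
Haario–Bardenet variant: exponentially forgetting mean/covariance
estimates and a global proposal scale steered toward 23.4% acceptance)
explores the posterior.  Because the rate parameters are positive scale
parameters spanning several decades within a common prior box, both
stages work on log-transformed coordinates by default (``transform=
"linear"`` disables this), and CMA-ES additionally profiles the
conductance out of its search: IKr is linear in GKr, so under the flat
prior the conditionally optimal conductance is a closed-form least-squares
coefficient (variable projection), reducing the global search by one
dimension and removing its strongest correlation.

The generic cores (:func:`cma_es_minimize`, :func:`adaptive_metropolis`)
accept arbitrary objectives/targets so they can be validated against
known test problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import HergfitError, ModelEvaluationError, SimulationError
from .fitting_io import FittingProblem
from .model import RateParameters, evaluate_rates

__all__ = [
    "ParameterVector",
    "RateConstraint",
    "PosteriorSample",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "cma_es_minimize",
    "cma_es_initialize",
    "adaptive_metropolis",
    "adaptive_mcmc",
    "run_inference",
]


@dataclass
class ParameterVector:
    """Ordered free-parameter values (prior-declaration order) plus the
    fixed (Point-prior) values carried alongside."""

    names: tuple[str, ...]
    values: np.ndarray
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values length must match names")


@dataclass(frozen=True)
class RateConstraint:
    """Physiological window for the four transition rates.

    A parameter set is admissible when, for each rate, its *maximum* over
    the voltage window [v_low, v_high] (attained at a window endpoint,
    since each rate is monotone in V) lies within [rate_min, rate_max]:
    the rate must be achievable somewhere in the window without ever
    becoming implausibly fast.  Defaults follow the conventional window of
    the whole-trace hERG fitting literature: V ∈ [-120, 60] mV, rates in
    [1.67e-5, 1000] ms⁻¹.
    """

    v_low: float = -120.0
    v_high: float = 60.0
    rate_min: float = 1.67e-5
    rate_max: float = 1000.0

    def __post_init__(self):
        if not self.v_low < self.v_high:
            raise ValueError("require v_low < v_high")
        if not 0 < self.rate_min < self.rate_max:
            raise ValueError("require 0 < rate_min < rate_max")

    def satisfied(self, params: RateParameters) -> bool:
        try:
            r_lo = evaluate_rates(params, self.v_low)
            r_hi = evaluate_rates(params, self.v_high)
        except ModelEvaluationError:
            return False
        for name in ("kO", "kC", "kI", "kA"):
            r_max = max(getattr(r_lo, name), getattr(r_hi, name))
            if not (self.rate_min <= r_max <= self.rate_max):
                return False
        return True


@dataclass
class PosteriorSample:
    """Retained MCMC output: post-burn-in chain (natural parameter units),
    per-sample log-posteriors, acceptance rate, seed, and the run's
    provenance (starting point, prior box, algorithm arguments)."""

    chain: np.ndarray  # (n_retained, d)
    log_posteriors: np.ndarray  # (n_retained,)
    acceptance_rate: float
    seed: int
    free_names: tuple[str, ...]
    theta0: Optional[np.ndarray] = None
    theta0_log_posterior: Optional[float] = None
    free_lower: Optional[np.ndarray] = None
    free_upper: Optional[np.ndarray] = None
    arguments: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chain = np.asarray(self.chain, dtype=float)
        self.log_posteriors = np.asarray(self.log_posteriors, dtype=float)
        if self.chain.shape[0] != self.log_posteriors.shape[0]:
            raise ValueError("chain and log_posteriors lengths differ")

    @property
    def n_retained(self) -> int:
        return self.chain.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            i = self.free_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; chain has {list(self.free_names)}"
            ) from None
        return self.chain[:, i]


# --------------------------------------------------------------------------
# Posterior pieces
# --------------------------------------------------------------------------

def log_likelihood(problem: FittingProblem, theta: np.ndarray) -> float:
    """Gaussian whole-trace log-likelihood; -inf on simulation failure."""
    theta = np.asarray(theta, dtype=float)
    sigma = problem.sigma(theta)
    if not (sigma > 0 and np.isfinite(sigma)):
        return -np.inf
    try:
        predicted = problem.simulate_currents(theta)
    except (SimulationError, ModelEvaluationError, ValueError):
        return -np.inf
    return _gaussian_loglik(problem.observed - predicted, sigma)


def _gaussian_loglik(residuals: np.ndarray, sigma: float) -> float:
    n = residuals.size
    return float(
        -0.5 * n * math.log(2.0 * math.pi * sigma * sigma)
        - float(residuals @ residuals) / (2.0 * sigma * sigma)
    )


def log_prior(problem: FittingProblem, theta: np.ndarray) -> float:
    """Box-uniform prior with the physiological rate-constraint assertion.

    -inf outside the prior box or the admissible-rate region; otherwise
    the constant -Σ log(upper - lower) over the free parameters.
    """
    theta = np.asarray(theta, dtype=float)
    lower, upper = problem.free_bounds()
    if theta.shape != lower.shape:
        raise ValueError(
            f"theta has dimension {theta.shape}, expected {lower.shape}"
        )
    if np.any(theta < lower) or np.any(theta > upper):
        return -np.inf
    try:
        params = problem.rate_parameters(theta)
    except ValueError:
        return -np.inf
    if not problem.rate_constraint.satisfied(params):
        return -np.inf
    return float(-np.sum(np.log(upper - lower)))


def log_posterior(problem: FittingProblem, theta: np.ndarray) -> float:
    """log prior + log likelihood; a -inf prior short-circuits the
    likelihood so no simulation is run for inadmissible parameters."""
    lp = log_prior(problem, theta)
    if not np.isfinite(lp):
        return -np.inf
    ll = log_likelihood(problem, theta)
    if not np.isfinite(ll):
        return -np.inf
    return lp + ll


# --------------------------------------------------------------------------
# CMA-ES
# --------------------------------------------------------------------------

class CmaResult:
    """Outcome of one CMA-ES run (coordinates in the caller's space)."""

    def __init__(self, x_best, f_best, mean, sigma, cov, n_evals):
        self.x_best = x_best
        self.f_best = f_best
        self.mean = mean
        self.sigma = sigma
        self.cov = cov
        self.n_evals = n_evals


def cma_es_minimize(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    max_fevals: int,
    rng: np.random.Generator,
    lower: Optional[np.ndarray] = None,
    upper: Optional[np.ndarray] = None,
    popsize: Optional[int] = None,
    tol_sigma: float = 1e-14,
    tol_stall_gens: Optional[int] = None,
) -> CmaResult:
    """Minimise ``f`` with the (μ/μ_w, λ) Covariance Matrix Adaptation
    Evolution Strategy (rank-1 + rank-μ update, cumulative step-size
    adaptation), with optional box constraints handled by resampling.

    Returns the best-ever evaluated point.  ``f`` may return +inf for
    rejected points (e.g. a zero-probability constraint region).  With
    ``tol_stall_gens`` set, the run stops early once the best value has
    not improved for that many consecutive generations (used by the
    multi-start initialiser to abandon flat basins and reinvest the
    remaining budget).
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    lam = popsize if popsize is not None else 4 + int(3 * math.log(d))
    mu = lam // 2
    w = math.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w = w / w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / d) / (d + 4 + 2 * mueff / d)
    cs = (mueff + 2) / (d + mueff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((d + 2) ** 2 + mueff))
    ds = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (d + 1)) - 1) + cs
    chi_n = math.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d * d))

    m = x0.copy()
    sigma = float(sigma0)
    C = np.eye(d)
    pc = np.zeros(d)
    ps = np.zeros(d)

    x_best = x0.copy()
    f_best = np.inf
    n_evals = 0
    gen = 0
    stall_gens = 0

    while n_evals < max_fevals and sigma > tol_sigma:
        if tol_stall_gens is not None and stall_gens >= tol_stall_gens:
            break
        # Eigendecomposition each generation (d is small here).
        C = (C + C.T) / 2.0
        eigvals, B = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        D = np.sqrt(eigvals)
        inv_sqrt_C = B @ np.diag(1.0 / D) @ B.T

        n_this = min(lam, max_fevals - n_evals)
        xs = np.empty((n_this, d))
        ys = np.empty((n_this, d))
        fs = np.empty(n_this)
        f_best_before = f_best
        for k in range(n_this):
            for _attempt in range(50):
                z = rng.standard_normal(d)
                y = B @ (D * z)
                x = m + sigma * y
                if lower is None or (np.all(x >= lower) and np.all(x <= upper)):
                    break
            else:
                x = np.clip(m + sigma * (B @ (D * rng.standard_normal(d))), lower, upper)
                y = (x - m) / sigma
            xs[k] = x
            ys[k] = y
            fs[k] = f(x)
            n_evals += 1
            if fs[k] < f_best:
                f_best = fs[k]
                x_best = x.copy()
        if n_this < lam:
            break  # budget exhausted mid-generation; best already tracked
        gen += 1
        improvement = f_best_before - f_best
        if np.isfinite(f_best) and improvement <= 1e-8 * max(abs(f_best), 1.0):
            stall_gens += 1
        else:
            stall_gens = 0

        order = np.argsort(fs)
        y_w = w @ ys[order[:mu]]
        m = m + sigma * y_w

        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mueff) * (inv_sqrt_C @ y_w)
        ps_norm = float(np.linalg.norm(ps))
        hsig = ps_norm / math.sqrt(1 - (1 - cs) ** (2 * gen)) / chi_n < 1.4 + 2 / (d + 1)
        pc = (1 - cc) * pc + (1.0 if hsig else 0.0) * math.sqrt(cc * (2 - cc) * mueff) * y_w

        rank_mu = sum(w[j] * np.outer(ys[order[j]], ys[order[j]]) for j in range(mu))
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (0.0 if hsig else 1.0) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma = sigma * math.exp((cs / ds) * (ps_norm / chi_n - 1))
        if not np.all(np.isfinite(C)) or not np.isfinite(sigma):
            break

    return CmaResult(x_best, f_best, m, sigma, C, n_evals)


class _SearchSpace:
    """Maps CMA-ES unit-box coordinates to free-parameter vectors,
    optionally on a log scale and with the conductance profiled out."""

    def __init__(self, problem: FittingProblem, transform: str, profile_conductance: bool):
        self.problem = problem
        lower, upper = problem.free_bounds()
        self.lower, self.upper = lower, upper
        names = problem.free_names
        if transform == "log" and np.any(lower <= 0):
            transform = "linear"  # log scale needs strictly positive bounds
        self.transform = transform

        self.g_index: Optional[int] = None
        if profile_conductance and "GKr" in names:
            self.g_index = names.index("GKr")
        self.search_idx = [i for i in range(len(names)) if i != self.g_index]
        lo = lower[self.search_idx]
        hi = upper[self.search_idx]
        if transform == "log":
            self.a = np.log(lo)
            self.span = np.log(hi) - self.a
        else:
            self.a = lo
            self.span = hi - lo

    @property
    def dim(self) -> int:
        return len(self.search_idx)

    def theta_from_u(self, u: np.ndarray, g_value: float) -> np.ndarray:
        vals = self.a + self.span * u
        if self.transform == "log":
            vals = np.exp(vals)
        theta = np.empty(len(self.problem.free_names))
        theta[self.search_idx] = vals
        if self.g_index is not None:
            theta[self.g_index] = g_value
        return theta

    def objective(self, u: np.ndarray) -> tuple[float, Optional[np.ndarray]]:
        """-log posterior at the expanded point, with GKr at its
        conditionally optimal (profiled) value when enabled."""
        problem = self.problem
        if self.g_index is None:
            theta = self.theta_from_u(u, np.nan)
            lp = log_posterior(problem, theta)
            return (-lp if np.isfinite(lp) else np.inf), theta
        # variable projection: simulate the GKr=1 basis once, then solve
        # the 1-D least-squares for the conductance in closed form
        theta1 = self.theta_from_u(u, 1.0)
        glo = self.lower[self.g_index]
        ghi = self.upper[self.g_index]
        lp_prior = log_prior(problem, np.clip(theta1, self.lower, self.upper))
        if not np.isfinite(lp_prior):
            return np.inf, None
        try:
            basis = problem.simulate_currents(theta1)
        except (SimulationError, ModelEvaluationError, ValueError):
            return np.inf, None
        bb = float(basis @ basis)
        if not (np.isfinite(bb) and bb > 0):
            return np.inf, None
        g = float(problem.observed @ basis) / bb
        g = min(max(g, glo), ghi)
        theta = self.theta_from_u(u, g)
        sigma = problem.sigma(theta)
        if not (sigma > 0 and np.isfinite(sigma)):
            return np.inf, theta
        ll = _gaussian_loglik(problem.observed - g * basis, sigma)
        lp = lp_prior + ll
        return (-lp if np.isfinite(lp) else np.inf), theta


def cma_es_initialize(
    problem: FittingProblem,
    restarts: int,
    max_fevals: int,
    seed: int,
    sigma0: float = 1.0 / 6.0,
    popsize: int = 6,
    n_screen: int = 100,
    transform: str = "log",
    profile_conductance: bool = True,
    budget_per_restart: bool = True,
) -> tuple[np.ndarray, CmaResult, "_SearchSpace"]:
    """Choose an MCMC starting point by multi-start CMA-ES on
    -log posterior.

    Runs ``restarts`` independent CMA-ES searches, each budgeted
    ``max_fevals`` objective evaluations (set ``budget_per_restart=False``
    to split a total budget equally instead).  Each restart screens
    ``n_screen`` admissible uniform prior draws — counted against its
    budget — and starts from the best, in unit-box coordinates of the
    (by default log-scaled) prior box with initial step ``sigma0``.
    The conductance is profiled out of the search by default (see module
    docstring).  Returns the best point found overall, its
    :class:`CmaResult` (search-space covariance; used to seed the MCMC
    proposal) and the search-space mapping.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    space = _SearchSpace(problem, transform, profile_conductance)
    d = space.dim

    best: Optional[CmaResult] = None
    best_theta: Optional[np.ndarray] = None
    budget = int(max_fevals) if budget_per_restart else max(1, int(max_fevals) // int(restarts))

    master = np.random.SeedSequence(seed)
    for child in master.spawn(restarts):
        rng = np.random.default_rng(child)
        used = 0
        candidates: list[np.ndarray] = []
        scores: list[float] = []
        thetas: list[np.ndarray] = []
        screen = min(n_screen, max(budget // 4, 1))
        while len(candidates) < screen and used < max(3 * screen, 10):
            u = rng.uniform(0.0, 1.0, size=d)
            value, theta = space.objective(u)
            used += 1
            if np.isfinite(value):
                candidates.append(u)
                scores.append(value)
                thetas.append(theta)
        if not candidates:
            continue
        order = list(np.argsort(scores))
        trace: dict = {"f": scores[order[0]], "theta": thetas[order[0]]}

        def f(u, _trace=trace):
            value, theta = space.objective(u)
            if theta is not None and value < _trace.get("f", np.inf):
                _trace["f"] = value
                _trace["theta"] = theta
            return value

        # Run from the best screened start; if the search stalls (e.g. a
        # flat basin where the channel barely conducts) with budget left,
        # reinvest it from the next-best unused candidate.
        result: Optional[CmaResult] = None
        while order and (result is None or used < budget - 200):
            u0 = candidates[order.pop(0)]
            run = cma_es_minimize(
                f,
                u0,
                sigma0,
                budget - used,
                rng,
                lower=np.zeros(d),
                upper=np.ones(d),
                popsize=popsize,
                tol_stall_gens=60,
            )
            used += run.n_evals
            if result is None or run.f_best < result.f_best:
                result = run
        if result is None:
            continue
        result.f_best = trace["f"]
        if best is None or result.f_best < best.f_best:
            best = result
            best_theta = trace.get("theta")

    if best is None or best_theta is None or not np.isfinite(best.f_best):
        raise HergfitError(
            "all CMA-ES restarts ended with zero posterior probability; "
            "review the prior bounds and rate constraint"
        )
    # Search covariance in (log-)parameter coordinates of the searched dims.
    scale = np.diag(space.span)
    best.cov = scale @ (best.sigma**2 * best.cov) @ scale
    best.x_best = best_theta
    return best_theta, best, space


# --------------------------------------------------------------------------
# Adaptive-covariance Metropolis (Haario–Bardenet variant)
# --------------------------------------------------------------------------

def adaptive_metropolis(
    log_target: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    n_iters: int,
    burn: int,
    rng: np.random.Generator,
    initial_cov: np.ndarray,
    adapt_start: int = 200,
    eta: float = 0.6,
    target_acceptance: float = 0.234,
    jitter: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Adaptive-covariance Metropolis on an arbitrary log target.

    Proposals are N(x, 2.38²/d · λₜ · (Σₜ + jitter·diag(initial_cov))).
    After ``adapt_start`` iterations the mean/covariance estimates (μₜ, Σₜ)
    and the global scale λₜ adapt with exponentially decaying weights
    γₜ = t^-eta, the scale steered toward the target acceptance rate
    (Haario–Bardenet).  Before that, Σ is held at ``initial_cov`` and
    λ = 1.  Out-of-support proposals (log target = -inf) are rejected and
    counted in the acceptance rate.

    Returns (retained chain, retained log targets, acceptance rate).
    """
    theta0 = np.asarray(theta0, dtype=float)
    d = theta0.size
    if not n_iters > burn >= 0:
        raise ValueError("require n_iters > burn >= 0")
    lp = float(log_target(theta0))
    if not np.isfinite(lp):
        raise ValueError("theta0 must have finite log target")

    base = 2.38**2 / d
    initial_cov = np.asarray(initial_cov, dtype=float)
    floor = jitter * np.diag(np.diag(initial_cov))

    chain = np.empty((n_iters, d))
    lps = np.empty(n_iters)

    x = theta0.copy()
    mean = x.copy()
    cov = initial_cov.copy()
    log_lambda = 0.0
    n_accept = 0
    chol = _safe_cholesky(base * (cov + floor))
    dirty = False

    for t in range(n_iters):
        if dirty:
            chol = _safe_cholesky(base * math.exp(log_lambda) * (cov + floor))
            dirty = False
        prop = x + chol @ rng.standard_normal(d)
        lpp = float(log_target(prop))
        accepted = np.isfinite(lpp) and math.log(rng.uniform()) < lpp - lp
        if accepted:
            x = prop
            lp = lpp
            n_accept += 1
        chain[t] = x
        lps[t] = lp
        if t >= adapt_start:
            gamma = (t - adapt_start + 1) ** (-eta)
            delta = x - mean
            mean = mean + gamma * delta
            cov = cov + gamma * (np.outer(delta, delta) - cov)
            log_lambda += gamma * ((1.0 if accepted else 0.0) - target_acceptance)
            dirty = True

    return chain[burn:], lps[burn:], n_accept / n_iters


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky with escalating diagonal regularisation."""
    d = cov.shape[0]
    eps = 0.0
    base = max(np.trace(cov) / d, 1e-300)
    for _ in range(12):
        try:
            return np.linalg.cholesky(cov + eps * np.eye(d))
        except np.linalg.LinAlgError:
            eps = base * 1e-12 if eps == 0.0 else eps * 100.0
    raise np.linalg.LinAlgError("covariance not positive definite")


def adaptive_mcmc(
    problem: FittingProblem,
    theta0: np.ndarray,
    num_iters: int,
    burn: int,
    seed: int,
    initial_cov: Optional[np.ndarray] = None,
    transform: str = "log",
) -> PosteriorSample:
    """Sample the fitting problem's posterior by adaptive-covariance
    Metropolis.

    With ``transform="log"`` (default; requires a positive prior box) the
    chain runs on φ = log θ with the Jacobian-corrected target
    log π(θ(φ)) + Σφ, and ``initial_cov`` is interpreted in φ-space; the
    returned chain and log-posteriors are in natural θ units either way.
    The default ``initial_cov`` is diagonal with (1% of each prior range)²
    in the sampling coordinates.  ``theta0`` must have finite posterior
    (use :func:`cma_es_initialize`).
    """
    lower, upper = problem.free_bounds()
    theta0 = np.asarray(theta0, dtype=float)
    lp0 = log_posterior(problem, theta0)
    if not np.isfinite(lp0):
        raise ValueError("theta0 has zero posterior probability")
    if transform == "log" and np.any(lower <= 0):
        transform = "linear"
    rng = np.random.default_rng(seed)

    if transform == "log":
        log_span = np.log(upper) - np.log(lower)
        if initial_cov is None:
            initial_cov = np.diag((0.01 * log_span) ** 2)

        def target(phi: np.ndarray) -> float:
            lp = log_posterior(problem, np.exp(phi))
            return lp + float(phi.sum()) if np.isfinite(lp) else -np.inf

        phi_chain, phi_lps, acc = adaptive_metropolis(
            target, np.log(theta0), int(num_iters), int(burn), rng, initial_cov
        )
        chain = np.exp(phi_chain)
        lps = phi_lps - phi_chain.sum(axis=1)  # back to θ-space densities
    else:
        if initial_cov is None:
            initial_cov = np.diag((0.01 * (upper - lower)) ** 2)
        chain, lps, acc = adaptive_metropolis(
            lambda th: log_posterior(problem, th),
            theta0,
            int(num_iters),
            int(burn),
            rng,
            initial_cov,
        )

    return PosteriorSample(
        chain=chain,
        log_posteriors=lps,
        acceptance_rate=acc,
        seed=seed,
        free_names=problem.free_names,
        theta0=theta0,
        theta0_log_posterior=float(lp0),
        free_lower=lower,
        free_upper=upper,
        arguments=dict(problem.arguments),
    )


def run_inference(
    problem: FittingProblem, seed: int, transform: str = "log"
) -> PosteriorSample:
    """Full pipeline per the problem's ``arguments``: multi-start CMA-ES
    start-point selection (``cmaOpt`` restarts × ``cmaMaxFevals``
    evaluations each), then adaptive-covariance MCMC (``numIters``
    iterations, ``burn`` discarded) whose initial proposal covariance is
    seeded from the winning CMA-ES search covariance (falling back to the
    1%-of-range diagonal if degenerate)."""
    args = problem.arguments
    master = np.random.SeedSequence(seed)
    cma_seed, mcmc_seed = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(2)
    ]

    theta0, cma, space = cma_es_initialize(
        problem,
        restarts=int(args["cmaOpt"]),
        max_fevals=int(args["cmaMaxFevals"]),
        seed=cma_seed,
        transform=transform,
    )

    lower, upper = problem.free_bounds()
    d = problem.n_free
    if space.transform == "log":
        span_all = np.log(upper) - np.log(lower)
    else:
        span_all = upper - lower
    # Embed the searched-dims covariance into the full free-parameter
    # space; profiled-out dims get the 1%-of-range diagonal.
    initial_cov = np.diag((0.01 * span_all) ** 2)
    cov_search = cma.cov
    if np.all(np.isfinite(cov_search)) and np.all(np.diag(cov_search) > 0):
        for a, ia in enumerate(space.search_idx):
            for b, ib in enumerate(space.search_idx):
                initial_cov[ia, ib] = cov_search[a, b]

    return adaptive_mcmc(
        problem,
        theta0,
        num_iters=int(args["numIters"]),
        burn=int(args["burn"]),
        seed=mcmc_seed,
        initial_cov=initial_cov,
        transform=space.transform,
    )
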