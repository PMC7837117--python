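"""Hierarchical Bayesian fitting by Expectation-Maximization with a Laplace E-step.

Per-unit (session or subject) parameter vectors ``h_i`` are modelled as draws
from a population Gaussian with mean ``mu`` and *diagonal* covariance
``Sigma`` in an unconstrained (transformed) parameter space.  The E-step
computes the MAP estimate ``m_i`` of each unit's parameters under the current
population prior together with a Laplace covariance ``V_i`` (inverse Hessian
of the negative log posterior); the M-step updates the population moments

    mu    <- mean_i(m_i)
    Sigma <- mean_i(m_i^2 + diag V_i) - mu^2

until the population means stop moving.  Model comparison uses the integrated
BIC: -1/2 iBIC = log p(D | theta_ML) - 1/2 |M| log |D|, with the marginal
likelihood of each unit approximated by averaging the data likelihood over K
samples drawn from the fitted prior.

The machinery is likelihood-agnostic: the same code fits the RL models of
:mod:`twostep.agents` (numerical gradients on a numba kernel) and the
hierarchical logistic regressions of :mod:`twostep.behavior` (analytic
Newton steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit as _logit, logsumexp

from ._rl_core import rl_loglik_multisession_batch
from .agents import MODELS, ModelSpec, PARAM_NAMES
from .task import Session

__all__ = [
    "transform_values",
    "untransform_values",
    "PopulationPrior",
    "SessionFit",
    "RLLikelihood",
    "BernoulliLikelihood",
    "map_fit",
    "em_fit",
    "m_step",
    "EMResult",
    "ibic",
    "IBICResult",
    "compare_models",
]

SIGMA_FLOOR = 1e-6      # floor on population variance diagonal
HESS_EIG_FLOOR = 1e-6   # floor on Hessian eigenvalues before inversion
HESS_STEP = 1e-4        # central-difference step for numerical Hessians
GRAD_STEP = 1e-6        # central-difference step for numerical gradients


# ---------------------------------------------------------------------------
# Parameter transforms

def transform_values(values: Sequence[float], transforms: Sequence[str]) -> np.ndarray:
    """Map natural-space parameters to unconstrained space (logit for unit-
    interval rates, log for positive weights, identity for biases)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i, (v, t) in enumerate(zip(values, transforms)):
        if t == "logit":
            if not 0.0 < v < 1.0:
                raise ValueError(f"value {v} outside (0, 1) for logit transform")
            out[i] = _logit(v)
        elif t == "log":
            if v <= 0.0:
                raise ValueError(f"value {v} not positive for log transform")
            out[i] = np.log(v)
        else:
            out[i] = v
    return out


def untransform_values(vector: Sequence[float], transforms: Sequence[str]) -> np.ndarray:
    """Inverse of :func:`transform_values`; clips extreme unconstrained values
    so that optimisers probing far from the origin stay finite."""
    vector = np.asarray(vector, dtype=float)
    out = np.empty_like(vector)
    for i, (h, t) in enumerate(zip(vector, transforms)):
        if t == "logit":
            out[i] = expit(h)
        elif t == "log":
            out[i] = np.exp(min(h, 30.0))
        else:
            out[i] = h
    return out


# ---------------------------------------------------------------------------
# Containers

@dataclass
class PopulationPrior:
    """Gaussian population distribution {mu, Sigma} in transformed space,
    with diagonal Sigma stored as the variance vector ``sigma2``."""

    names: tuple[str, ...]
    transforms: tuple[str, ...]
    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.maximum(np.asarray(self.sigma2, dtype=float), SIGMA_FLOOR)
        if not (len(self.names) == len(self.transforms) == self.mu.size == self.sigma2.size):
            raise ValueError("inconsistent prior dimensions")

    @property
    def n_params(self) -> int:
        return self.mu.size

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` transformed parameter vectors from the prior."""
        return self.mu + np.sqrt(self.sigma2) * rng.standard_normal((size, self.n_params))

    def log_pdf(self, h: np.ndarray) -> float:
        d = h - self.mu
        return float(-0.5 * np.sum(d * d / self.sigma2)
                     - 0.5 * np.sum(np.log(2 * np.pi * self.sigma2)))

    def mean_natural(self) -> dict:
        vals = untransform_values(self.mu, self.transforms)
        return dict(zip(self.names, vals))


@dataclass
class SessionFit:
    """MAP fit of one unit: posterior mode ``m``, Laplace covariance ``V``
    (symmetric PSD after eigenvalue repair) and the data log-likelihood at
    the mode."""

    m: np.ndarray
    V: np.ndarray
    map_loglik: float
    converged: bool = True


# ---------------------------------------------------------------------------
# Likelihoods

class RLLikelihood:
    """Session likelihood of an RL component model, evaluated in transformed
    space through the numba forward-pass kernel."""

    def __init__(self, model: str | ModelSpec = "best"):
        self.spec = MODELS[model] if isinstance(model, str) else model
        self.names = self.spec.free
        self.transforms = self.spec.transforms
        # Precompute the vectorised free-space -> full-natural-vector expansion.
        self._template = self.spec.full_vector([
            {"logit": 0.5, "log": 1.0, "identity": 0.0}[t] for t in self.transforms])
        self._free_idx = np.array([PARAM_NAMES.index(n) for n in self.names], dtype=int)
        tr = np.array(self.transforms)
        self._logit_cols = np.flatnonzero(tr == "logit")
        self._log_cols = np.flatnonzero(tr == "log")
        self._id_cols = np.flatnonzero(tr == "identity")

    def prepare(self, dataset: Session | Sequence[Session]):
        """Pack one unit (a session, or a subject's list of sessions) into
        concatenated arrays with session-boundary offsets."""
        sessions = [dataset] if isinstance(dataset, Session) else list(dataset)
        if any(s.n_trials == 0 for s in sessions):
            raise ValueError("empty session")
        starts = np.cumsum([0] + [s.n_trials for s in sessions]).astype(np.int64)
        cat = lambda attr: np.ascontiguousarray(
            np.concatenate([getattr(s, attr) for s in sessions]), dtype=np.int64)
        return cat("choice"), cat("second_step"), cat("outcome"), starts

    def _expand(self, H: np.ndarray) -> np.ndarray:
        """Transformed free vectors (B, d) -> natural full vectors (B, 14)."""
        H = np.atleast_2d(np.asarray(H, dtype=float))
        vals = np.empty_like(H)
        vals[:, self._logit_cols] = expit(H[:, self._logit_cols])
        vals[:, self._log_cols] = np.exp(np.minimum(H[:, self._log_cols], 30.0))
        vals[:, self._id_cols] = H[:, self._id_cols]
        full = np.tile(self._template, (H.shape[0], 1))
        full[:, self._free_idx] = vals
        return full

    def loglik_transformed(self, H: np.ndarray, data) -> np.ndarray:
        choices, seconds, outcomes, starts = data
        return rl_loglik_multisession_batch(self._expand(H), choices, seconds, outcomes, starts)

    def n_obs(self, data) -> int:
        return int(data[3][-1])


class BernoulliLikelihood:
    """Logistic-regression likelihood y ~ Bernoulli(sigmoid(X beta)); all
    coefficients unconstrained.  Supplies an analytic Newton MAP fit, which
    the EM machinery uses instead of the generic optimiser."""

    def __init__(self, names: Sequence[str]):
        self.names = tuple(names)
        self.transforms = ("identity",) * len(self.names)

    def prepare(self, dataset):
        X, y = dataset
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("design/response shape mismatch")
        if X.shape[1] != len(self.names):
            raise ValueError("design has wrong number of columns")
        return X, 2.0 * y - 1.0  # store responses as +-1

    def loglik_transformed(self, H: np.ndarray, data) -> np.ndarray:
        X, yl = data
        H = np.atleast_2d(np.asarray(H, dtype=float))
        Z = yl[:, None] * (X @ H.T)
        return -np.logaddexp(0.0, -Z).sum(axis=0)

    def n_obs(self, data) -> int:
        return data[0].shape[0]

    def map_fit_analytic(self, data, prior: PopulationPrior,
                         x0: Optional[np.ndarray] = None) -> SessionFit:
        """Newton-Raphson MAP for the strictly convex logistic + Gaussian
        posterior; V is the exact inverse Hessian at the mode."""
        X, yl = data
        y01 = (yl + 1.0) / 2.0
        prec = 1.0 / prior.sigma2
        b = prior.mu.copy() if x0 is None else np.asarray(x0, dtype=float).copy()

        def logpost(beta):
            return (float(self.loglik_transformed(beta[None, :], data)[0])
                    - 0.5 * np.sum((beta - prior.mu) ** 2 * prec))

        lp = logpost(b)
        converged = False
        for _ in range(100):
            p = expit(X @ b)
            g = X.T @ (y01 - p) - (b - prior.mu) * prec
            w = np.maximum(p * (1.0 - p), 1e-12)
            Hmat = (X * w[:, None]).T @ X + np.diag(prec)
            try:
                step = np.linalg.solve(Hmat, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hmat, g, rcond=None)[0]
            # Damped Newton: backtrack until the log posterior improves.
            scale = 1.0
            for _ in range(40):
                b_new = b + scale * step
                lp_new = logpost(b_new)
                if lp_new >= lp - 1e-12:
                    break
                scale *= 0.5
            b, lp = b_new, lp_new
            if np.max(np.abs(scale * step)) < 1e-9:
                converged = True
                break
        p = expit(X @ b)
        w = np.maximum(p * (1.0 - p), 1e-12)
        Hmat = (X * w[:, None]).T @ X + np.diag(prec)
        V = _psd_inverse(Hmat)
        ll = float(self.loglik_transformed(b[None, :], data)[0])
        return SessionFit(m=b, V=V, map_loglik=ll, converged=converged)


# ---------------------------------------------------------------------------
# MAP fitting (generic, gradient-based)

def _psd_inverse(H: np.ndarray) -> np.ndarray:
    """Invert a (near-)symmetric matrix through its eigendecomposition,
    flooring eigenvalues so the result is symmetric positive definite."""
    Hs = 0.5 * (H + H.T)
    w, Q = np.linalg.eigh(Hs)
    w = np.maximum(w, HESS_EIG_FLOOR)
    return (Q / w) @ Q.T


def _neg_logpost_and_grad(h, likelihood, data, prior):
    d = h.size
    pts = np.empty((1 + 2 * d, d))
    pts[0] = h
    for i in range(d):
        pts[1 + 2 * i] = h
        pts[1 + 2 * i, i] += GRAD_STEP
        pts[2 + 2 * i] = h
        pts[2 + 2 * i, i] -= GRAD_STEP
    L = likelihood.loglik_transformed(pts, data)
    grad_lik = (L[1::2] - L[2::2]) / (2.0 * GRAD_STEP)
    dm = h - prior.mu
    f = -(L[0] - 0.5 * np.sum(dm * dm / prior.sigma2))
    g = -(grad_lik - dm / prior.sigma2)
    return f, g


def _numerical_hessian(h, likelihood, data, prior):
    """Central-difference Hessian of the negative log posterior."""
    d = h.size
    s = HESS_STEP
    pts = [h]
    for i in range(d):
        for sign in (s, -s):
            p = h.copy()
            p[i] += sign
            pts.append(p)
    pairs = []
    for i in range(d):
        for j in range(i + 1, d):
            for si in (s, -s):
                for sj in (s, -s):
                    p = h.copy()
                    p[i] += si
                    p[j] += sj
                    pts.append(p)
            pairs.append((i, j))
    L = likelihood.loglik_transformed(np.array(pts), data)
    dm_all = np.array(pts) - prior.mu
    F = -(L - 0.5 * np.sum(dm_all * dm_all / prior.sigma2, axis=1))
    H = np.empty((d, d))
    f0 = F[0]
    for i in range(d):
        fp, fm = F[1 + 2 * i], F[2 + 2 * i]
        H[i, i] = (fp + fm - 2.0 * f0) / (s * s)
    base = 1 + 2 * d
    for k, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = F[base + 4 * k: base + 4 * k + 4]
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * s * s)
    return H


def map_fit(
    data,
    prior: PopulationPrior,
    likelihood,
    x0: Optional[np.ndarray] = None,
    n_restarts: int = 3,
    rng: Optional[np.random.Generator] = None,
    jitter: float = 0.5,
) -> SessionFit:
    """MAP estimate of one unit's transformed parameters under the prior.

    Uses the likelihood's analytic Newton solver when it provides one;
    otherwise multi-start L-BFGS with central-difference gradients, followed
    by a numerical Hessian (step ``HESS_STEP``) whose eigenvalues are floored
    before inversion to give a PSD Laplace covariance.
    """
    if hasattr(likelihood, "map_fit_analytic"):
        return likelihood.map_fit_analytic(data, prior, x0=x0)

    rng = rng if rng is not None else np.random.default_rng(0)
    starts = [np.asarray(x0, dtype=float)] if x0 is not None else [prior.mu.copy()]
    if x0 is not None and n_restarts > 1:
        starts.append(prior.mu.copy())
    while len(starts) < n_restarts:
        starts.append(prior.mu + jitter * np.sqrt(prior.sigma2)
                      * rng.standard_normal(prior.n_params))

    best = None
    any_success = False
    for start in starts:
        res = minimize(
            _neg_logpost_and_grad, start, args=(likelihood, data, prior),
            jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        warnings.warn("MAP optimisation did not report convergence from any start",
                      RuntimeWarning)

    m = best.x
    H = _numerical_hessian(m, likelihood, data, prior)
    V = _psd_inverse(H)
    ll = float(likelihood.loglik_transformed(m[None, :], data)[0])
    return SessionFit(m=m, V=V, map_loglik=ll, converged=bool(any_success))


# ---------------------------------------------------------------------------
# Expectation-Maximization

def m_step(ms: np.ndarray, v_diags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population-moment update from unit MAP means and Laplace variances:
    mu = mean(m_i); Sigma = mean(m_i^2 + V_i) - mu^2 (diagonal, floored)."""
    ms = np.atleast_2d(ms)
    v_diags = np.atleast_2d(v_diags)
    mu = ms.mean(axis=0)
    sigma2 = np.maximum((ms ** 2 + v_diags).mean(axis=0) - mu ** 2, SIGMA_FLOOR)
    return mu, sigma2


@dataclass
class EMResult:
    prior: PopulationPrior
    fits: list
    n_iter: int
    converged: bool
    prior_history: list = field(default_factory=list)


def em_fit(
    datasets: Sequence,
    likelihood,
    init_prior: Optional[PopulationPrior] = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    n_restarts: int = 3,
    seed: int = 0,
    init_sigma2: float = 4.0,
    verbose: bool = False,
) -> EMResult:
    """Fit the population prior to a collection of units by EM.

    ``datasets`` are raw units (Sessions, lists of Sessions, or (X, y) pairs,
    whatever the likelihood's ``prepare`` accepts).  MAP fits are warm-started
    from the previous iteration's modes; multi-start jitter is applied on the
    first iteration only.  Convergence is the sup-norm change of ``mu``.
    """
    if len(datasets) < 2:
        raise ValueError("em_fit needs at least 2 units")
    rng = np.random.default_rng(seed)
    prepared = [likelihood.prepare(d) for d in datasets]
    d = len(likelihood.names)
    prior = init_prior if init_prior is not None else PopulationPrior(
        names=tuple(likelihood.names), transforms=tuple(likelihood.transforms),
        mu=np.zeros(d), sigma2=np.full(d, init_sigma2))

    fits: list[Optional[SessionFit]] = [None] * len(prepared)
    history = [prior]
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        for i, data in enumerate(prepared):
            x0 = fits[i].m if fits[i] is not None else None
            fits[i] = map_fit(data, prior, likelihood, x0=x0,
                              n_restarts=(n_restarts if it == 0 else 1), rng=rng)
        mu, sigma2 = m_step(np.array([f.m for f in fits]),
                            np.array([np.diag(f.V) for f in fits]))
        delta = np.max(np.abs(mu - prior.mu))
        prior = PopulationPrior(names=prior.names, transforms=prior.transforms,
                                mu=mu, sigma2=sigma2)
        history.append(prior)
        if verbose:
            print(f"EM iter {n_iter}: max|dmu| = {delta:.2e}")
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", RuntimeWarning)
    return EMResult(prior=prior, fits=fits, n_iter=n_iter, converged=converged,
                    prior_history=history)


# ---------------------------------------------------------------------------
# Model comparison

@dataclass
class IBICResult:
    ibic: float
    log_marginal: float
    penalty: float
    n_prior_params: int
    n_obs: int
    ci: tuple[float, float]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci
        return f"IBICResult(ibic={self.ibic:.1f}, 95% CI [{lo:.1f}, {hi:.1f}])"


def ibic(
    datasets: Sequence,
    prior: PopulationPrior,
    likelihood,
    K: int = 5000,
    rng: Optional[np.random.Generator] = None,
    n_boot: int = 1000,
) -> IBICResult:
    """Integrated BIC of a fitted population prior.

    Each unit's marginal likelihood is approximated by a log-mean-exp over K
    parameter vectors sampled from the prior.  The prior parameter count |M|
    is two per model parameter (mean and variance).  The bootstrap CI
    resamples the K prior draws with replacement within each unit.
    """
    if K < 100:
        raise ValueError("K must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(0)
    prepared = [likelihood.prepare(d) for d in datasets]
    n_obs = sum(likelihood.n_obs(data) for data in prepared)

    per_unit_L = []
    log_marg = 0.0
    for data in prepared:
        H = prior.sample(rng, K)
        L = likelihood.loglik_transformed(H, data)
        per_unit_L.append(L)
        log_marg += logsumexp(L) - np.log(K)

    n_prior_params = 2 * prior.n_params
    penalty = n_prior_params * np.log(n_obs)
    score = -2.0 * log_marg + penalty

    boot = np.empty(n_boot)
    for b in range(n_boot):
        tot = 0.0
        for L in per_unit_L:
            idx = rng.integers(0, K, size=K)
            tot += logsumexp(L[idx]) - np.log(K)
        boot[b] = -2.0 * tot + penalty
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return IBICResult(ibic=float(score), log_marginal=float(log_marg),
                      penalty=float(penalty), n_prior_params=n_prior_params,
                      n_obs=n_obs, ci=ci)


def group_by_subject(sessions: Sequence[Session]) -> list[list[Session]]:
    """Group sessions into per-subject lists (fit unit = subject)."""
    groups: dict[str, list[Session]] = {}
    for s in sessions:
        groups.setdefault(s.subject_id, []).append(s)
    return list(groups.values())


@dataclass
class ComparisonResult:
    scores: dict
    em_results: dict
    best: str


def compare_models(
    sessions: Sequence[Session],
    models: Sequence[str] = ("mf", "mb", "best"),
    unit: str = "session",
    K: int = 5000,
    seed: int = 0,
    **em_kwargs,
) -> ComparisonResult:
    """Fit each RL component model hierarchically and rank them by iBIC."""
    datasets = (list(sessions) if unit == "session" else group_by_subject(sessions))
    scores, em_results = {}, {}
    for name in models:
        lik = RLLikelihood(name)
        em = em_fit(datasets, lik, seed=seed, **em_kwargs)
        res = ibic(datasets, em.prior, lik, K=K, rng=np.random.default_rng(seed + 1))
        scores[name] = res
        em_results[name] = em
    best = min(scores, key=lambda m: scores[m].ibic)
    return ComparisonResult(scores=scores, em_results=em_results, best=best)
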