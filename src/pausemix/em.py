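"""Lognormal mixture fitting by expectation-maximization.

Pause latencies are heavy-tailed and, after a log transform, typically
still leptokurtic: a single Normal underfits.  The working model is a
K-component mixture of Normals on log-milliseconds (equivalently, a
mixture of lognormals on the raw latencies),

    g(x | theta) = sum_k pi_k * Normal(x; mu_k, sigma_k),

with a latent indicator z attaching each pause to one component,
P(z = k) = pi_k.  Components ordered by mean are read as low-to-high
cognitive processes; the smallest-mean component is the "low-cognitive"
(fluency/orthographic) one.

Fitting is plain EM: the E-step computes responsibilities
P(z = k | x_i, theta) and the observed-data log-likelihood, the M-step
re-estimates (pi, mu, sigma) from responsibility-weighted moments.  The
likelihood and downstream information criteria are computed on the log
scale; the Jacobian of the transform is the same for every K fit to the
same data, so model comparison is unaffected.

Degeneracy handling: the lognormal-mixture likelihood is unbounded (a
component can shrink onto one point), so sigma is floored and a restart
that terminates at the sigma floor or with a near-empty component is
marked non-converged rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .core import MixtureSpec, ValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))


class NotEstimableError(ValueError):
    """Too few distinct observations to estimate a K-component mixture."""


class DegenerateFitError(RuntimeError):
    """The likelihood underflowed to zero for some observation."""


@dataclass(frozen=True)
class EMConfig:
    """Tuning knobs for the EM fitter.

    tol
        Convergence threshold on the relative log-likelihood improvement
        per iteration.
    max_iter
        Iteration cap for the final (refinement) run.
    n_restarts
        Number of initializations.  The first is deterministic
        (quantile-block slicing of the sorted data); the rest jitter the
        block boundaries with seeded uniform noise to explore the
        multimodal likelihood.
    short_iter
        Multistart is run short-EM style: each initialization is advanced
        only ``short_iter`` iterations (at a loosened tolerance) and only
        the best short run is refined to full convergence.  This explores
        as many basins as full multistart at a fraction of the cost.
        Set to 0 to refine every restart fully.
    sigma_floor
        Lower bound on component SDs (log-ms).  Guards the unbounded-
        likelihood pathology.
    weight_floor
        Minimum mixing proportion; ``None`` means 1/n.  A fit resting on
        either floor is reported as non-converged.
    """

    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 10
    short_iter: int = 50
    sigma_floor: float = 1e-3
    weight_floor: float | None = None
    seed: int = 0


@dataclass
class MixtureFit:
    """A fitted mixture plus its estimation record.

    ``spec`` is always ordered by component mean (label switching is
    resolved by the smallest-mean-first convention).  ``loglik_trace`` is
    the per-iteration observed-data log-likelihood of the winning restart;
    EM guarantees it is non-decreasing up to round-off.
    """

    spec: MixtureSpec
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray
    n_obs: int
    restarts: list[dict] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.spec.K

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "mu": self.spec.mu.tolist(),
            "sigma": self.spec.sigma.tolist(),
            "pi": self.spec.pi.tolist(),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_obs": int(self.n_obs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureFit":
        return cls(
            spec=MixtureSpec(np.asarray(d["mu"]), np.asarray(d["sigma"]), np.asarray(d["pi"])),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            loglik_trace=np.empty(0),
            n_obs=int(d["n_obs"]),
        )


def log_transform(durations) -> np.ndarray:
    """Natural log of positive latencies (ms -> log-ms)."""
    y = np.asarray(durations, dtype=float)
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        raise ValidationError(f"durations must be strictly positive; offending indices {bad.tolist()[:10]}")
    return np.log(y)


def _component_logpdf(x: np.ndarray, spec: MixtureSpec) -> np.ndarray:
    """(n, K) matrix of log[pi_k * Normal(x_i; mu_k, sigma_k)]."""
    sigma = np.maximum(spec.sigma, np.finfo(float).tiny)
    z = (x[:, None] - spec.mu[None, :]) / sigma[None, :]
    with np.errstate(divide="ignore"):
        return np.log(spec.pi[None, :]) - np.log(sigma[None, :]) - 0.5 * (z * z + _LOG_2PI)


def mixture_logdensity(x, spec: MixtureSpec) -> np.ndarray | float:
    """Log of the mixture density at ``x`` (log-scale values).

    Uses log-sum-exp across components, so extreme ``x`` does not
    overflow; the result is -inf only where the density is truly zero.
    """
    spec.validate()
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = logsumexp(_component_logpdf(arr, spec), axis=1)
    return float(out[0]) if np.ndim(x) == 0 else out


def e_step(x: np.ndarray, spec: MixtureSpec) -> tuple[np.ndarray, float]:
    """Responsibilities P(z=k | x_i, theta) and the log-likelihood.

    Row i is proportional to pi_k * Normal(x_i; mu_k, sigma_k), normalized
    to sum to one; the returned log-likelihood is the sum over i of the
    mixture log-density.
    """
    lp = _component_logpdf(x, spec)
    norm = logsumexp(lp, axis=1)
    if not np.all(np.isfinite(norm)):
        raise DegenerateFitError("mixture density underflowed to 0 for some observation")
    resp = np.exp(lp - norm[:, None])
    return resp, float(norm.sum())


def m_step(
    x: np.ndarray,
    resp: np.ndarray,
    sigma_floor: float = 1e-3,
) -> MixtureSpec:
    """Maximize the expected complete-data log-likelihood.

    pi_k is the column mean of the responsibilities, mu_k the
    responsibility-weighted mean of x, sigma_k the square root of the
    weighted variance about mu_k, floored at ``sigma_floor``.
    """
    n = x.shape[0]
    mass = resp.sum(axis=0)
    # a numerically empty component keeps its slot but will trip the
    # weight floor in the convergence verdict
    safe = np.maximum(mass, np.finfo(float).tiny)
    mu = (resp * x[:, None]).sum(axis=0) / safe
    var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / safe
    sigma = np.maximum(np.sqrt(var), sigma_floor)
    pi = mass / n
    pi = pi / pi.sum()
    return MixtureSpec(mu, sigma, pi)


def order_components(fit: MixtureFit) -> MixtureFit:
    """Sort components by mean, ascending (stable on ties).

    sigma and pi are permuted consistently; the log-likelihood is
    invariant under the relabeling.
    """
    return replace(fit, spec=fit.spec.ordered())


def _quantile_init(x_sorted: np.ndarray, K: int, jitter: np.ndarray | None) -> MixtureSpec:
    """Initial spec from K contiguous blocks of the sorted data.

    ``jitter`` perturbs the interior block boundaries (fractions of n);
    ``None`` gives the deterministic equal-count slicing.
    """
    n = x_sorted.shape[0]
    bounds = np.linspace(0.0, 1.0, K + 1)
    if jitter is not None:
        bounds = bounds.copy()
        bounds[1:-1] = np.clip(bounds[1:-1] + jitter, 0.02, 0.98)
        bounds[1:-1] = np.sort(bounds[1:-1])
    idx = np.unique(np.round(bounds * n).astype(int))
    if idx.size < K + 1:  # collapsed blocks: fall back to equal slicing
        idx = np.round(np.linspace(0, n, K + 1)).astype(int)
    mu, sigma, pi = np.empty(K), np.empty(K), np.empty(K)
    for k in range(K):
        block = x_sorted[idx[k] : idx[k + 1]]
        if block.size == 0:
            block = x_sorted[min(idx[k], n - 1) : min(idx[k], n - 1) + 1]
        mu[k] = block.mean()
        sigma[k] = max(block.std(), 1e-2)
        pi[k] = max(block.size, 1)
    pi /= pi.sum()
    return MixtureSpec(mu, sigma, pi)


@njit(cache=False)
def _em_loop(x, mu, sigma, pi, tol, max_iter, sigma_floor):  # pragma: no cover - jitted
    """Compiled EM alternation.

    Mutates (mu, sigma, pi) in place; returns (loglik, tol_hit, n_iter,
    n_evals, trace, ok).  The E-step uses a per-observation max shift
    (log-sum-exp) so extreme observations do not underflow.  ``ok`` is
    False when the likelihood still became non-finite (true zero
    density).
    """
    n = x.shape[0]
    K = mu.shape[0]
    trace = np.empty(max_iter + 1)
    resp = np.empty((n, K))
    logc = np.empty(K)
    ll = -np.inf
    tol_hit = False
    n_iter = 0
    n_evals = 0
    for t in range(max_iter + 1):
        for k in range(K):
            logc[k] = np.log(pi[k]) - np.log(sigma[k])
        ll_new = 0.0
        for i in range(n):
            m = -1e308
            for k in range(K):
                z = (x[i] - mu[k]) / sigma[k]
                lp = logc[k] - 0.5 * (z * z + _LOG_2PI)
                resp[i, k] = lp
                if lp > m:
                    m = lp
            s = 0.0
            for k in range(K):
                v = np.exp(resp[i, k] - m)
                resp[i, k] = v
                s += v
            inv = 1.0 / s
            for k in range(K):
                resp[i, k] *= inv
            ll_new += m + np.log(s)
        trace[t] = ll_new
        n_evals = t + 1
        if not np.isfinite(ll_new):
            return ll_new, False, n_iter, n_evals, trace, False
        if t > 0 and abs(ll_new - ll) / max(abs(ll), 1.0) < tol:
            ll = ll_new
            tol_hit = t < max_iter
            break
        ll = ll_new
        if t == max_iter:
            break
        n_iter = t + 1
        for k in range(K):
            mass = 0.0
            m1 = 0.0
            m2 = 0.0
            for i in range(n):
                r = resp[i, k]
                mass += r
                m1 += r * x[i]
                m2 += r * x[i] * x[i]
            if mass < 1e-300:
                mass = 1e-300
            mu[k] = m1 / mass
            var = m2 / mass - mu[k] * mu[k]
            if var < 0.0:
                var = 0.0
            sigma[k] = max(np.sqrt(var), sigma_floor)
            pi[k] = mass / n
        s = 0.0
        for k in range(K):
            s += pi[k]
        if s > 0.0:
            for k in range(K):
                pi[k] /= s
    return ll, tol_hit, n_iter, n_evals, trace, True


def _run_em(
    x: np.ndarray, init: MixtureSpec, cfg: EMConfig, weight_floor: float
) -> tuple[MixtureSpec, float, bool, int, np.ndarray]:
    """One EM run from one initialization (thin wrapper over the jitted loop)."""
    mu, sigma, pi = init.mu.copy(), init.sigma.copy(), init.pi.copy()
    ll, tol_hit, n_iter, n_evals, trace, ok = _em_loop(
        np.ascontiguousarray(x, dtype=float), mu, sigma, pi,
        cfg.tol, cfg.max_iter, cfg.sigma_floor,
    )
    if not ok:
        raise DegenerateFitError("mixture density underflowed to 0 for some observation")
    spec = MixtureSpec(mu, sigma, pi)
    at_floor = bool(np.any(sigma <= cfg.sigma_floor * (1 + 1e-12)) or np.any(pi < weight_floor))
    converged = tol_hit and not at_floor
    return spec, ll, converged, n_iter, trace[:n_evals].copy()


def fit_em(durations, K: int, config: EMConfig | None = None) -> MixtureFit:
    """Fit a K-component lognormal mixture to one essay's latencies.

    Best-of-restarts EM on the log-transformed latencies.  ``converged``
    requires the tolerance to be met before the iteration cap with no
    component resting on the sigma or weight floor.  Components in the
    returned fit are ordered by mean.  Raises :class:`NotEstimableError`
    when there are fewer than K distinct log values (such essays count as
    non-converged in the corpus census).

    The data are sorted internally, so the result is exactly invariant to
    the input order.
    """
    cfg = config or EMConfig()
    if K < 1:
        raise ValidationError("K must be >= 1")
    x = np.sort(log_transform(durations))
    n = x.shape[0]
    if np.unique(x).size < K:
        raise NotEstimableError(f"need at least {K} distinct values, got {np.unique(x).size}")
    weight_floor = cfg.weight_floor if cfg.weight_floor is not None else 1.0 / n

    if K == 1:
        mu = float(x.mean())
        sigma = max(float(x.std()), cfg.sigma_floor)
        spec = MixtureSpec([mu], [sigma], [1.0])
        _, ll = e_step(x, spec)
        return MixtureFit(spec, ll, True, 1, np.array([ll]), n)

    rng = np.random.default_rng(cfg.seed)
    inits = []
    for r in range(cfg.n_restarts):
        jitter = None if r == 0 else rng.uniform(-0.5 / K, 0.5 / K, size=K - 1)
        inits.append(_quantile_init(x, K, jitter))
    restarts: list[dict] = []

    if cfg.short_iter > 0 and cfg.n_restarts > 1:
        # short-EM multistart: advance every initialization a few dozen
        # iterations, then refine only the most promising basin
        short_cfg = replace(cfg, max_iter=cfg.short_iter)
        best_short: tuple | None = None
        for init in inits:
            try:
                spec, ll, _, n_it, tr = _run_em(x, init, short_cfg, weight_floor)
            except DegenerateFitError:
                restarts.append({"loglik": float("-inf"), "converged": False, "n_iter": 0})
                continue
            restarts.append({"loglik": ll, "converged": False, "n_iter": n_it})
            if best_short is None or ll > best_short[1]:
                best_short = (spec, ll, tr)
        if best_short is None:
            raise DegenerateFitError("all EM restarts degenerated")
        spec0, _, tr0 = best_short
        spec, ll, conv, n_iter, tr = _run_em(x, spec0, cfg, weight_floor)
        # the refinement's first evaluation repeats the short run's last
        trace = np.concatenate([tr0, tr[1:]])
        fit = MixtureFit(spec, ll, conv, n_iter, trace, n, restarts=restarts)
        return order_components(fit)

    best: tuple | None = None
    for init in inits:
        try:
            spec, ll, conv, n_iter, trace = _run_em(x, init, cfg, weight_floor)
        except DegenerateFitError:
            restarts.append({"loglik": float("-inf"), "converged": False, "n_iter": 0})
            continue
        restarts.append({"loglik": ll, "converged": conv, "n_iter": n_iter})
        # prefer converged restarts; among equals, higher likelihood
        key = (conv, ll)
        if best is None or key > (best[2], best[1]):
            best = (spec, ll, conv, n_iter, trace)
    if best is None:
        raise DegenerateFitError("all EM restarts degenerated")
    spec, ll, conv, n_iter, trace = best
    fit = MixtureFit(spec, ll, conv, n_iter, trace, n, restarts=restarts)
    return order_components(fit)


def fit_k_sweep(durations, k_values, config: EMConfig | None = None) -> dict[int, MixtureFit | None]:
    """Fit each K in ``k_values`` to the same latencies.

    A K that is not estimable (too few distinct values) maps to ``None``;
    estimation failures never raise here, matching the per-essay census
    semantics.
    """
    out: dict[int, MixtureFit | None] = {}
    for K in k_values:
        try:
            out[K] = fit_em(durations, K, config)
        except (NotEstimableError, DegenerateFitError):
            out[K] = None
    return out
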