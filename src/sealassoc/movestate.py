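"""Two-state hidden Markov model for hourly travel distances.

Hourly displacements y_t (metres moved over a 1-h step) are modelled as
draws from one of two exponential distributions,

    f(y | lambda_j) = (1/lambda_j) exp(-y / lambda_j),

where lambda_j is the mean hourly displacement of latent movement state j,
and the state sequence is a first-order Markov chain.  The slow state
(small lambda) is interpreted as area-restricted search (ARS) — tortuous,
low-displacement movement typical of foraging or resting — and the fast
state as directed transit.  Fitting is by Baum–Welch EM on the scaled
forward–backward recursions, with multiple quantile-anchored restarts;
states are relabelled so lambda_slow < lambda_fast.  A step is classified
ARS when its smoothed posterior p(ARS) exceeds 0.5 (strictly).

Missing steps split a track into independent segments; no imputation is
performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "HMMParameters",
    "HMMFit",
    "hmm_loglik",
    "hmm_fit",
    "hmm_posterior",
    "classify_states",
]

SLOW, FAST = 0, 1


@dataclass
class HMMParameters:
    """Emission means (m/h), transition matrix and initial distribution.

    State 0 is slow (ARS), state 1 fast; ``validate`` enforces positivity
    and stochasticity but not the ordering (use :func:`relabelled`).
    """

    lam: np.ndarray          # (2,) exponential means, metres per hour
    trans: np.ndarray        # (2, 2) row-stochastic
    init: np.ndarray         # (2,) simplex

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.init = np.asarray(self.init, dtype=float)

    def validate(self) -> None:
        if self.lam.shape != (2,) or np.any(self.lam <= 0):
            raise ValueError("emission means must be two positive values")
        if (self.trans.shape != (2, 2) or np.any(self.trans < 0)
                or not np.allclose(self.trans.sum(axis=1), 1.0)):
            raise ValueError("trans must be 2x2 row-stochastic")
        if self.init.shape != (2,) or np.any(self.init < 0) \
                or not np.isclose(self.init.sum(), 1.0):
            raise ValueError("init must be a length-2 simplex")

    def relabelled(self) -> "HMMParameters":
        """Return parameters with states ordered so lam[0] <= lam[1]."""
        if self.lam[0] <= self.lam[1]:
            return self
        perm = [1, 0]
        return HMMParameters(self.lam[perm], self.trans[np.ix_(perm, perm)],
                             self.init[perm])


@dataclass
class HMMFit:
    params: HMMParameters
    loglik: float
    posterior: np.ndarray        # p(ARS) per input element, NaN at gaps
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)


def _segments(rates) -> list[np.ndarray]:
    """Split a rate sequence at missing values into contiguous segments."""
    y = np.asarray(rates, dtype=float)
    if y.ndim != 1:
        raise ValueError("rates must be 1-D")
    finite = np.isfinite(y)
    if np.any(y[finite] < 0):
        raise ValueError("travel distances must be non-negative")
    segs, start = [], None
    for i, ok in enumerate(finite):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            segs.append(y[start:i])
            start = None
    if start is not None:
        segs.append(y[start:])
    if not segs:
        raise ValueError("no usable (non-missing) travel distances")
    return segs


def _emission_dens(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """(T, 2) exponential densities."""
    return np.exp(-y[:, None] / lam[None, :]) / lam[None, :]


def _forward_backward(y: np.ndarray, p: HMMParameters):
    """Scaled forward–backward for one segment.

    Returns (loglik, gamma, xi_sum) where gamma[t, j] = P(s_t = j | y) and
    xi_sum[i, j] = sum_t P(s_t = i, s_{t+1} = j | y).
    """
    T = len(y)
    B = _emission_dens(y, p.lam)
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a = p.init * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ p.trans) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (p.trans @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        w = B[1:] * beta[1:] / c[1:, None]      # (T-1, 2)
        xi_sum = p.trans * (alpha[:-1].T @ w)
    else:
        xi_sum = np.zeros((2, 2))
    return float(np.log(c).sum()), gamma, xi_sum


def hmm_loglik(rates, params: HMMParameters) -> float:
    """Log-likelihood of hourly displacements under the two-state model.

    ``rates`` is a 1-D sequence of hourly displacements (metres per hour);
    NaN entries split it into independent segments whose log-likelihoods
    add.  Computed with the scaled forward recursion.
    """
    params.validate()
    total = 0.0
    for y in _segments(rates):
        ll, _, _ = _forward_backward(y, params)
        total += ll
    return total


def hmm_posterior(rates, params: HMMParameters) -> np.ndarray:
    """Smoothed posterior probability of the slow (ARS) state per element.

    Forward–backward smoothing; missing inputs give NaN posteriors.
    """
    params.validate()
    y = np.asarray(rates, dtype=float)
    out = np.full(len(y), np.nan)
    finite = np.isfinite(y)
    pos = np.nonzero(finite)[0]
    offset = 0
    for seg in _segments(rates):
        _, gamma, _ = _forward_backward(seg, params)
        out[pos[offset:offset + len(seg)]] = gamma[:, SLOW]
        offset += len(seg)
    return out


def classify_states(posterior) -> np.ndarray:
    """Label each step 'slow' (ARS) when p(ARS) > 0.5, else 'fast'.

    The inequality is strict: p(ARS) exactly 0.5 is labelled fast.  Missing
    posteriors give empty labels.
    """
    p = np.asarray(posterior, dtype=float)
    labels = np.where(p > 0.5, "slow", "fast").astype(object)
    labels[~np.isfinite(p)] = None
    return labels


def _initial_params(segs: list[np.ndarray], rng: np.random.Generator,
                    jitter: bool) -> HMMParameters:
    y = np.concatenate(segs)
    q25, q75 = np.quantile(y, [0.25, 0.75])
    lam = np.array([max(q25, 1e-8 + 0.01 * y.mean()), max(q75, q25 * 1.5 + 1e-8)])
    if jitter:
        lam = lam * np.exp(rng.normal(0.0, 0.3, 2))
        lam = np.sort(np.maximum(lam, 1e-8))
    trans = np.array([[0.8, 0.2], [0.2, 0.8]])
    return HMMParameters(lam, trans, np.array([0.5, 0.5]))


def hmm_fit(rates, n_restarts: int = 5, seed: int = 0, tol: float = 1e-6,
            max_iter: int = 500) -> HMMFit:
    """Fit the two-state exponential HMM by Baum–Welch EM.

    Initial emission means are anchored at the 25th/75th percentiles of the
    observed displacements (the first restart unjittered, the rest with
    lognormal jitter); the best log-likelihood over restarts is kept and
    states are relabelled so lambda_slow < lambda_fast.  Convergence when
    the log-likelihood improves by less than ``tol``.

    The M-step for exponential emissions is the posterior-weighted mean:
    lambda_j = sum_t gamma_t(j) y_t / sum_t gamma_t(j).
    """
    segs = _segments(rates)
    n_obs = sum(len(s) for s in segs)
    if n_obs < 20:
        raise ValueError(f"need >= 20 usable steps to fit (got {n_obs})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    y_all = np.concatenate(segs)
    if np.allclose(y_all, y_all[0]):
        warnings.warn("degenerate data: all travel distances equal; "
                      "emission means may coincide")
    rng = np.random.default_rng(seed)
    best: HMMFit | None = None
    for r in range(n_restarts):
        p = _initial_params(segs, rng, jitter=(r > 0))
        trace: list[float] = []
        prev_ll = -np.inf
        converged = False
        for it in range(1, max_iter + 1):
            ll = 0.0
            g_sum = np.zeros(2)
            gy_sum = np.zeros(2)
            xi_tot = np.zeros((2, 2))
            init_acc = np.zeros(2)
            for ygroup in segs:
                seg_ll, gamma, xi = _forward_backward(ygroup, p)
                ll += seg_ll
                g_sum += gamma.sum(axis=0)
                gy_sum += gamma.T @ ygroup
                xi_tot += xi
                init_acc += gamma[0]
            trace.append(ll)
            if ll - prev_ll < tol and it > 1:
                converged = True
                break
            prev_ll = ll
            lam = np.maximum(gy_sum / np.maximum(g_sum, 1e-300), 1e-8)
            denom = xi_tot.sum(axis=1, keepdims=True)
            trans = np.where(denom > 0, xi_tot / np.maximum(denom, 1e-300),
                             np.array([[0.5, 0.5], [0.5, 0.5]]))
            trans /= trans.sum(axis=1, keepdims=True)
            init = init_acc / init_acc.sum()
            p = HMMParameters(lam, trans, init)
        fit = HMMFit(params=p, loglik=trace[-1], posterior=np.empty(0),
                     converged=converged, n_iter=len(trace),
                     loglik_trace=trace)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    best.params = best.params.relabelled()
    best.posterior = hmm_posterior(rates, best.params)
    if not best.converged:
        log.warning("hmm_fit: EM did not converge in %d iterations", max_iter)
    return best
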