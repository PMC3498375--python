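"""Mixed-model and count inference on association state.

Depth and travel rate are compared across association categories with a
Gaussian linear mixed model: a random intercept per animal and first-order
autoregressive (AR(1)) residual correlation within each animal's serially
ordered observations,

    y_g = X_g beta + b_g 1 + e_g,   b_g ~ N(0, sigma_b^2),
    Cov(e_g) = sigma_e^2 R(phi),    R(phi)_{st} = phi^{|s-t|},

maximised over (beta, sigma_b, sigma_e, phi) by exact marginal maximum
likelihood (beta profiled by GLS; the AR(1) structure is exploited through
the innovations transform, so each likelihood evaluation is O(n)).

Sex-pair composition (MM / MF / FF association counts) is tested with the
likelihood-ratio G statistic with the Williams small-sample correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "LMMFit",
    "fit_lmm_ar1",
    "lmm_loglik",
    "GTestResult",
    "g_test_williams",
    "AssociationSummary",
    "summarize_associations",
]


@dataclass
class LMMFit:
    """Maximum-likelihood fit of the random-intercept + AR(1) model."""

    terms: list                  # fixed-effect names, baseline first
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma_b: float               # among-group sd
    sigma_e: float               # residual (marginal AR(1)) sd
    phi: float                   # AR(1) autocorrelation, |phi| < 1
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.beta, "se": self.se,
                             "t": self.t, "p": self.p}, index=self.terms)


def _group_arrays(data: pd.DataFrame, response: str, category: str,
                  group: str, order: str | None, baseline: str,
                  terms: list[str]):
    """Assemble per-group (y, X) in serial order, with treatment coding:
    intercept = baseline category, one offset column per other category."""
    cats = [baseline] + [t for t in terms if t != baseline]
    groups = []
    for _, grp in data.groupby(group, sort=True):
        if order is not None:
            grp = grp.sort_values(order)
        y = grp[response].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        X = np.ones((len(grp), len(cats)))
        for k, cat in enumerate(cats[1:], start=1):
            X[:, k] = (grp[category] == cat).to_numpy(dtype=float)
        groups.append((y, X))
    return cats, groups


def _ar1_transform(v: np.ndarray, phi: float) -> np.ndarray:
    """Innovations transform T with T R(phi) T' = (1 - phi^2) I."""
    w = np.empty_like(v)
    w[0] = np.sqrt(1.0 - phi * phi) * v[0]
    w[1:] = v[1:] - phi * v[:-1]
    return w


def lmm_loglik(groups, beta: np.ndarray, sigma_b: float, sigma_e: float,
               phi: float) -> float:
    """Exact Gaussian log-likelihood of the random-intercept + AR(1) model.

    ``groups`` is a list of (y, X) pairs in serial order.  Uses the
    Woodbury identity on Sigma = sigma_b^2 J + sigma_e^2 R(phi), with
    R(phi)^-1 applied via the innovations transform; O(n) per group.
    """
    if not (abs(phi) < 1 and sigma_e > 0 and sigma_b >= 0):
        return -np.inf
    s2e, s2b = sigma_e ** 2, sigma_b ** 2
    omp2 = 1.0 - phi * phi
    total = 0.0
    for y, X in groups:
        n = len(y)
        r = y - X @ beta
        tr = _ar1_transform(r, phi)
        ones = np.ones(n)
        t1 = _ar1_transform(ones, phi)
        # quadratic forms under A^-1 = R^-1 / s2e
        rAr = tr @ tr / (s2e * omp2)
        oAr = t1 @ tr / (s2e * omp2)
        oAo = t1 @ t1 / (s2e * omp2)
        c = 1.0 + s2b * oAo
        quad = rAr - s2b * oAr * oAr / c
        logdet = n * np.log(s2e) + (n - 1) * np.log(omp2) + np.log(c)
        total += -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    return float(total)


def _profile_beta(groups, sigma_b, sigma_e, phi):
    """GLS estimate of beta and its covariance at fixed variance params."""
    s2e, s2b = sigma_e ** 2, sigma_b ** 2
    omp2 = 1.0 - phi * phi
    p = groups[0][1].shape[1]
    XtSX = np.zeros((p, p))
    XtSy = np.zeros(p)
    for y, X in groups:
        tX = np.empty_like(X)
        for k in range(p):
            tX[:, k] = _ar1_transform(X[:, k], phi)
        ty = _ar1_transform(y, phi)
        t1 = _ar1_transform(np.ones(len(y)), phi)
        c = 1.0 + s2b * (t1 @ t1) / (s2e * omp2)
        XtA = tX.T / (s2e * omp2)
        XtSX += XtA @ tX - s2b / c * np.outer(XtA @ t1, XtA @ t1)
        XtSy += XtA @ ty - s2b / c * (XtA @ t1) * (t1 @ ty / (s2e * omp2))
    cov = np.linalg.inv(XtSX)
    return cov @ XtSy, cov


def fit_lmm_ar1(data: pd.DataFrame, response: str, category: str,
                group: str, baseline: str, order: str | None = None,
                terms: list[str] | None = None) -> LMMFit:
    """Fit the Gaussian mixed model by exact maximum likelihood.

    ``data`` needs one row per observation with columns ``response``
    (finite numeric), ``category`` (association-state label), ``group``
    (animal ID; observations of a group are serially ordered by ``order``
    or by their current row order) and optionally ``order``.  ``baseline``
    names the category absorbed into the intercept; the other fixed-effect
    terms are differences from it.

    Variance parameters are optimised on an unconstrained scale
    (log sigma_b, log sigma_e, atanh phi) with Nelder–Mead, beta profiled
    by GLS at each point; standard errors come from the GLS information
    matrix at the optimum.  Deterministic given the data.
    """
    if terms is None:
        terms = sorted(data[category].unique())
    if baseline not in terms:
        raise ValueError(f"baseline {baseline!r} not among categories {terms}")
    cats, groups = _group_arrays(data, response, category, group, order,
                                 baseline, terms)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if min(len(y) for y, _ in groups) < 3:
        raise ValueError("need >= 3 observations per group")
    Xall = np.vstack([X for _, X in groups])
    if np.linalg.matrix_rank(Xall) < Xall.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effect design")

    # moment starting values from OLS residuals
    yall = np.concatenate([y for y, _ in groups])
    b0, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    resid = yall - Xall @ b0
    s_e0 = max(float(np.std(resid)), 1e-6)
    gmeans = [float(np.mean(y - X @ b0)) for y, X in groups]
    s_b0 = max(float(np.std(gmeans)), 1e-3 * s_e0)
    r1 = [np.corrcoef(y[:-1] - (X @ b0)[:-1], y[1:] - (X @ b0)[1:])[0, 1]
          for y, X in groups if len(y) > 4]
    phi0 = float(np.clip(np.nanmean(r1) if r1 else 0.0, -0.9, 0.9))

    def negll(theta):
        sb, se, ph = np.exp(theta[0]), np.exp(theta[1]), np.tanh(theta[2])
        beta, _ = _profile_beta(groups, sb, se, ph)
        return -lmm_loglik(groups, beta, sb, se, ph)

    x0 = np.array([np.log(s_b0), np.log(s_e0), np.arctanh(phi0)])
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 2000})
    sb, se_, ph = np.exp(res.x[0]), np.exp(res.x[1]), np.tanh(res.x[2])
    beta, cov = _profile_beta(groups, sb, se_, ph)
    se_beta = np.sqrt(np.diag(cov))
    tval = beta / se_beta
    n_obs = sum(len(y) for y, _ in groups)
    pval = 2.0 * stats.t.sf(np.abs(tval), df=max(n_obs - len(beta), 1))
    if not res.success:
        log.warning("fit_lmm_ar1: optimizer did not report convergence (%s)",
                    res.message)
    return LMMFit(terms=cats, beta=beta, se=se_beta, t=tval, p=pval,
                  sigma_b=float(sb), sigma_e=float(se_), phi=float(ph),
                  loglik=float(-res.fun), converged=bool(res.success),
                  n_obs=n_obs, n_groups=len(groups))


@dataclass
class GTestResult:
    G: float
    G_adj: float        # Williams-corrected statistic
    df: int
    p: float
    q: float            # Williams correction factor


def g_test_williams(counts, expected_props=None) -> GTestResult:
    """Likelihood-ratio goodness-of-fit G test with Williams correction.

    G = 2 * sum O_i ln(O_i / E_i) with E_i = n * p_i (zero counts
    contribute 0); the Williams factor q = 1 + (k^2 - 1) / (6 n (k - 1))
    deflates G for small samples; p is the chi-square upper tail on k - 1
    degrees of freedom.
    """
    O = np.asarray(counts, dtype=float)
    if np.any(O < 0) or O.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    k = len(O)
    n = O.sum()
    p_exp = (np.full(k, 1.0 / k) if expected_props is None
             else np.asarray(expected_props, dtype=float))
    if not np.isclose(p_exp.sum(), 1.0) or np.any(p_exp < 0):
        raise ValueError("expected_props must be a probability simplex")
    if np.any((p_exp == 0) & (O > 0)):
        raise ValueError("observed count in a zero-probability category")
    E = n * p_exp
    nz = O > 0
    G = 2.0 * float(np.sum(O[nz] * np.log(O[nz] / E[nz])))
    q = 1.0 + (k * k - 1.0) / (6.0 * n * (k - 1.0))
    G_adj = G / q
    df = k - 1
    return GTestResult(G=G, G_adj=G_adj, df=df,
                       p=float(stats.chi2.sf(G_adj, df)), q=q)


def _quantiles(x: np.ndarray) -> dict[str, float]:
    """Median and quartiles by linear interpolation between order stats."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return {"q25": np.nan, "median": np.nan, "q75": np.nan,
                "min": np.nan, "max": np.nan}
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return {"q25": float(q25), "median": float(med), "q75": float(q75),
            "min": float(x.min()), "max": float(x.max())}


@dataclass
class AssociationSummary:
    n_associations: int
    n_events: int
    events_per_association: dict
    duration_h: dict
    separation_km: dict
    dyad_matrix: pd.DataFrame = field(repr=False)
    sex_pair_counts: dict = field(default_factory=dict)   # MM/MF/FF (+unknown)
    sex_pair_percent: dict = field(default_factory=dict)  # rounded to 0.1
    gtest: GTestResult | None = None


def summarize_associations(associations: pd.DataFrame,
                           sexes: dict[str, str] | None = None,
                           expected_props=None) -> AssociationSummary:
    """Summary statistics of an associations table.

    Computes totals, the per-dyad association(detection) matrix, medians
    and quartiles of events per association, duration and separation, and —
    given a ``seal_id -> 'M'/'F'`` lookup — counts and percentages of MM,
    MF and FF associations with a Williams-corrected G test of their
    composition (uniform expectation by default).  Dyads with a seal of
    unknown sex are tallied separately and excluded from the test.
    """
    n_assoc = int(len(associations))
    n_events = int(associations["n_events"].sum()) if n_assoc else 0
    dyads = sorted(set(associations["seal_a"]) | set(associations["seal_b"])) \
        if n_assoc else []
    matrix = pd.DataFrame(0, index=dyads, columns=dyads, dtype=object)
    if n_assoc:
        for (a, b), grp in associations.groupby(["seal_a", "seal_b"]):
            matrix.loc[a, b] = f"{len(grp)} ({int(grp['n_events'].sum())})"

    summary = AssociationSummary(
        n_associations=n_assoc,
        n_events=n_events,
        events_per_association=_quantiles(
            associations["n_events"].to_numpy() if n_assoc else np.empty(0)),
        duration_h=_quantiles(
            associations["duration_h"].to_numpy() if n_assoc else np.empty(0)),
        separation_km=_quantiles(
            associations["separation_km"].to_numpy()
            if n_assoc and "separation_km" in associations else np.empty(0)),
        dyad_matrix=matrix,
    )

    if sexes is not None and n_assoc:
        classes = []
        for row in associations.itertuples(index=False):
            sa, sb = sexes.get(row.seal_a), sexes.get(row.seal_b)
            if sa in ("M", "F") and sb in ("M", "F"):
                classes.append("".join(sorted((sa, sb), reverse=True)))  # MM/MF/FF
            else:
                classes.append("unknown")
        counts = pd.Series(classes).value_counts()
        summary.sex_pair_counts = {k: int(counts.get(k, 0))
                                   for k in ("MM", "MF", "FF")}
        if counts.get("unknown", 0):
            summary.sex_pair_counts["unknown"] = int(counts["unknown"])
        known_total = sum(summary.sex_pair_counts.get(k, 0)
                          for k in ("MM", "MF", "FF"))
        if known_total:
            summary.sex_pair_percent = {
                k: round(100.0 * summary.sex_pair_counts[k] / known_total, 1)
                for k in ("MM", "MF", "FF")}
            summary.gtest = g_test_williams(
                [summary.sex_pair_counts[k] for k in ("MM", "MF", "FF")],
                expected_props)
    return summary
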