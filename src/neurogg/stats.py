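"""Rank tests, single-covariate Cox regression and survival meta-analysis.

The inference layer used throughout the pipeline, written from scratch:

* enumeration-exact Mann–Whitney U (two-sided p = twice the smaller
  enumerated tail, tie-safe because the enumeration permutes the observed
  values themselves);
* Spearman rank correlation with mid-rank ties;
* Cox proportional hazards with one continuous covariate, maximising the
  Breslow partial likelihood by Newton–Raphson with step-halving;
* common-effect (inverse-variance) and DerSimonian–Laird random-effects
  pooling of log hazard ratios with the heterogeneity statistics Q, tau²
  and I².

The twice-the-smaller-tail convention reproduces the exact probabilities
2/330 ≈ 0.0061 (complete separation) and 4/330 ≈ 0.0121 (one inversion)
for group sizes 7 vs 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "EXACT_ENUMERATION_CAP",
    "GroupComparisonResult", "CorrelationResult", "CoxFit", "MetaResult",
    "mann_whitney_u", "mann_whitney_exact", "spearman_rho",
    "cox_fit_single", "meta_fixed_random", "midranks",
]

#: exact enumeration is used while C(n1+n2, n1) stays at or below this
EXACT_ENUMERATION_CAP = 200_000


@dataclass(frozen=True)
class GroupComparisonResult:
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int


@dataclass(frozen=True)
class CoxFit:
    log_hr: float
    se: float
    n: int
    n_events: int
    converged: bool
    n_iter: int

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    @property
    def z(self) -> float:
        return self.log_hr / self.se

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.log_hr - 1.96 * self.se),
                math.exp(self.log_hr + 1.96 * self.se))


@dataclass(frozen=True)
class MetaResult:
    k: int
    common_effect: float
    common_se: float
    random_effect: float
    random_se: float
    tau2: float
    i2: float
    q: float
    df: int
    p_q: float
    common_weights: tuple[float, ...] = field(repr=False, default=())
    random_weights: tuple[float, ...] = field(repr=False, default=())


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U = #{(i,j): x_i > y_j} + half-count of ties."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    gt = (xa[:, None] > ya[None, :]).sum()
    eq = (xa[:, None] == ya[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> GroupComparisonResult:
    """Two-sided Mann–Whitney test, exact by full enumeration when feasible.

    All C(n1+n2, n1) assignments of the observed (possibly tied) pooled
    values to the two groups are enumerated; p = min(1, 2·min(P(U ≤ u),
    P(U ≥ u))).  Beyond the enumeration cap a tie-corrected normal
    approximation with continuity correction is used.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = mann_whitney_u(x, y)
    pooled = np.asarray(x + y, float)
    n = n1 + n2

    if math.comb(n, n1) <= EXACT_ENUMERATION_CAP:
        # pairwise "greater" matrix over pooled values; U for an assignment
        # X is sum_{i in X, j not in X} G[i, j]
        g = (pooled[:, None] > pooled[None, :]).astype(float)
        g += 0.5 * (pooled[:, None] == pooled[None, :])
        np.fill_diagonal(g, 0.0)
        row_tot = g.sum(axis=1)
        all_idx = np.arange(n)
        n_le = n_ge = 0
        total = 0
        eps = 1e-9
        for comb in combinations(all_idx, n1):
            idx = np.fromiter(comb, int, n1)
            u = row_tot[idx].sum() - g[np.ix_(idx, idx)].sum()
            total += 1
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return GroupComparisonResult(u_obs, p, "exact", n1, n2)

    # tie-corrected normal approximation with continuity correction
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = math.sqrt(sigma2)
    z = (abs(u_obs - mu) - 0.5) / sigma if sigma > 0 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return GroupComparisonResult(u_obs, p, "normal_approx", n1, n2)


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks (1-based, average over ties)."""
    a = np.asarray(values, float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a), float)
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman correlation: Pearson correlation of mid-ranks."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rx, ry = midranks(xa), midranks(ya)
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    return CorrelationResult(rho, n)


def _breslow_derivatives(beta: float, t_desc: np.ndarray, event: np.ndarray,
                         x: np.ndarray, group_last: np.ndarray
                         ) -> tuple[float, float, float]:
    """(log-lik, score, information) of the Breslow partial likelihood.

    Arrays are sorted by descending time; ``group_last[i]`` is the last
    index sharing ``t_desc[i]`` so tied times share the at-risk set.
    """
    w = np.exp(beta * x)
    s0 = np.cumsum(w)[group_last]
    s1 = np.cumsum(w * x)[group_last]
    s2 = np.cumsum(w * x * x)[group_last]
    ev = event.astype(bool)
    loglik = float(np.sum(beta * x[ev] - np.log(s0[ev])))
    mean = s1[ev] / s0[ev]
    score = float(np.sum(x[ev] - mean))
    info = float(np.sum(s2[ev] / s0[ev] - mean ** 2))
    return loglik, score, info


def cox_fit_single(time: Sequence[float], event: Sequence[int], x: Sequence[float],
                   tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Cox proportional hazards with one continuous covariate (Breslow ties).

    Newton–Raphson with step-halving; converged when |score| <= tol.
    The covariate is centred internally for numerical stability (the
    estimate is unaffected).  Raises on degenerate input (no events,
    constant covariate); returns ``converged=False`` with NaN estimates
    for monotone likelihoods / failed convergence.
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    xv = np.asarray(x, float)
    if not (len(t) == len(e) == len(xv)):
        raise ValueError("time, event and x must have equal length")
    if (t <= 0).any():
        raise ValueError("event times must be positive")
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    if np.all(xv == xv[0]):
        raise ValueError("covariate is constant: no information")
    order = np.argsort(-t, kind="mergesort")
    t_desc, e_desc, x_desc = t[order], e[order], xv[order]
    x_desc = x_desc - x_desc.mean()
    # last index of each tied-time block (sorted descending)
    group_last = np.searchsorted(-t_desc, -t_desc, side="right") - 1

    beta = 0.0
    loglik, score, info = _breslow_derivatives(beta, t_desc, e_desc, x_desc, group_last)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if abs(score) <= tol:
            converged = True
            break
        if info <= 0:
            break
        step = score / info
        # step-halving on log-likelihood decrease
        for _ in range(30):
            cand = beta + step
            ll_new, sc_new, in_new = _breslow_derivatives(cand, t_desc, e_desc, x_desc, group_last)
            if ll_new >= loglik - 1e-12:
                break
            step /= 2.0
        beta, loglik, score, info = cand, ll_new, sc_new, in_new
        if abs(beta) > 200:  # monotone likelihood / complete separation
            break
    else:
        it = max_iter
    if abs(score) <= tol and info > 0:
        converged = True
    if not converged or abs(beta) > 200:
        return CoxFit(math.nan, math.nan, len(t), int(e.sum()), False, it)
    se = 1.0 / math.sqrt(info)
    return CoxFit(float(beta), se, len(t), int(e.sum()), True, it)


def meta_fixed_random(estimates: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Common-effect and DerSimonian–Laird random-effects pooling.

    Inputs are per-study log hazard ratios and their standard errors.
    Q = Σw(θ−θ̄)² with w = 1/se²; tau² = max(0, (Q−df)/(Σw − Σw²/Σw));
    I² = max(0, (Q−df)/Q) (defined as 0 when Q = 0); random-effects
    weights are 1/(se²+tau²).  Reported weights are normalised to sum
    to one within each model.
    """
    theta = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if theta.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    k = len(theta)
    if k == 0:
        raise ValueError("at least one study is required")
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / se ** 2
    common = float((w * theta).sum() / w.sum())
    common_se = float(1.0 / math.sqrt(w.sum()))
    df = k - 1
    q = float((w * (theta - common) ** 2).sum())
    if df > 0:
        c = float(w.sum() - (w ** 2).sum() / w.sum())
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        p_q = float(chi2.sf(q, df))
    else:
        tau2, p_q = 0.0, math.nan
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    wr = 1.0 / (se ** 2 + tau2)
    random = float((wr * theta).sum() / wr.sum())
    random_se = float(1.0 / math.sqrt(wr.sum()))
    return MetaResult(
        k=k, common_effect=common, common_se=common_se,
        random_effect=random, random_se=random_se,
        tau2=tau2, i2=i2, q=q, df=df, p_q=p_q,
        common_weights=tuple(w / w.sum()),
        random_weights=tuple(wr / wr.sum()),
    )
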