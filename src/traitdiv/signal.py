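"""Phylogenetic signal statistics and the phylogenetic ANOVA.

* Blomberg's K compares the observed ratio of non-phylogenetic to
  phylogenetically-scaled mean squared error with its Brownian-motion
  expectation; K = 1 under Brownian motion, K < 1 means close relatives are
  more variable than Brownian motion predicts.  Support comes from a
  tip-label permutation test on the phylogenetically-scaled MSE (small MSE
  = strong signal), as in the standard implementation, not on K itself.
* Pagel's lambda scales the off-diagonal (shared-path) entries of the
  Brownian covariance; the continuous version is fitted by profiled Gaussian
  ML over lambda in [0, 1] with a likelihood-ratio test against lambda = 0.
  The discrete version applies the corresponding branch-length transform
  (internal branches scaled, terminal branches stretched to preserve tip
  depths) inside an Mk maximum-likelihood fit.
* The phylogenetic ANOVA computes the ordinary one-way F statistic and
  calibrates it against F values from Brownian-motion simulations on the
  tree, with the Brownian rate estimated from the data by ML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .mk import MkModelSpec, fit_mk, mk_loglik
from .simulate import shared_path_matrix
from .tree import TimeTree, check_ultrametric

__all__ = [
    "SignalResult",
    "AnovaResult",
    "blomberg_k",
    "pagel_lambda_continuous",
    "pagel_lambda_discrete",
    "phyl_anova",
    "lambda_transform",
]


@dataclass
class SignalResult:
    statistic: str
    estimate: float
    p_value: float = None
    loglik: float = None
    loglik_null: float = None
    n_rand: int = None
    extra: dict = None


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict
    n_sim: int


def _as_vector(tree: TimeTree, x) -> np.ndarray:
    """Accept a dict keyed by tip label or an array in tip order."""
    if isinstance(x, dict):
        missing = [t for t in tree.tip_labels if t not in x]
        if missing:
            raise KeyError(f"tips without trait values: {missing}")
        x = [x[t] for t in tree.tip_labels]
    x = np.asarray(x, dtype=float)
    if x.size != tree.n_tips or np.any(np.isnan(x)):
        raise ValueError("need one non-missing value per tip")
    return x


# ----------------------------------------------------------------------
# Blomberg's K
# ----------------------------------------------------------------------
def blomberg_k(tree: TimeTree, x, n_rand: int = 1000, seed=0) -> SignalResult:
    """Blomberg's K with a permutation test (``n_rand`` randomizations)."""
    x = _as_vector(tree, x)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("K undefined for a constant trait")
    C = shared_path_matrix(tree)
    cf = cho_factor(C)
    Cinv1 = cho_solve(cf, np.ones(n))
    denom1 = Cinv1.sum()
    expected = (np.trace(C) - n / denom1) / (n - 1)

    def mse_ratio(v):
        a = (Cinv1 @ v) / denom1
        r = v - a
        mse0 = r @ r / (n - 1)
        mse = r @ cho_solve(cf, r) / (n - 1)
        return mse0 / mse, mse

    ratio, mse_obs = mse_ratio(x)
    K = ratio / expected
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rand):
        _, mse_p = mse_ratio(rng.permutation(x))
        if mse_p <= mse_obs:
            hits += 1
    p = (hits + 1.0) / (n_rand + 1.0)
    return SignalResult(statistic="BlombergK", estimate=float(K),
                        p_value=float(p), n_rand=n_rand)


# ----------------------------------------------------------------------
# Pagel's lambda, continuous
# ----------------------------------------------------------------------
def _gaussian_profile_ll(x: np.ndarray, C: np.ndarray):
    """Profiled (mean, rate) Gaussian log-likelihood and its components."""
    n = x.size
    cf = cho_factor(C)
    Cinv1 = cho_solve(cf, np.ones(n))
    a = (Cinv1 @ x) / Cinv1.sum()
    r = x - a
    s2 = r @ cho_solve(cf, r) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, a, s2


def pagel_lambda_continuous(tree: TimeTree, x, boundary_halved: bool = False) -> SignalResult:
    """ML lambda in [0, 1] for a continuous trait, LRT against lambda = 0."""
    x = _as_vector(tree, x)
    if x.size < 4:
        raise ValueError("need at least 4 tips")
    C = shared_path_matrix(tree)
    diag = np.diag(np.diag(C))
    off = C - diag

    def ll(lam):
        M = lam * off + diag
        try:
            return _gaussian_profile_ll(x, M)[0]
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular phylogenetic covariance; check for duplicate "
                "zero-length tips"
            ) from exc

    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([ll(g) for g in grid])
    g0 = grid[int(np.argmax(vals))]
    lo, hi = max(0.0, g0 - 0.1), min(1.0, g0 + 0.1)
    res = minimize_scalar(lambda g: -ll(g), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    lam_hat, ll_hat = float(res.x), float(-res.fun)
    # snap to the boundary when the interior optimum does not beat it
    for b in (0.0, 1.0):
        if ll(b) >= ll_hat:
            lam_hat, ll_hat = b, float(ll(b))
    ll0 = float(ll(0.0))
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(chi2.sf(lrt, df=1))
    if boundary_halved:
        p = p / 2.0 if lrt > 0 else 1.0
    return SignalResult(statistic="PagelLambdaContinuous", estimate=lam_hat,
                        p_value=p, loglik=ll_hat, loglik_null=ll0)


# ----------------------------------------------------------------------
# Pagel's lambda, discrete
# ----------------------------------------------------------------------
def lambda_transform(tree: TimeTree, lam: float) -> TimeTree:
    """Scale internal branches by lambda, preserving tip depths.

    Terminal branches are stretched by the depth their parent lost, so every
    tip keeps its original distance from the root; requires an ultrametric
    tree for the transform to be meaningful.
    """
    ok, dev = check_ultrametric(tree)
    if not ok:
        raise ValueError(
            f"lambda transform requires an ultrametric tree (spread {dev:g})"
        )
    depth = tree.depth
    brlen = tree.brlen.copy()
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        if v < tree.n_tips:
            brlen[v] = tree.brlen[v] + (1.0 - lam) * depth[p]
        else:
            brlen[v] = lam * tree.brlen[v]
    return TimeTree(tree.parent.copy(), brlen, list(tree.labels), tree.n_tips)


def pagel_lambda_discrete(tree: TimeTree, tip_states: dict, spec: MkModelSpec,
                          n_starts: int = 5, seed=0,
                          boundary_halved: bool = False) -> SignalResult:
    """Joint ML of lambda and Mk rates; LRT against lambda = 0 (star tree)."""
    rng = np.random.default_rng(seed)
    k = spec.n_params
    scale = 1.0 / max(tree.depth.max(), 1e-12)

    def nll(theta):
        lam = theta[0]
        val = mk_loglik(lambda_transform(tree, lam), tip_states, spec,
                        np.exp(theta[1:]))
        return -val if np.isfinite(val) else 1e10

    bounds = [(0.0, 1.0)] + [(np.log(1e-9), np.log(1e3))] * k
    best = None
    for s in range(max(1, n_starts)):
        lam0 = 0.5 if s == 0 else rng.random()
        r0 = (np.full(k, np.log(scale)) if s == 0
              else np.log(scale) + rng.uniform(np.log(0.01), np.log(100.0), k))
        res = minimize(nll, np.concatenate([[lam0], r0]), method="L-BFGS-B",
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lam_hat = float(best.x[0])
    ll_hat = float(-best.fun)
    null = fit_mk(lambda_transform(tree, 0.0), tip_states, spec,
                  n_starts=max(1, n_starts // 2), seed=seed + 1)
    ll0 = null.loglik
    if ll0 > ll_hat:  # lambda = 0 is nested; keep the better optimum
        lam_hat, ll_hat = 0.0, ll0
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(chi2.sf(lrt, df=1))
    if boundary_halved:
        p = p / 2.0 if lrt > 0 else 1.0
    return SignalResult(statistic="PagelLambdaDiscrete", estimate=lam_hat,
                        p_value=p, loglik=ll_hat, loglik_null=ll0,
                        extra={"rates": np.exp(best.x[1:])})


# ----------------------------------------------------------------------
# phylogenetic ANOVA
# ----------------------------------------------------------------------
def f_oneway(y: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Classical one-way between/within mean-square ratio."""
    n = y.size
    gm = y.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        yg = y[codes == g]
        ssb += yg.size * (yg.mean() - gm) ** 2
        ssw += ((yg - yg.mean()) ** 2).sum()
    msb = ssb / (n_groups - 1)
    msw = ssw / (n - n_groups)
    return float(msb / msw)


def phyl_anova(tree: TimeTree, groups, y, n_sim: int = 10_000,
               seed=0) -> AnovaResult:
    """One-way F with a Brownian-motion simulation null on the tree."""
    y = _as_vector(tree, y)
    if isinstance(groups, dict):
        groups = [groups[t] for t in tree.tip_labels]
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    codes = np.array([levels.index(g) for g in groups])
    for g in range(len(levels)):
        if (codes == g).sum() < 2:
            raise ValueError(f"group {levels[g]!r} has fewer than 2 members")
    f_obs = f_oneway(y, codes, len(levels))
    C = shared_path_matrix(tree)
    _, _, s2 = _gaussian_profile_ll(y, C)  # ML Brownian rate from the data
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sim, y.size))
    sims = np.sqrt(s2) * z @ L.T
    hits = sum(f_oneway(sims[i], codes, len(levels)) >= f_obs
               for i in range(n_sim))
    p = (hits + 1.0) / (n_sim + 1.0)
    means = {levels[g]: float(y[codes == g].mean()) for g in range(len(levels))}
    return AnovaResult(f_statistic=f_obs, p_value=float(p),
                       group_means=means, n_sim=n_sim)
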