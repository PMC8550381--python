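"""Multi-start ML fitting, AIC ranking, Akaike-weight model averaging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ..tree import TimeTree
from .likelihood import observed_marginals, sse_loglik
from .spec import SSEModelSpec

__all__ = [
    "ModelFitResult",
    "fit_sse",
    "rank_models",
    "akaike_weights",
    "model_average_rates",
]

#: box bounds per parameter block (per my): turnover, extinction fraction,
#: transition rates
TAU_BOUNDS = (1e-4, 10.0)
EPS_BOUNDS = (1e-6, 3.0)
Q_BOUNDS = (1e-6, 1.0)


@dataclass
class ModelFitResult:
    name: str
    description: str
    loglik: float
    n_params: int
    aic: float
    aicc: float
    theta: np.ndarray
    spec: SSEModelSpec = field(repr=False)
    n_tips: int = 0
    delta_aic: float = None
    weight: float = None
    start_logliks: np.ndarray = field(default=None, repr=False)

    @property
    def rates(self):
        lam, mu, Q = self.spec.rates(self.theta)
        return {"lambda": lam, "mu": mu, "Q": Q,
                "net_diversification": lam - mu, "turnover": lam + mu,
                "extinction_fraction": np.divide(
                    mu, lam, out=np.zeros_like(mu), where=lam > 0)}


def _bounds(spec: SSEModelSpec):
    b = ([TAU_BOUNDS] * spec.n_tau + [EPS_BOUNDS] * spec.n_eps
         + [Q_BOUNDS] * spec.n_q)
    return np.log(np.asarray(b))


def fit_sse(tree: TimeTree, tip_codes: dict, spec: SSEModelSpec,
            n_starts: int = 25, seed=0, rtol: float = 1e-8,
            atol: float = 1e-10) -> ModelFitResult:
    """Maximum-likelihood fit from ``n_starts`` random starting points.

    Optimisation runs in log space with box constraints; starts are drawn
    log-uniformly within the bounds, except the first, which sits at a
    birth-rate heuristic (pure-birth rate from tip count and tree depth).
    """
    if n_starts < 1:
        raise ValueError("need at least one start")
    rng = np.random.default_rng(seed)
    lb = _bounds(spec)
    k = spec.n_params

    def nll(logtheta):
        ll = sse_loglik(tree, tip_codes, spec, np.exp(logtheta),
                        rtol=rtol, atol=atol)
        return -ll if np.isfinite(ll) else 1e10

    depth = tree.depth.max()
    r0 = max(np.log(tree.n_tips / 2.0) / depth, 1e-3)
    x_heur = np.concatenate([
        np.full(spec.n_tau, np.log(np.clip(1.5 * r0, *TAU_BOUNDS))),
        np.full(spec.n_eps, np.log(0.5)),
        np.full(spec.n_q, np.log(np.clip(0.1 / depth, *Q_BOUNDS))),
    ])
    best = None
    start_lls = []
    for s in range(n_starts):
        x0 = x_heur if s == 0 else rng.uniform(lb[:, 0], lb[:, 1], size=k)
        res = minimize(nll, x0, method="L-BFGS-B", bounds=lb)
        start_lls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError(f"all starts failed for model {spec.name}")
    ll = -best.fun
    n = tree.n_tips
    aic = 2 * k - 2 * ll
    denom = n - k - 1
    aicc = aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)
    return ModelFitResult(
        name=spec.name, description=spec.description, loglik=ll,
        n_params=k, aic=aic, aicc=aicc, theta=np.exp(best.x), spec=spec,
        n_tips=n, start_logliks=np.asarray(start_lls),
    )


def akaike_weights(aics) -> tuple:
    """(delta, weight) vectors for a set of AIC (or AICc) values."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def rank_models(fits, criterion: str = "aic") -> list:
    """Sort fits by Akaike weight (descending), filling delta and weight."""
    if not fits:
        raise ValueError("no fits to rank")
    key = {"aic": "aic", "aicc": "aicc"}[criterion]
    delta, w = akaike_weights([getattr(f, key) for f in fits])
    for f, d, wi in zip(fits, delta, w):
        f.delta_aic = float(d)
        f.weight = float(wi)
    return sorted(fits, key=lambda f: -f.weight)


def ranking_frame(fits) -> pd.DataFrame:
    """Table-style summary: one row per model, best first."""
    rows = [{
        "model": f.name,
        "description": f.description,
        "free_parameters": f.n_params,
        "lnL": f.loglik,
        "AIC": f.aic,
        "AICc": f.aicc,
        "delta_AIC": f.delta_aic,
        "weight": f.weight,
    } for f in fits]
    return pd.DataFrame(rows)


def model_average_rates(fits, reconstructions: dict,
                        threshold: float = 1e-3) -> pd.DataFrame:
    """Akaike-weight averaged per-node diversification rates.

    ``reconstructions`` maps model name -> (n_nodes, K) composite marginals.
    Every model with weight above ``threshold`` must have a reconstruction;
    weights are renormalised over the models supplied.  Per node and model,
    the rate is the marginal-weighted mean over composite states; the
    averaged value is the weight-weighted mean over models, hence always
    inside the [min, max] of the contributing models' node rates.
    """
    ranked = [f for f in fits if f.weight is not None]
    if not ranked:
        raise ValueError("rank_models must run before averaging")
    used = []
    for f in ranked:
        if f.name in reconstructions:
            used.append(f)
        elif f.weight > threshold:
            raise ValueError(
                f"model {f.name!r} has weight {f.weight:.3g} > {threshold} "
                "but no reconstruction"
            )
    wsum = sum(f.weight for f in used)
    n_nodes = next(iter(reconstructions.values())).shape[0]
    out = {
        "net_diversification": np.zeros(n_nodes),
        "turnover": np.zeros(n_nodes),
        "speciation": np.zeros(n_nodes),
        "extinction": np.zeros(n_nodes),
        "transition_total": np.zeros(n_nodes),
    }
    state_prob = np.zeros((n_nodes, 3))
    for f in used:
        P = reconstructions[f.name]
        if P.shape != (n_nodes, f.spec.n_states):
            raise ValueError(f"reconstruction shape mismatch for {f.name!r}")
        lam, mu, Q = f.spec.rates(f.theta)
        wf = f.weight / wsum
        out["net_diversification"] += wf * (P @ (lam - mu))
        out["turnover"] += wf * (P @ (lam + mu))
        out["speciation"] += wf * (P @ lam)
        out["extinction"] += wf * (P @ mu)
        out["transition_total"] += wf * (P @ Q.sum(axis=1))
        state_prob += wf * observed_marginals(P, f.spec.hidden)
    df = pd.DataFrame(out)
    df.insert(0, "node", np.arange(n_nodes))
    for i, code in enumerate(("01", "10", "11")):
        df[f"p_{code}"] = state_prob[:, i]
    return df
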