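"""Continuous-time Markov (Mk) models for discrete characters on trees.

Supports the standard rate structures — equal rates (ER), symmetric (SYM)
and all-rates-different (ARD) — plus *constrained* variants of the ordered
three-state characters in which direct moves between the two extreme states
are structurally zero, so every path runs through the intermediate state.

The likelihood is Felsenstein pruning with per-branch transition matrices
``P(t) = expm(Q t)`` (scaling-and-squaring; no diagonalisability assumption,
since masked rate matrices may be defective).  The root can be handled by
FitzJohn state-frequency weighting (default), a uniform prior, or the
stationary distribution of ``Q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .tree import TimeTree

__all__ = [
    "MkModelSpec",
    "MkFitResult",
    "build_rate_matrix",
    "mk_loglik",
    "fit_mk",
    "marginal_asr",
]

ROOT_MODES = ("fitzjohn", "uniform", "stationary")


@dataclass
class MkModelSpec:
    """Rate-matrix structure: which cells are free, shared, or zero."""

    states: tuple
    share: np.ndarray          # (m, m) int; -1 on diagonal and masked cells
    root: str = "fitzjohn"
    name: str = ""

    def __post_init__(self):
        self.states = tuple(self.states)
        self.share = np.asarray(self.share, dtype=np.int64)
        m = len(self.states)
        if self.share.shape != (m, m):
            raise ValueError("share map shape mismatch")
        if self.root not in ROOT_MODES:
            raise ValueError(f"root must be one of {ROOT_MODES}")
        idx = np.unique(self.share[self.share >= 0])
        if idx.size and not np.array_equal(idx, np.arange(idx.size)):
            raise ValueError("share indices must be 0..k-1 without gaps")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        s = self.share[self.share >= 0]
        return int(s.max()) + 1 if s.size else 0

    @property
    def mask(self) -> np.ndarray:
        """Structurally-zero off-diagonal cells."""
        m = self.n_states
        off = ~np.eye(m, dtype=bool)
        return off & (self.share < 0)

    def rate_matrix(self, rates) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        if rates.size != self.n_params:
            raise ValueError(f"expected {self.n_params} rates, got {rates.size}")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        Q = np.zeros_like(self.share, dtype=float)
        free = self.share >= 0
        Q[free] = rates[self.share[free]]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary(self, rates) -> np.ndarray:
        Q = self.rate_matrix(rates)
        m = self.n_states
        A = np.vstack([Q.T, np.ones(m)])
        b = np.zeros(m + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def build_rate_matrix(alphabet, model: str = "ARD", constrained: bool = False,
                      intermediate=None, root: str = "fitzjohn") -> MkModelSpec:
    """Construct an ER/SYM/ARD structure, optionally constrained.

    ``constrained=True`` zeroes direct transitions between the two extreme
    states of a three-state ordered character (e.g. small<->large,
    benthic<->pelagic), forcing passage through the intermediate state,
    which defaults to the middle element of ``alphabet``.
    """
    states = tuple(alphabet)
    m = len(states)
    if m < 2:
        raise ValueError("need at least 2 states")
    model = model.upper()
    if model not in ("ER", "SYM", "ARD"):
        raise ValueError("model must be ER, SYM or ARD")
    mask = np.zeros((m, m), dtype=bool)
    if constrained:
        if m != 3:
            raise ValueError("constrained structure requires a 3-state alphabet")
        if intermediate is None:
            intermediate = states[1]
        if intermediate not in states:
            raise ValueError(f"intermediate state {intermediate!r} not in alphabet")
        mid = states.index(intermediate)
        ext = [i for i in range(3) if i != mid]
        mask[ext[0], ext[1]] = mask[ext[1], ext[0]] = True
    share = np.full((m, m), -1, dtype=np.int64)
    nxt = 0
    pair_index = {}
    for i in range(m):
        for j in range(m):
            if i == j or mask[i, j]:
                continue
            if model == "ER":
                share[i, j] = 0
            elif model == "SYM":
                key = (min(i, j), max(i, j))
                if key not in pair_index:
                    pair_index[key] = nxt
                    nxt += 1
                share[i, j] = pair_index[key]
            else:
                share[i, j] = nxt
                nxt += 1
    if model == "ER":
        nxt = 1
    name = model + ("+constrained" if constrained else "")
    return MkModelSpec(states=states, share=share, root=root, name=name)


# ----------------------------------------------------------------------
# likelihood machinery
# ----------------------------------------------------------------------
def tip_partials(tree: TimeTree, tip_states: dict, states) -> np.ndarray:
    """(n_tips, m) indicator rows; missing/None/ambiguous -> all ones."""
    states = tuple(states)
    m = len(states)
    X = np.zeros((tree.n_tips, m))
    for i, lab in enumerate(tree.tip_labels):
        if lab not in tip_states:
            raise KeyError(f"tip {lab!r} missing from the state table")
        s = tip_states[lab]
        if s is None or (isinstance(s, float) and np.isnan(s)):
            X[i] = 1.0
        elif isinstance(s, (set, frozenset, list, tuple)):
            for y in s:
                X[i, states.index(y)] = 1.0
        else:
            if s not in states:
                raise ValueError(f"state {s!r} at tip {lab!r} not in alphabet")
            X[i, states.index(s)] = 1.0
    return X


def _branch_matrices(tree: TimeTree, Q: np.ndarray) -> list:
    P = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        if tree.parent[v] >= 0:
            P[v] = expm(Q * tree.brlen[v])
    return P


def _down_pass(tree: TimeTree, X: np.ndarray, P: list):
    """Partial likelihoods D[v] (scaled) and the accumulated log-scale."""
    m = X.shape[1]
    D = np.zeros((tree.n_nodes, m))
    logscale = 0.0
    for v in tree.postorder:
        if v < tree.n_tips:
            D[v] = X[v]
            continue
        acc = np.ones(m)
        for c in tree.children[v]:
            acc = acc * (P[c] @ D[c])
        s = acc.sum()
        if s <= 0 or not np.isfinite(s):
            return D, -np.inf
        D[v] = acc / s
        logscale += np.log(s)
    return D, logscale


def _root_likelihood(Droot: np.ndarray, spec: MkModelSpec, rates) -> float:
    if spec.root == "uniform":
        prior = np.full(spec.n_states, 1.0 / spec.n_states)
    elif spec.root == "stationary":
        prior = spec.stationary(rates)
    else:  # FitzJohn: weight each state by its share of the data likelihood
        s = Droot.sum()
        prior = Droot / s if s > 0 else np.full(spec.n_states, 1.0 / spec.n_states)
    return float(prior @ Droot)


def mk_loglik(tree: TimeTree, tip_states: dict, spec: MkModelSpec, rates) -> float:
    """Pruning log-likelihood of the tip data under ``Q(rates)``."""
    Q = spec.rate_matrix(rates)
    X = tip_partials(tree, tip_states, spec.states)
    P = _branch_matrices(tree, Q)
    D, logscale = _down_pass(tree, X, P)
    if not np.isfinite(logscale):
        return -np.inf
    L = _root_likelihood(D[tree.root], spec, rates)
    if L <= 0:
        return -np.inf
    return float(np.log(L) + logscale)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
@dataclass
class MkFitResult:
    spec: MkModelSpec
    rates: np.ndarray
    loglik: float
    n_params: int
    aic: float
    aicc: float
    n_tips: int
    start_logliks: np.ndarray = field(default=None, repr=False)

    @property
    def rate_matrix(self) -> np.ndarray:
        return self.spec.rate_matrix(self.rates)


LOG_RATE_BOUNDS = (np.log(1e-9), np.log(1e3))


def fit_mk(tree: TimeTree, tip_states: dict, spec: MkModelSpec,
           n_starts: int = 10, seed=0) -> MkFitResult:
    """Maximum-likelihood rates by multi-start box-constrained optimisation.

    Optimises in log-rate space (bounds 1e-9..1e3 per my) from ``n_starts``
    random initial points drawn log-uniformly around the characteristic
    rate scale 1 / tree depth.
    """
    rng = np.random.default_rng(seed)
    X = tip_partials(tree, tip_states, spec.states)
    definite = X.sum(axis=1) == 1
    if np.flatnonzero(X[definite].sum(axis=0) > 0).size < 2:
        import warnings

        warnings.warn("fewer than two observed states; fit will sit on the "
                      "lower rate bound", stacklevel=2)
    k = spec.n_params
    scale = 1.0 / max(tree.depth.max(), 1e-12)

    def nll(logr):
        val = mk_loglik(tree, tip_states, spec, np.exp(logr))
        return -val if np.isfinite(val) else 1e10

    best = None
    start_lls = []
    for s in range(max(1, n_starts)):
        if s == 0:
            x0 = np.full(k, np.log(scale))
        else:
            x0 = np.log(scale) + rng.uniform(np.log(0.01), np.log(100.0), size=k)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[LOG_RATE_BOUNDS] * k,
                       options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500})
        start_lls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    ll = -best.fun
    n = tree.n_tips
    aic = 2 * k - 2 * ll
    denom = n - k - 1
    aicc = aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)
    return MkFitResult(spec=spec, rates=rates, loglik=ll, n_params=k,
                       aic=aic, aicc=aicc, n_tips=n,
                       start_logliks=np.asarray(start_lls))


# ----------------------------------------------------------------------
# marginal ancestral states
# ----------------------------------------------------------------------
def marginal_asr(tree: TimeTree, tip_states: dict, spec: MkModelSpec,
                 rates) -> np.ndarray:
    """Per-node marginal state probabilities (re-rooting up/down passes).

    Returns an (n_nodes, m) array, rows summing to 1; tip rows concentrate
    on the observed state (spread over compatible states when ambiguous).
    """
    Q = spec.rate_matrix(rates)
    X = tip_partials(tree, tip_states, spec.states)
    P = _branch_matrices(tree, Q)
    D, logscale = _down_pass(tree, X, P)
    if not np.isfinite(logscale):
        raise ValueError("zero likelihood: data impossible under this model")
    m = spec.n_states
    if spec.root == "uniform":
        prior = np.full(m, 1.0 / m)
    elif spec.root == "stationary":
        prior = spec.stationary(rates)
    else:
        prior = D[tree.root] / D[tree.root].sum()
    # outside pass: O[v][i] = (scaled) likelihood of everything not below v
    O = np.zeros_like(D)
    O[tree.root] = prior
    for u in tree.postorder[::-1]:
        if u < tree.n_tips:
            continue
        msgs = {c: P[c] @ D[c] for c in tree.children[u]}
        for c in tree.children[u]:
            W = O[u].copy()
            for c2, msg in msgs.items():
                if c2 != c:
                    W = W * msg
            Ov = W @ P[c]
            s = Ov.sum()
            O[c] = Ov / s if s > 0 else Ov
    marg = D * O
    tot = marg.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return marg / tot
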