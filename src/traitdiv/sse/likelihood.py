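"""Likelihood and marginal ancestral reconstruction for SSE models."""

from __future__ import annotations

import numpy as np

from ..coding import OBSERVED_CODES
from ..tree import TimeTree, check_ultrametric
from ._kernels import branch_propagator, integrate_branch, tree_loglik
from .spec import SSEModelSpec

__all__ = ["sse_loglik", "marginal_reconstruction_sse", "prepare_tree"]

RTOL, ATOL = 1e-8, 1e-10


def prepare_tree(tree: TimeTree):
    """Flat arrays for the kernels; requires a bifurcating ultrametric tree."""
    ok, dev = check_ultrametric(tree, tol=1e-6)
    if not ok:
        raise ValueError(f"SSE models need an ultrametric tree (spread {dev:g})")
    n = tree.n_nodes
    children = np.full((n, 2), -1, dtype=np.int64)
    is_tip = np.zeros(n, dtype=np.bool_)
    for v in range(n):
        ch = tree.children[v]
        if v < tree.n_tips:
            if ch:
                raise ValueError("tip with children?")
            is_tip[v] = True
        else:
            if len(ch) != 2:
                raise ValueError(
                    "SSE likelihood requires a fully bifurcating tree "
                    f"(node {v} has {len(ch)} children)"
                )
            children[v] = ch
    return children, is_tip, tree.brlen.astype(float), tree.postorder, tree.root


def _tip_matrices(tree: TimeTree, tip_codes: dict, spec: SSEModelSpec):
    K = spec.n_states
    rho_c = spec.rho_per_composite()
    tipD = np.zeros((tree.n_nodes, K))
    for i, lab in enumerate(tree.tip_labels):
        if lab not in tip_codes:
            raise KeyError(f"tip {lab!r} missing from the code table")
        c = tip_codes[lab]
        if c in ("?", None):
            tipD[i] = rho_c
            continue
        if c not in OBSERVED_CODES:
            raise ValueError(f"tip {lab!r} has unobservable code {c!r}")
        o = OBSERVED_CODES.index(c)
        for h in range(spec.hidden):
            tipD[i, h * 3 + o] = rho_c[h * 3 + o]
    E0 = 1.0 - rho_c
    return tipD, E0


def sse_loglik(tree: TimeTree, tip_codes: dict, spec: SSEModelSpec, theta,
               rtol: float = RTOL, atol: float = ATOL) -> float:
    """Log-likelihood of the tip codes under one SSE model.

    ``theta`` packs [tau classes, eps classes, q classes]; the root uses
    FitzJohn weighting (or uniform) and, by default, conditions on the
    survival of both root lineages.
    """
    children, is_tip, brlen, postorder, root = prepare_tree(tree)
    lam, mu, Q = spec.rates(theta)
    qtot = Q.sum(axis=1)
    tipD, E0 = _tip_matrices(tree, tip_codes, spec)
    root_mode = 0 if spec.root == "fitzjohn" else 1
    ll = tree_loglik(children, is_tip, brlen, postorder, root,
                     tipD, E0, lam, mu, Q, qtot, root_mode,
                     spec.condition_on_survival, rtol, atol)
    return float(ll)


def marginal_reconstruction_sse(tree: TimeTree, tip_codes: dict,
                                spec: SSEModelSpec, theta,
                                rtol: float = RTOL, atol: float = ATOL):
    """Per-node marginal probabilities over composite states.

    Down pass: standard pruning storing branch-top E and D.  Up pass: the D
    system is linear given E, so each branch has a fundamental matrix M with
    D_top = M D_bottom; transporting the root weights through M^T yields the
    outside vector, and the marginal at a node is the normalised product of
    inside and outside vectors.  Returns an (n_nodes, K) array; sum over
    hidden classes for observed-state marginals.
    """
    children, is_tip, brlen, postorder, root = prepare_tree(tree)
    lam, mu, Q = spec.rates(theta)
    qtot = Q.sum(axis=1)
    tipD, E0 = _tip_matrices(tree, tip_codes, spec)
    K = spec.n_states
    n = tree.n_nodes

    Ebot = np.zeros((n, K))
    Dbot = np.zeros((n, K))   # normalised inside vector at the node itself
    Etop = np.zeros((n, K))
    Dtop = np.zeros((n, K))
    for v in postorder:
        if is_tip[v]:
            Ebot[v] = E0
            Dbot[v] = tipD[v]
        else:
            c1, c2 = children[v]
            Ebot[v] = Etop[c1]
            d = lam * Dtop[c1] * Dtop[c2]
            s = d.sum()
            if not s > 0:
                raise ValueError("zero likelihood during reconstruction")
            Dbot[v] = d / s
        if v == root:
            break
        y = np.concatenate([Ebot[v], Dbot[v]])
        y = integrate_branch(y, brlen[v], lam, mu, Q, qtot, rtol, atol)
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"integration failed on branch above node {v}")
        Etop[v] = np.clip(y[:K], 0.0, 1.0)
        d = np.clip(y[K:], 0.0, None)
        Dtop[v] = d / d.sum()

    w = Dbot[root] / Dbot[root].sum() if spec.root == "fitzjohn" \
        else np.full(K, 1.0 / K)
    R = np.zeros((n, K))
    if spec.condition_on_survival:
        R[root] = w / (lam * (1.0 - Ebot[root]) ** 2)
    else:
        R[root] = w
    R[root] /= R[root].sum()

    for u in postorder[::-1]:
        if is_tip[u]:
            continue
        c1, c2 = children[u]
        for c, s_ in ((c1, c2), (c2, c1)):
            r_top = R[u] * lam * Dtop[s_]
            _, M = branch_propagator(Ebot[c], brlen[c], lam, mu, Q, qtot,
                                     rtol, atol)
            r = M.T @ r_top
            tot = r.sum()
            R[c] = r / tot if tot > 0 else r
    marg = R * Dbot
    tot = marg.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return marg / tot


def observed_marginals(marginals: np.ndarray, hidden: int) -> np.ndarray:
    """Sum composite-state marginals over hidden classes -> (n_nodes, 3)."""
    n = marginals.shape[0]
    return marginals.reshape(n, hidden, 3).sum(axis=1)
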