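"""Stochastic character mapping: sampled histories and transition counts.

Histories are drawn from the joint conditional distribution of node states
(backward pruning, forward sampling) and within-branch paths are sampled
conditional on branch endpoints by uniformization, which remains exact when
endpoint states differ and rates are small — no rejection loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mode as _mode

from .mk import MkModelSpec, _branch_matrices, _down_pass, tip_partials
from .tree import TimeTree

__all__ = ["StochasticMapSet", "sample_stochastic_maps", "count_transitions"]

MAX_JUMPS = 100_000


@dataclass
class StochasticMapSet:
    """M sampled histories on one tree under one fitted Mk model."""

    tree: TimeTree = field(repr=False)
    states: tuple
    node_states: np.ndarray          # (M, n_nodes) sampled state indices
    segments: list = field(repr=False)  # [map][node] -> [(state_idx, duration), ...]
    counts: np.ndarray               # (M, m, m) integer per-map change counts

    @property
    def n_maps(self) -> int:
        return self.node_states.shape[0]

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def modal_counts(self) -> np.ndarray:
        return _mode(self.counts, axis=0).mode

    def to_simmap_newick(self, which: int = 0) -> str:
        """One map as a SIMMAP-annotated Newick string."""
        segs = self.segments[which]

        def annot(v):
            parts = [f"{self.states[s]},{d:.8g}" for s, d in segs[v]]
            return "{" + ":".join(parts) + "}"

        def rec(v):
            if v < self.tree.n_tips:
                core = self.tree.labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.tree.children[v]) + ")"
            if self.tree.parent[v] < 0:
                return core
            return f"{core}:{annot(v)}{self.tree.brlen[v]:.8g}"

        return rec(self.tree.root) + ";"


def _sample_path(a: int, b: int, t: float, Q: np.ndarray, R: np.ndarray,
                 Lam: float, Pab: float, rng) -> list:
    """Uniformized path from state ``a`` to ``b`` over duration ``t``.

    Returns ``[(state, duration), ...]``; consecutive states differ.
    """
    if Lam <= 0 or t <= 0:
        return [(a, t)]
    # number of uniformized jumps ~ P(N=n | a, b, t)
    u = rng.random()
    pois = np.exp(-Lam * t)
    term = pois  # e^{-Lt} (Lt)^n / n!
    r_vec = np.zeros(R.shape[0])
    r_vec[a] = 1.0  # e_a R^n, updated incrementally
    acc = term * (1.0 if a == b else 0.0) / Pab
    n = 0
    while acc < u and n < MAX_JUMPS:
        n += 1
        term *= Lam * t / n
        r_vec = r_vec @ R
        acc += term * r_vec[b] / Pab
    if n == 0:
        return [(a, t)]
    # jump-chain states by backward powers of R
    Rpow = [np.eye(R.shape[0])]
    for _ in range(n):
        Rpow.append(Rpow[-1] @ R)
    chain = [a]
    for step in range(1, n):
        prev = chain[-1]
        w = R[prev] * Rpow[n - step][:, b]
        tot = w.sum()
        if tot <= 0:
            chain.append(b)
            continue
        chain.append(int(rng.choice(w.size, p=w / tot)))
    chain.append(b)
    times = np.sort(rng.random(n)) * t
    # collapse virtual (self) jumps into segments
    segs = []
    cur = a
    last = 0.0
    for s, tm in zip(chain[1:], times):
        if s != cur:
            segs.append((cur, tm - last))
            cur = s
            last = tm
    segs.append((cur, t - last))
    return segs


def sample_stochastic_maps(tree: TimeTree, tip_states: dict, spec: MkModelSpec,
                           rates, n_maps: int = 100, seed=0) -> StochasticMapSet:
    """Sample ``n_maps`` full character histories conditional on tip data."""
    if n_maps < 1:
        raise ValueError("need at least one map")
    rng = np.random.default_rng(seed)
    Q = spec.rate_matrix(rates)
    m = spec.n_states
    X = tip_partials(tree, tip_states, spec.states)
    P = _branch_matrices(tree, Q)
    D, logscale = _down_pass(tree, X, P)
    if not np.isfinite(logscale):
        raise ValueError("zero likelihood: data impossible under this model")
    if spec.root == "uniform":
        prior = np.full(m, 1.0 / m)
    elif spec.root == "stationary":
        prior = spec.stationary(rates)
    else:
        prior = D[tree.root] / D[tree.root].sum()
    root_post = prior * D[tree.root]
    root_post = root_post / root_post.sum()

    Lam = float(-Q.diagonal().min())
    R = np.eye(m) + (Q / Lam if Lam > 0 else 0.0 * Q)
    preorder = tree.postorder[::-1]

    all_states = np.zeros((n_maps, tree.n_nodes), dtype=np.int64)
    all_segments = []
    all_counts = np.zeros((n_maps, m, m), dtype=np.int64)
    for mi in range(n_maps):
        ns = np.zeros(tree.n_nodes, dtype=np.int64)
        segs = [None] * tree.n_nodes
        ns[tree.root] = int(rng.choice(m, p=root_post))
        segs[tree.root] = [(ns[tree.root], 0.0)]
        for v in preorder:
            p = tree.parent[v]
            if p < 0:
                continue
            w = P[v][ns[p]] * D[v]
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError(
                    f"no allowed endpoint state on branch above node {v}"
                )
            ns[v] = int(rng.choice(m, p=w / tot))
            segs[v] = _sample_path(ns[p], ns[v], tree.brlen[v], Q, R, Lam,
                                   P[v][ns[p], ns[v]], rng)
            for (s1, _), (s2, _) in zip(segs[v][:-1], segs[v][1:]):
                all_counts[mi, s1, s2] += 1
        all_states[mi] = ns
        all_segments.append(segs)
    return StochasticMapSet(tree=tree, states=spec.states,
                            node_states=all_states, segments=all_segments,
                            counts=all_counts)


@dataclass
class TransitionCounts:
    states: tuple
    per_map: np.ndarray     # (M, m, m) integers
    mean: np.ndarray
    modal: np.ndarray
    mask: np.ndarray = None  # structurally-zero pairs, if any

    def to_frame(self):
        import pandas as pd

        rows = []
        m = len(self.states)
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                rows.append({
                    "from": self.states[i],
                    "to": self.states[j],
                    "mean_count": self.mean[i, j],
                    "modal_count": int(self.modal[i, j]),
                    "structural_zero": bool(self.mask[i, j]) if self.mask is not None else False,
                })
        return pd.DataFrame(rows)


def count_transitions(maps: StochasticMapSet, spec: MkModelSpec = None) -> TransitionCounts:
    """Per-pair transition counts: per-map integers, means, and modes."""
    if maps.n_maps == 0:
        raise ValueError("empty map set")
    return TransitionCounts(
        states=maps.states,
        per_map=maps.counts,
        mean=maps.mean_counts,
        modal=maps.modal_counts,
        mask=spec.mask if spec is not None else None,
    )
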