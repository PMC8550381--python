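"""Synthetic trees and traits with the structure the analyses assume.

Generators
----------
* :func:`yule_tree` — pure-birth tree conditioned on a tip count, the null
  used by the gamma/MCCR machinery;
* :func:`simulate_sse_tree` — forward state-dependent birth–death with
  anagenetic character change, extinct lineages pruned and tips subsampled
  per-state, retaining true character-history summaries;
* :func:`simulate_mk_traits` — exact continuous-time Markov evolution of a
  discrete character down a fixed tree;
* :func:`simulate_continuous_traits` — Brownian motion with a Pagel-lambda
  covariance structure;
* :func:`make_fixture_suite` — canonical text fixtures with a JSON manifest.

All generators take a :class:`numpy.random.Generator` or an integer seed and
are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tree import TimeTree

__all__ = [
    "SimScenario",
    "SimulatedSSE",
    "yule_tree",
    "simulate_sse_tree",
    "simulate_mk_traits",
    "simulate_continuous_traits",
    "shared_path_matrix",
    "make_fixture_suite",
    "ScenarioError",
]


class ScenarioError(RuntimeError):
    """Raised when a simulation scenario cannot produce a usable tree."""


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ----------------------------------------------------------------------
# pure birth conditioned on n
# ----------------------------------------------------------------------
def yule_tree(n_tips: int, birth: float = 1.0, rng=0, prefix: str = "t") -> TimeTree:
    """Pure-birth tree with exactly ``n_tips`` extant tips.

    Starts from a bifurcating root; inter-event intervals with ``j`` lineages
    are Exp(``j * birth``), including the final interval with all ``n`` tips
    (memorylessness of the process observed before the next event).
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = _rng(rng)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    start = np.zeros(n_nodes)  # time each branch began
    root = n_tips
    next_internal = n_tips + 1
    active = [0, 1]  # tip ids 0,1 hang off the root at time 0
    parent[0] = parent[1] = root
    t = 0.0
    tip_cursor = 2
    for j in range(2, n_tips):
        t += rng.exponential(1.0 / (j * birth))
        k = int(rng.integers(len(active)))
        v = active[k]
        # lineage v speciates: insert an internal node where v's branch ends
        node = next_internal
        next_internal += 1
        parent[node] = parent[v]
        start[node] = start[v]
        w = tip_cursor
        tip_cursor += 1
        parent[v] = node
        parent[w] = node
        start[v] = start[w] = t
        active.append(w)
    t += rng.exponential(1.0 / (n_tips * birth))
    end = np.full(n_nodes, t)
    # an internal node's branch ends where its children's branches begin
    for i in range(n_nodes):
        p = parent[i]
        if p >= 0:
            end[p] = start[i]
    brlen = end - start
    brlen[root] = 0.0
    labels = [f"{prefix}{i+1}" for i in range(n_tips)]
    return TimeTree(parent, brlen, labels, n_tips=n_tips)


# ----------------------------------------------------------------------
# state-dependent birth-death
# ----------------------------------------------------------------------
@dataclass
class SimScenario:
    """Parameters of one tree+trait simulation.

    ``tau`` (turnover = speciation + extinction, events/my) and ``eps``
    (extinction fraction = mu/lambda) parameterise per-state speciation
    ``lam = tau / (1 + eps)`` and extinction ``mu = tau * eps / (1 + eps)``.
    ``q`` is the anagenetic transition-rate matrix among observed states
    (rows sum ignored; diagonal unused).  ``rho`` is the per-state sampling
    fraction applied to extant tips.
    """

    tau: np.ndarray
    eps: np.ndarray
    q: np.ndarray
    target_tips: int = None
    t_stop: float = None
    rho: np.ndarray = None
    root_state: int = None          # None: uniform over states
    tip_window: float = 0.2         # accepted relative deviation from target
    max_tries: int = 1000
    state_labels: tuple = None

    def __post_init__(self):
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        k = self.tau.size
        self.q = np.zeros((1, 1)) if k == 1 else np.asarray(self.q, dtype=float)
        if self.rho is None:
            self.rho = np.ones(k)
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if np.any(self.tau < 0) or np.any(self.eps < 0) or np.any(self.q < 0):
            raise ValueError("rates must be non-negative")
        if self.target_tips is None and self.t_stop is None:
            raise ValueError("need target_tips or t_stop")
        if self.state_labels is None:
            self.state_labels = tuple(f"s{i}" for i in range(k))

    @property
    def n_states(self) -> int:
        return self.tau.size

    @property
    def lam(self) -> np.ndarray:
        return self.tau / (1.0 + self.eps)

    @property
    def mu(self) -> np.ndarray:
        return self.tau * self.eps / (1.0 + self.eps)


@dataclass
class SimulatedSSE:
    """One accepted realisation of a state-dependent birth-death scenario."""

    tree: TimeTree                 # extant, subsampled tree
    tip_states: dict               # tip label -> state label
    transition_counts: np.ndarray  # realized i->j anagenetic changes (full process)
    state_times: np.ndarray        # total lineage-time spent in each state
    n_extinct: int
    n_unsampled: int
    scenario: SimScenario = field(repr=False)


def simulate_sse_tree(scenario: SimScenario, rng=0) -> SimulatedSSE:
    """Forward-simulate a state-dependent birth-death tree.

    Runs the Gillespie process from a bifurcating root, prunes extinct
    lineages, subsamples extant tips per-state with probability ``rho``,
    and retries until the surviving tip count falls in the acceptance
    window (``target_tips`` mode) or returns directly (``t_stop`` mode).
    """
    rng = _rng(rng)
    sc = scenario
    for _ in range(sc.max_tries):
        out = _simulate_once(sc, rng)
        if out is None:
            continue
        return out
    raise ScenarioError(
        "no accepted tree within retry budget; "
        "adjust rates, target size, or the acceptance window"
    )


def _simulate_once(sc: SimScenario, rng) -> "SimulatedSSE | None":
    k = sc.n_states
    lam, mu = sc.lam, sc.mu
    qrow = sc.q.copy()
    np.fill_diagonal(qrow, 0.0)
    qtot = qrow.sum(axis=1)
    if sc.root_state is None:
        root_state = int(rng.integers(k))
    else:
        root_state = sc.root_state

    # root splits at t=0 into two lineages
    nodes_parent = [-1, 0, 0]
    nodes_start = [0.0, 0.0, 0.0]
    nodes_state = [root_state, root_state, root_state]
    nodes_end = [0.0, None, None]          # None while active
    nodes_kind = ["internal", None, None]  # internal / extinct / extant
    active = [1, 2]
    active_state = {1: root_state, 2: root_state}

    counts = np.zeros((k, k))
    state_times = np.zeros(k)
    t = 0.0
    cap = None
    if sc.target_tips is not None:
        cap = int(np.ceil(sc.target_tips * 4)) + 20  # runaway guard

    while True:
        if not active:
            return None  # total extinction
        st = np.array([active_state[v] for v in active])
        per = lam[st] + mu[st] + qtot[st]
        total = per.sum()
        if total <= 0:
            # nothing can happen: stop at t_stop if given, else reject
            if sc.t_stop is not None:
                t_next = np.inf
            else:
                return None
        else:
            t_next = t + rng.exponential(1.0 / total)

        stop_now = None
        if sc.t_stop is not None and t_next >= sc.t_stop:
            stop_now = sc.t_stop
        if sc.target_tips is not None and len(active) >= sc.target_tips:
            # present drawn uniformly inside the constant-count interval
            if np.isfinite(t_next):
                stop_now = t + (t_next - t) * rng.random()
            else:
                return None
        if stop_now is not None:
            np.add.at(state_times, st, stop_now - t)
            for v in active:
                nodes_end[v] = stop_now
                nodes_kind[v] = "extant"
            break

        # time accrues in each active lineage's current state
        np.add.at(state_times, st, t_next - t)
        t = t_next
        u = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(per), u))
        idx = min(idx, len(active) - 1)
        v = active[idx]
        s = active_state[v]
        u2 = rng.random() * per[idx]
        if u2 < lam[s]:
            # speciation: v closes as an internal node, two children open
            nodes_end[v] = t
            nodes_kind[v] = "internal"
            for _ in range(2):
                nodes_parent.append(v)
                nodes_start.append(t)
                nodes_state.append(s)
                nodes_end.append(None)
                nodes_kind.append(None)
                w = len(nodes_parent) - 1
                active.append(w)
                active_state[w] = s
            active.remove(v)
            del active_state[v]
            if cap is not None and len(active) > cap:
                return None
        elif u2 < lam[s] + mu[s]:
            nodes_end[v] = t
            nodes_kind[v] = "extinct"
            active.remove(v)
            del active_state[v]
        else:
            # anagenetic state change
            u3 = u2 - lam[s] - mu[s]
            j = int(np.searchsorted(np.cumsum(qrow[s]), u3))
            j = min(j, k - 1)
            counts[s, j] += 1
            active_state[v] = j
            nodes_state[v] = j  # state at lineage end; start states kept via parent

    # ---- assemble the complete tree, then prune to sampled extant tips ----
    n_all = len(nodes_parent)
    extant = [v for v in range(n_all) if nodes_kind[v] == "extant"]
    n_extinct = sum(1 for v in range(n_all) if nodes_kind[v] == "extinct")
    if len(extant) < 2:
        return None
    keep = []
    for v in extant:
        if rng.random() < sc.rho[nodes_state[v]]:
            keep.append(v)
    if len(keep) < 2:
        return None
    if sc.target_tips is not None:
        lo = sc.target_tips * (1 - sc.tip_window)
        hi = sc.target_tips * (1 + sc.tip_window)
        if not (lo <= len(keep) <= hi):
            return None

    # flat arrays for the complete tree: tips first
    tipish = [v for v in range(n_all) if nodes_kind[v] in ("extant", "extinct")]
    internals = [v for v in range(n_all) if nodes_kind[v] == "internal"]
    index = {v: i for i, v in enumerate(tipish)}
    index.update({v: len(tipish) + j for j, v in enumerate(internals)})
    parent_arr = np.full(n_all, -1, dtype=np.int64)
    brlen_arr = np.zeros(n_all)
    for v in range(n_all):
        i = index[v]
        p = nodes_parent[v]
        parent_arr[i] = index[p] if p >= 0 else -1
        if p >= 0:
            brlen_arr[i] = nodes_end[v] - nodes_start[v]
    labels = [f"t{index[v]+1}" for v in tipish]
    full = TimeTree(parent_arr, brlen_arr, labels, n_tips=len(tipish))
    keep_labels = [f"t{index[v]+1}" for v in keep]
    pruned = full.prune_to(keep_labels) if len(keep) < len(tipish) else full
    tip_states = {
        f"t{index[v]+1}": sc.state_labels[nodes_state[v]] for v in keep
    }
    return SimulatedSSE(
        tree=pruned,
        tip_states=tip_states,
        transition_counts=counts,
        state_times=state_times,
        n_extinct=n_extinct,
        n_unsampled=len(extant) - len(keep),
        scenario=sc,
    )


# ----------------------------------------------------------------------
# discrete traits on a fixed tree
# ----------------------------------------------------------------------
def simulate_mk_traits(tree: TimeTree, Q: np.ndarray, rng=0, labels=None,
                       root_state: int = None):
    """Evolve a discrete character down ``tree`` by exact CTMC sampling.

    Returns ``(tip_states, node_states, counts)`` where ``tip_states`` maps
    tip label -> state label, ``node_states`` gives the true state at every
    node (index order of the tree), and ``counts`` is the realized i->j
    change matrix.  The root state is uniform unless given.
    """
    rng = _rng(rng)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if labels is None:
        labels = [str(i) for i in range(k)]
    rates = -np.diag(Q)
    jump = Q.copy()
    np.fill_diagonal(jump, 0.0)
    node_states = np.zeros(tree.n_nodes, dtype=np.int64)
    counts = np.zeros((k, k), dtype=np.int64)
    order = tree.postorder[::-1]  # root first
    node_states[tree.root] = (
        int(rng.integers(k)) if root_state is None else root_state
    )
    for v in order:
        p = tree.parent[v]
        if p < 0:
            continue
        s = node_states[p]
        t_left = tree.brlen[v]
        while rates[s] > 0:
            w = rng.exponential(1.0 / rates[s])
            if w >= t_left:
                break
            t_left -= w
            j = int(np.searchsorted(np.cumsum(jump[s]), rng.random() * rates[s]))
            j = min(j, k - 1)
            counts[s, j] += 1
            s = j
        node_states[v] = s
    tip_states = {tree.labels[i]: labels[node_states[i]] for i in range(tree.n_tips)}
    return tip_states, node_states, counts


# ----------------------------------------------------------------------
# continuous traits
# ----------------------------------------------------------------------
def shared_path_matrix(tree: TimeTree, lam: float = 1.0) -> np.ndarray:
    """Brownian-motion covariance (shared root-to-MRCA path lengths).

    With ``lam`` < 1 the off-diagonal entries are scaled (Pagel's lambda
    transform); diagonals are untouched.
    """
    n = tree.n_tips
    depth = tree.depth
    C = np.zeros((n, n))
    tips_below = [None] * tree.n_nodes
    for v in tree.postorder:
        if v < n:
            tips_below[v] = [v]
        else:
            groups = [tips_below[c] for c in tree.children[v]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.asarray(groups[a])
                    ib = np.asarray(groups[b])
                    C[np.ix_(ia, ib)] = depth[v]
                    C[np.ix_(ib, ia)] = depth[v]
            tips_below[v] = [t for g in groups for t in g]
    np.fill_diagonal(C, depth[:n])
    if lam != 1.0:
        off = C - np.diag(np.diag(C))
        C = lam * off + np.diag(np.diag(C))
    return C


def simulate_continuous_traits(tree: TimeTree, sigma2: float = 1.0,
                               lam: float = 1.0, rng=0, mean: float = 0.0,
                               size: int = None):
    """Draw tip values from N(mean, sigma2 * C(lam)).

    Returns a 1-D array in tip order, or ``(size, n_tips)`` when ``size``
    is given.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    rng = _rng(rng)
    C = shared_path_matrix(tree, lam)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    shape = (tree.n_tips,) if size is None else (size, tree.n_tips)
    z = rng.standard_normal(shape)
    return mean + np.sqrt(sigma2) * z @ L.T


# ----------------------------------------------------------------------
# fixture suite
# ----------------------------------------------------------------------
def make_fixture_suite(out_dir, seed: int = 20_240_101) -> dict:
    """Write the canonical text fixtures and a manifest of their provenance.

    Includes hand-checkable 2/3/4/6-tip trees, a 128-tip pure-birth tree,
    and a 300-tip state-dependent scenario with three observed states, two
    hidden diversification classes in the generating process, constrained
    transitions, and per-state sampling fractions (0.72, 0.68, 0.76).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "files": {}}

    hand = {
        "tree2.nwk": "(A:1.0,B:1.0);",
        "tree3.nwk": "((A:1.0,B:1.0):1.0,C:2.0);",
        "tree4.nwk": "((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5);",
        "tree6.nwk": "(((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5):1.0,(E:2.0,F:2.0):1.0);",
    }
    for name, text in hand.items():
        (out / name).write_text(text + "\n")
        manifest["files"][name] = {"generator": "hand-written ultrametric fixture"}

    t128 = yule_tree(128, birth=1.0, rng=seed)
    t128.write(out / "yule128.nwk")
    manifest["files"]["yule128.nwk"] = {
        "generator": "yule_tree", "n_tips": 128, "birth": 1.0, "seed": seed,
    }

    # 3 observed states x 2 hidden classes in the generating process;
    # hidden class B doubles turnover, transitions constrained through the
    # intermediate state, per-state sampling fractions as in the study design
    tau_obs = np.array([4.0, 5.0, 6.0])
    tau = np.concatenate([tau_obs, 2.0 * tau_obs]) / 15.0
    eps = np.full(6, 0.3)
    q = np.zeros((6, 6))
    q_obs = 0.03
    q_hidden = 0.01
    for h in (0, 3):
        for a, b in ((0, 2), (2, 0), (1, 2), (2, 1)):  # through intermediate only
            q[h + a, h + b] = q_obs
    for i in range(3):
        q[i, i + 3] = q[i + 3, i] = q_hidden
    rho_obs = np.array([0.72, 0.68, 0.76])
    sc = SimScenario(
        tau=tau, eps=eps, q=q, target_tips=300,
        rho=np.concatenate([rho_obs, rho_obs]),
        state_labels=("01A", "10A", "11A", "01B", "10B", "11B"),
    )
    sim = simulate_sse_tree(sc, rng=seed + 1)
    sim.tree.write(out / "sse300.nwk")
    rows = ["species,state"]
    for lab in sim.tree.tip_labels:
        rows.append(f"{lab},{sim.tip_states[lab][:2]}")  # observed part only
    (out / "sse300_states.csv").write_text("\n".join(rows) + "\n")
    from collections import Counter
    state_counts = dict(Counter(v[:2] for v in sim.tip_states.values()))
    manifest["files"]["sse300.nwk"] = {
        "generator": "simulate_sse_tree",
        "seed": seed + 1,
        "target_tips": 300,
        "n_tips": sim.tree.n_tips,
        "tau": tau.tolist(),
        "eps": eps.tolist(),
        "q_obs": q_obs,
        "q_hidden": q_hidden,
        "rho": rho_obs.tolist(),
        "tip_state_counts": state_counts,
    }
    manifest["files"]["sse300_states.csv"] = {
        "generator": "simulate_sse_tree (observed two-character codes)",
        "tip_state_counts": state_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ----------------------------------------------------------------------
# full synthetic trait table
# ----------------------------------------------------------------------
def simulate_trait_table(tree: TimeTree, rng=0, sigma2_log_tl: float = 0.004,
                         lam_tl: float = 0.9, q_ecotype: float = None,
                         q_farming: float = None, q_size: float = None,
                         size_centers=(6.8, 12.2, 22.0)):
    """A complete trait table (sizes, depth, ecotype, farming) on a tree.

    Total length is clustered, as gap-codable size data must be: a latent
    small/medium/large class evolves under the constrained Markov process
    (no direct small<->large moves) and log-length is the class centre
    (default 6.8 / 12.2 / 22 cm, matching the small-medium-large ranges of
    the study system) plus a Brownian within-class deviation
    (``sigma2_log_tl`` is that total log-scale variance); body depth
    maps a Brownian deviate into the observed 27-66 %SL range through a
    logistic; ecotype
    evolves under a constrained 3-state Markov process (no direct
    benthic<->pelagic moves) and farming as a binary gain/loss character.
    """
    import pandas as pd

    from .coding import TraitTable

    rng = _rng(rng)
    depth = tree.depth.max()
    if q_ecotype is None:
        q_ecotype = 1.5 / depth
    if q_farming is None:
        q_farming = 0.8 / depth
    if q_size is None:
        q_size = 2.0 / depth
    scale = 1.0 / depth
    # latent size class: constrained S <-> M <-> L walk
    Qs = np.array([
        [-q_size, q_size, 0.0],
        [q_size, -2 * q_size, q_size],
        [0.0, q_size, -q_size],
    ])
    size_cls, _, _ = simulate_mk_traits(tree, Qs, rng, labels=[0, 1, 2],
                                        root_state=1)
    centers = np.log(np.asarray(size_centers, dtype=float))
    cls_idx = np.array([int(size_cls[t]) for t in tree.tip_labels])
    log_tl = centers[cls_idx] + simulate_continuous_traits(
        tree, sigma2_log_tl * scale, lam_tl, rng)
    bd_lat = simulate_continuous_traits(tree, 1.0 * scale, lam_tl, rng)
    body_depth = 27.0 + 39.0 / (1.0 + np.exp(-bd_lat))
    Qe = np.array([
        [-q_ecotype, 0.0, q_ecotype],
        [0.0, -q_ecotype, q_ecotype],
        [q_ecotype, q_ecotype, -2 * q_ecotype],
    ])
    eco, _, _ = simulate_mk_traits(
        tree, Qe, rng, labels=["benthic", "pelagic", "intermediate"])
    Qf = np.array([[-q_farming, q_farming], [q_farming / 2, -q_farming / 2]])
    farm, _, _ = simulate_mk_traits(tree, Qf, rng, labels=[0, 1], root_state=0)
    df = pd.DataFrame({
        "species": tree.tip_labels,
        "total_length_cm": np.exp(log_tl),
        "body_depth_pct": body_depth,
        "ecotype": [eco[t] for t in tree.tip_labels],
        "farming": [farm[t] for t in tree.tip_labels],
    })
    return TraitTable(df)
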