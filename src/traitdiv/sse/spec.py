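"""Model structures for multistate (hidden-state) speciation-extinction.

A model is a parameter-sharing structure over K = 3 x H composite states
(three observed two-character codes ``01``, ``10``, ``11`` crossed with H
hidden diversification classes).  Diversification is parameterised by net
turnover ``tau = lam + mu`` and extinction fraction ``eps = mu / lam``
(the reparameterisation that behaves better than (lam, mu) when speciation
and extinction are correlated), so

    lam_i = tau_i / (1 + eps_i),    mu_i = tau_i * eps_i / (1 + eps_i).

Transitions are anagenetic single-character moves: observed-state moves run
through the intermediate code ``11`` only (the constrained structure:
``01<->11`` and ``10<->11``, never ``01<->10``), hidden-class moves change
the hidden class only, and simultaneous observed+hidden jumps are excluded.
The never-observed code ``00`` is excluded from the state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..coding import OBSERVED_CODES

__all__ = ["SSEModelSpec", "build_model_set", "TRAIT_STATE_NAMES"]

#: index of each observed code in the composite layout
OBS_INDEX = {c: i for i, c in enumerate(OBSERVED_CODES)}
INTERMEDIATE = OBS_INDEX["11"]

#: human state names per trait, in observed-code order (01, 10, 11)
TRAIT_STATE_NAMES = {
    "size": ("small", "large", "medium"),
    "ecotype": ("benthic", "pelagic", "intermediate"),
}

HIDDEN_NAMES = "ABC"


@dataclass
class SSEModelSpec:
    """Sharing structure for one diversification model."""

    name: str
    description: str
    hidden: int
    tau_share: np.ndarray          # (K,) parameter-class index per composite
    eps_share: np.ndarray          # (K,)
    q_share: np.ndarray            # (K, K); -1 = structural zero
    rho: np.ndarray                # (3,) sampling fraction per observed state
    root: str = "fitzjohn"         # or "uniform"
    condition_on_survival: bool = True

    def __post_init__(self):
        self.tau_share = np.asarray(self.tau_share, dtype=np.int64)
        self.eps_share = np.asarray(self.eps_share, dtype=np.int64)
        self.q_share = np.asarray(self.q_share, dtype=np.int64)
        self.rho = np.asarray(self.rho, dtype=float)
        K = 3 * self.hidden
        if self.tau_share.size != K or self.eps_share.size != K:
            raise ValueError("sharing maps must cover all composite states")
        if self.q_share.shape != (K, K):
            raise ValueError("q sharing map shape mismatch")
        if np.any((self.rho <= 0) | (self.rho > 1)):
            raise ValueError("sampling fractions must lie in (0, 1]")

    # -- parameter bookkeeping -----------------------------------------
    @property
    def n_states(self) -> int:
        return 3 * self.hidden

    @property
    def n_tau(self) -> int:
        return int(self.tau_share.max()) + 1

    @property
    def n_eps(self) -> int:
        return int(self.eps_share.max()) + 1

    @property
    def n_q(self) -> int:
        m = self.q_share[self.q_share >= 0]
        return int(m.max()) + 1 if m.size else 0

    @property
    def n_params(self) -> int:
        return self.n_tau + self.n_eps + self.n_q

    def composite_labels(self) -> list:
        return [
            f"{OBSERVED_CODES[i % 3]}{HIDDEN_NAMES[i // 3]}"
            for i in range(self.n_states)
        ]

    def split_params(self, theta):
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters")
        a, b = self.n_tau, self.n_tau + self.n_eps
        return theta[:a], theta[a:b], theta[b:]

    def rates(self, theta):
        """(lam, mu, Q) per composite state for a packed parameter vector."""
        tau_p, eps_p, q_p = self.split_params(theta)
        tau = tau_p[self.tau_share]
        eps = eps_p[self.eps_share]
        lam = tau / (1.0 + eps)
        mu = tau * eps / (1.0 + eps)
        K = self.n_states
        Q = np.zeros((K, K))
        free = self.q_share >= 0
        Q[free] = q_p[self.q_share[free]]
        return lam, mu, Q

    def rho_per_composite(self) -> np.ndarray:
        return np.tile(self.rho, self.hidden)


# ----------------------------------------------------------------------
# transition-structure helpers
# ----------------------------------------------------------------------
def _q_structure(hidden: int, absorbing_obs: int = None,
                 relaxed_hidden: bool = False) -> np.ndarray:
    """Sharing map over composite states.

    Observed moves (through the intermediate only) get one free rate per
    ordered move, shared across hidden classes; all hidden-class moves share
    one rate, or two directional rates when ``relaxed_hidden``; moves out of
    ``absorbing_obs`` (observed index) are structurally zero.
    """
    K = 3 * hidden
    share = np.full((K, K), -1, dtype=np.int64)
    moves = [(OBS_INDEX["01"], INTERMEDIATE), (INTERMEDIATE, OBS_INDEX["01"]),
             (OBS_INDEX["10"], INTERMEDIATE), (INTERMEDIATE, OBS_INDEX["10"])]
    nxt = 0
    for a, b in moves:
        if absorbing_obs is not None and a == absorbing_obs:
            continue
        for h in range(hidden):
            share[h * 3 + a, h * 3 + b] = nxt
        nxt += 1
    if hidden > 1:
        if relaxed_hidden and hidden == 2:
            up, down = nxt, nxt + 1
            for o in range(3):
                share[o, 3 + o] = up
                share[3 + o, o] = down
        else:
            for h1 in range(hidden):
                for h2 in range(hidden):
                    if h1 == h2:
                        continue
                    for o in range(3):
                        share[h1 * 3 + o, h2 * 3 + o] = nxt
    return share


def build_model_set(trait: str = "ecotype", rho=None, root: str = "fitzjohn",
                    condition_on_survival: bool = True) -> list:
    """The eight-model comparison set for one three-state trait.

    Models: an equal-rates null ("Dull"); state-dependent diversification
    (MuSSE); state-dependent with one hidden class (MuHiSSE) and its relaxed
    variant (one extra free hidden transition rate); two absorbing variants
    (no transitions out of one extreme state); and character-independent
    nulls with 2 and 3 hidden classes (CID2/CID3).  All models use the
    constrained observed-transition mask.

    ``rho`` gives per-observed-state sampling fractions in code order
    (01, 10, 11); the default is the study-design ecotype values
    0.72 (benthic), 0.68 (pelagic), 0.76 (intermediate).
    """
    if trait not in TRAIT_STATE_NAMES:
        raise ValueError(f"unknown trait {trait!r}; use 'size' or 'ecotype'")
    names = TRAIT_STATE_NAMES[trait]
    if rho is None:
        rho = np.array([0.72, 0.68, 0.76])
    rho = np.asarray(rho, dtype=float)

    def comp(per: str, hidden: int) -> np.ndarray:
        """Composite sharing map: per 'all'|'observed'|'hidden'."""
        K = 3 * hidden
        idx = np.zeros(K, dtype=np.int64)
        for i in range(K):
            if per == "all":
                idx[i] = 0
            elif per == "observed":
                idx[i] = i % 3
            elif per == "hidden":
                idx[i] = i // 3
            else:  # per composite state
                idx[i] = i
        return idx

    common = dict(rho=rho, root=root,
                  condition_on_survival=condition_on_survival)
    ext0 = names[0].capitalize()   # small / benthic (code 01)
    ext1 = names[1].capitalize()   # large / pelagic (code 10)
    models = [
        SSEModelSpec(
            name='"Dull"', description="Equal rates", hidden=1,
            tau_share=comp("all", 1), eps_share=comp("all", 1),
            q_share=_q_structure(1), **common),
        SSEModelSpec(
            name="MuSSE", description="State dependent diversification",
            hidden=1, tau_share=comp("observed", 1),
            eps_share=comp("observed", 1), q_share=_q_structure(1), **common),
        SSEModelSpec(
            name="MuHiSSE",
            description="State dependent diversification with a hidden state",
            hidden=2, tau_share=comp("state", 2), eps_share=comp("state", 2),
            q_share=_q_structure(2), **common),
        SSEModelSpec(
            name="MuHiSSE Relaxed",
            description="Relaxed state dependent diversification with a hidden state",
            hidden=2, tau_share=comp("state", 2), eps_share=comp("state", 2),
            q_share=_q_structure(2, relaxed_hidden=True), **common),
        SSEModelSpec(
            name=f"{ext1} Absorbing",
            description=f"No transitions out of {names[1]} state",
            hidden=2, tau_share=comp("state", 2), eps_share=comp("state", 2),
            q_share=_q_structure(2, absorbing_obs=OBS_INDEX["10"]), **common),
        SSEModelSpec(
            name=f"{ext0} Absorbing",
            description=f"No transitions out of {names[0]} state",
            hidden=2, tau_share=comp("state", 2), eps_share=comp("state", 2),
            q_share=_q_structure(2, absorbing_obs=OBS_INDEX["01"]), **common),
        SSEModelSpec(
            name="CID2", description="Character-independent with 2 hidden states",
            hidden=2, tau_share=comp("hidden", 2), eps_share=comp("hidden", 2),
            q_share=_q_structure(2), **common),
        SSEModelSpec(
            name="CID3", description="Character-independent with 3 hidden states",
            hidden=3, tau_share=comp("hidden", 3), eps_share=comp("hidden", 3),
            q_share=_q_structure(3), **common),
    ]
    return models
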