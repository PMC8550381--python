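"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a route deliberately different from the
package's own: exhaustive enumeration instead of pruning, fixed-step RK4
instead of the adaptive kernel, direct formula tabulation instead of vector
code.  They are kept brutally simple so they can be checked by eye.
"""

import itertools

import numpy as np
from scipy.linalg import expm


def gap_code_bruteforce(values, k):
    """Best (k-1)-breakpoint placement by enumerating all of them.

    Maximises the summed widths of the chosen gaps; ties resolved toward
    placements using smaller values.  Returns midpoint breakpoints.
    """
    distinct = np.unique(np.asarray(values, dtype=float))
    gaps = np.diff(distinct)
    best = None
    for combo in itertools.combinations(range(gaps.size), k - 1):
        width = sum(gaps[c] for c in combo)
        key = (-width, combo)  # ties -> lexicographically smaller positions
        if best is None or key < best[0]:
            best = (key, combo)
    return np.array([(distinct[c] + distinct[c + 1]) / 2 for c in best[1]])


def gamma_direct(tree):
    """Gamma by explicit tabulation of g_j and T_k from node depths."""
    n = tree.n_tips
    depths = np.sort(tree.depth[n:])
    T_total = tree.depth[:n].max()
    g = {}
    for j in range(2, n + 1):
        lo = depths[j - 2]
        hi = depths[j - 1] if j - 1 < len(depths) else T_total
        g[j] = hi - lo
    T = {}
    acc = 0.0
    for j in range(2, n + 1):
        acc += j * g[j]
        T[j] = acc
    mean_T = np.mean([T[k] for k in range(2, n)])
    return (mean_T - T[n] / 2) / (T[n] * np.sqrt(1.0 / (12 * (n - 2))))


def mk_loglik_enumerate(tree, tip_states, spec, rates):
    """Mk likelihood by summing over every internal-node state assignment."""
    Q = spec.rate_matrix(rates)
    m = spec.n_states
    P = {v: expm(Q * tree.brlen[v]) for v in range(tree.n_nodes)
         if tree.parent[v] >= 0}
    internal = list(range(tree.n_tips, tree.n_nodes))
    X = np.zeros((tree.n_tips, m))
    for i, lab in enumerate(tree.tip_labels):
        s = tip_states[lab]
        if s is None:
            X[i] = 1.0
        else:
            X[i, spec.states.index(s)] = 1.0
    per_root = np.zeros(m)
    for assign in itertools.product(range(m), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        pr = 1.0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if v < tree.n_tips:
                pr *= P[v][amap[p]] @ X[v]
            else:
                pr *= P[v][amap[p], amap[v]]
        per_root[amap[tree.root]] += pr
    if spec.root == "uniform":
        prior = np.full(m, 1.0 / m)
    elif spec.root == "stationary":
        prior = spec.stationary(rates)
    else:
        prior = per_root / per_root.sum()
    return np.log(prior @ per_root)


def mk_marginals_enumerate(tree, tip_states, spec, rates):
    """Joint enumeration posterior over internal-node states."""
    Q = spec.rate_matrix(rates)
    m = spec.n_states
    P = {v: expm(Q * tree.brlen[v]) for v in range(tree.n_nodes)
         if tree.parent[v] >= 0}
    internal = list(range(tree.n_tips, tree.n_nodes))
    X = np.zeros((tree.n_tips, m))
    for i, lab in enumerate(tree.tip_labels):
        X[i, spec.states.index(tip_states[lab])] = 1.0
    per_root = np.zeros(m)
    joint = []
    for assign in itertools.product(range(m), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        pr = 1.0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if v < tree.n_tips:
                pr *= P[v][amap[p]] @ X[v]
            else:
                pr *= P[v][amap[p], amap[v]]
        per_root[amap[tree.root]] += pr
        joint.append((assign, pr))
    prior = per_root / per_root.sum()  # FitzJohn weights
    marg = np.zeros((len(internal), m))
    ridx = internal.index(tree.root)
    for assign, pr in joint:
        w = pr * prior[assign[ridx]]
        for vi, s in enumerate(assign):
            marg[vi, s] += w
    marg /= marg.sum(axis=1, keepdims=True)
    return internal, marg


def sse_loglik_rk4(tree, tip_codes, spec, theta, step=1e-4):
    """SSE log-likelihood by classic fixed-step RK4 on the same equations."""
    lam, mu, Q = spec.rates(theta)
    qtot = Q.sum(axis=1)
    K = spec.n_states
    rho = spec.rho_per_composite()

    def rhs(y):
        E, D = y[:K], y[K:]
        dE = mu - (lam + mu + qtot) * E + lam * E * E + Q @ E
        dD = -(lam + mu + qtot) * D + 2 * lam * E * D + Q @ D
        return np.concatenate([dE, dD])

    def integrate(y, t):
        nsteps = max(1, int(np.ceil(t / step)))
        h = t / nsteps
        for _ in range(nsteps):
            k1 = rhs(y)
            k2 = rhs(y + h / 2 * k1)
            k3 = rhs(y + h / 2 * k2)
            k4 = rhs(y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    from traitdiv.coding import OBSERVED_CODES

    logscale = 0.0
    tops = {}
    for v in tree.postorder:
        if v < tree.n_tips:
            D = np.zeros(K)
            o = OBSERVED_CODES.index(tip_codes[tree.labels[v]])
            for h in range(spec.hidden):
                D[h * 3 + o] = rho[h * 3 + o]
            y = np.concatenate([1.0 - rho, D])
        else:
            c1, c2 = tree.children[v]
            E1, D1 = tops[c1]
            _, D2 = tops[c2]
            D = lam * D1 * D2
            s = D.sum()
            logscale += np.log(s)
            y = np.concatenate([E1, D / s])
        if v == tree.root:
            Eroot, Droot = y[:K], y[K:]
            break
        y = integrate(y, tree.brlen[v])
        s = y[K:].sum()
        logscale += np.log(s)
        tops[v] = (y[:K], y[K:] / s)
    w = Droot / Droot.sum() if spec.root == "fitzjohn" else np.full(K, 1 / K)
    term = Droot / (lam * (1 - Eroot) ** 2) if spec.condition_on_survival \
        else Droot
    return np.log(w @ term) + logscale


def f_oneway_twopass(y, groups):
    """Textbook between/within mean-square ratio, two explicit passes."""
    levels = sorted(set(groups))
    n = len(y)
    grand = sum(y) / n
    ssb = 0.0
    ssw = 0.0
    for lv in levels:
        yg = [yi for yi, g in zip(y, groups) if g == lv]
        mg = sum(yg) / len(yg)
        ssb += len(yg) * (mg - grand) ** 2
        ssw += sum((yi - mg) ** 2 for yi in yg)
    return (ssb / (len(levels) - 1)) / (ssw / (n - len(levels)))
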