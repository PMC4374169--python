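"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own recursions: likelihoods by
exhaustive path enumeration, mixture fits by dense simplex grid search,
Ward heights by the Lance–Williams recurrence, consensus by direct clade
tallies.
"""

import itertools

import numpy as np


def brute_force_loglik(target, donors, gpos, ne, theta, prior=None):
    """Total copying-model likelihood by summing over all donor paths."""
    donors = np.asarray(donors)
    k, L = donors.shape
    prior = np.full(k, 1.0 / k) if prior is None else np.asarray(prior)
    g = np.diff(np.asarray(gpos, dtype=float))
    r = np.exp(-ne * g)

    def emis(l, d):
        if target[l] < 0 or donors[d, l] < 0:
            return 1.0
        return 1.0 - theta if donors[d, l] == target[l] else theta

    total = 0.0
    for path in itertools.product(range(k), repeat=L):
        p = prior[path[0]] * emis(0, path[0])
        for l in range(1, L):
            trans = (r[l - 1] if path[l] == path[l - 1] else 0.0) + (
                1.0 - r[l - 1]
            ) * prior[path[l]]
            p *= trans * emis(l, path[l])
        total += p
    return np.log(total)


def simplex_grid_best(C, c, step=0.001):
    """Best fitted-vector norm over the 3-simplex grid at the given step."""
    C = np.asarray(C, dtype=float)
    c = np.asarray(c, dtype=float)
    assert C.shape[1] == 3
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    best = np.inf
    for a1 in ticks:
        a2 = np.arange(0.0, 1.0 - a1 + step / 2, step)
        a3 = 1.0 - a1 - a2
        A = np.column_stack([np.full_like(a2, a1), a2, a3])
        resid = A @ C.T - c
        d = np.sqrt((resid**2).sum(axis=1))
        m = d.min()
        if m < best:
            best = m
    return best


def lance_williams_ward(points):
    """Ward linkage heights via the Lance–Williams update on squared
    Euclidean distances (ward.D2 convention: heights reported as sqrt)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d2 = {
        frozenset((i, j)): ((pts[i] - pts[j]) ** 2).sum()
        for i in range(n)
        for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    nxt = n
    while len(active) > 1:
        (a, b), h2 = min(
            ((tuple(sorted(p)), v) for p, v in d2.items()
             if p <= frozenset(active)),
            key=lambda kv: kv[1],
        )
        heights.append(np.sqrt(h2))
        na, nb = sizes[a], sizes[b]
        new = nxt
        nxt += 1
        for c in active - {a, b}:
            nc = sizes[c]
            dac = d2[frozenset((a, c))]
            dbc = d2[frozenset((b, c))]
            dab = d2[frozenset((a, b))]
            d2[frozenset((new, c))] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * dab
            ) / (na + nb + nc)
        active -= {a, b}
        active.add(new)
        sizes[new] = na + nb
        d2 = {p: v for p, v in d2.items() if p <= frozenset(active) or True}
    return np.array(heights)


def jackknife_se_closed_form(values):
    """sqrt((n-1)/n * sum (a_j - abar)^2) evaluated directly."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    return np.sqrt((n - 1) / n * ((v - v.mean()) ** 2).sum())
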