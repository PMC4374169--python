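"""Partitioning donor individuals from chunk-count matrices.

Each donor individual's painting yields a row of (rounded) chunk counts —
how many genome segments it copied from every other donor.  Individuals
with statistically indistinguishable rows belong to the same genetic
cluster.  Rows aggregated within a cluster are scored by a symmetric
Dirichlet-multinomial marginal likelihood; the posterior over set
partitions (with a prior uniform on the number of clusters K) is explored
by a Metropolis–Hastings MCMC over partitions with single-individual
reassignment, cluster-merge and random-binary-split moves.  The Maximum A
Posteriori (MAP) state visited across independent chains defines the donor
clusters; a greedy agglomeration of the MAP clusters produces a tree.

The donor columns of the chunk matrix stay fixed during the MCMC (they are
not re-aggregated by the evolving partition) — a deliberate simplification
that keeps the likelihood a proper Dirichlet-multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .trees import TreeNode, SupportedTree


def dirichlet_multinomial_logpmf(x: np.ndarray, beta: float) -> float:
    """Log pmf of counts ``x`` under a symmetric Dirichlet(beta) multinomial."""
    x = np.asarray(x, dtype=float)
    n = x.sum()
    m = len(x)
    return float(
        gammaln(n + 1.0)
        - gammaln(x + 1.0).sum()
        + gammaln(m * beta)
        - gammaln(m * beta + n)
        + (gammaln(x + beta) - gammaln(beta)).sum()
    )


def cluster_log_marginal(x: np.ndarray, beta: float) -> float:
    """Partition-dependent marginal of a cluster's aggregated counts.

    Equals log B(x + beta) / B(beta) with B the multivariate Beta function:
    the Dirichlet-multinomial marginal of the cluster's pooled rows with
    the per-row multinomial coefficients (constant across partitions)
    dropped.  Keeping the pooled coefficient instead would spuriously
    reward merges.
    """
    x = np.asarray(x, dtype=float)
    m = len(x)
    return float(
        gammaln(m * beta)
        - gammaln(m * beta + x.sum())
        + (gammaln(x + beta) - gammaln(beta)).sum()
    )


@dataclass
class Partition:
    """Assignment of individuals to clusters (ids dense 1..K)."""

    individuals: list[str]
    labels: np.ndarray  # 0-based internally
    beta: float = 1.0
    log_marginal_likelihood: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.individuals):
            raise ValueError("labels must align with individuals")
        self.labels = _densify(self.labels)

    @property
    def K(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for ind, lab in zip(self.individuals, self.labels):
            out.setdefault(int(lab) + 1, []).append(ind)
        return out

    def assignment(self) -> dict[str, int]:
        return {ind: int(lab) + 1 for ind, lab in zip(self.individuals, self.labels)}

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


def _densify(labels: np.ndarray) -> np.ndarray:
    _, dense = np.unique(labels, return_inverse=True)
    # preserve first-appearance order for determinism
    order: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def partition_log_marginal(X: pd.DataFrame, partition: Partition, beta: float) -> float:
    """Log marginal likelihood of a chunk matrix under a partition.

    Rows of ``X`` (individuals × donor columns) are summed within each
    cluster; each aggregated count vector is scored by the symmetric
    Dirichlet-multinomial marginal and the per-cluster log marginals are
    summed.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    Xv = X.loc[partition.individuals].to_numpy(dtype=float)
    total = 0.0
    for k in range(partition.K):
        total += cluster_log_marginal(Xv[partition.labels == k].sum(axis=0), beta)
    return total


def _log_stirling2_table(n: int) -> np.ndarray:
    """log S(n, k) for k = 0..n (Stirling numbers of the second kind)."""
    NEG = -np.inf
    prev = np.full(n + 1, NEG)
    prev[0] = 0.0  # S(0,0) = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, NEG)
        for k in range(1, m + 1):
            a = np.log(k) + prev[k] if prev[k] > NEG else NEG
            b = prev[k - 1]
            cur[k] = np.logaddexp(a, b)
        prev = cur
    return prev


def _score_partition_arrays(X, labels, beta, log_s2, n) -> float:
    labels = _densify(labels)
    K = labels.max() + 1
    tot = 0.0
    for k in range(K):
        tot += cluster_log_marginal(X[labels == k].sum(axis=0), beta)
    return tot - np.log(n) - log_s2[K]


@dataclass
class MCMCResult:
    map_partition: Partition
    map_log_posterior: float
    trace: pd.DataFrame
    chains: int


def cluster_mcmc(
    X: pd.DataFrame,
    n_iter: int = 50_000,
    beta: float = 1.0,
    seed: int = 0,
    n_chains: int = 2,
    init: str = "singletons",
    trace_every: int = 200,
) -> MCMCResult:
    """MCMC over partitions of the chunk-count matrix's row individuals.

    Runs ``n_chains`` independent Metropolis–Hastings chains (moves:
    single-individual reassignment, merge, random binary split) and returns
    the best MAP state visited.  Non-convergence is diagnosed from the
    returned trace, never raised.  Deterministic in ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    individuals = list(X.index)
    n = len(individuals)
    Xv = np.rint(X.to_numpy(dtype=float))
    if (Xv < 0).any():
        raise ValueError("chunk counts must be nonnegative")
    log_s2 = _log_stirling2_table(n)
    best_labels, best_post = None, -np.inf
    traces = []
    for chain in range(n_chains):
        rng = np.random.default_rng((seed, chain))
        if init == "singletons":
            labels = np.arange(n)
        else:
            labels = np.zeros(n, dtype=int)
        labels, post, trace = _run_chain(
            Xv, labels, beta, log_s2, n_iter, rng, trace_every
        )
        traces.append(pd.DataFrame({"chain": chain, **trace}))
        if post > best_post:
            best_post, best_labels = post, labels
    map_part = Partition(individuals, best_labels, beta=beta)
    map_part.log_marginal_likelihood = partition_log_marginal(
        X, map_part, beta
    )
    return MCMCResult(
        map_partition=map_part,
        map_log_posterior=float(best_post),
        trace=pd.concat(traces, ignore_index=True),
        chains=n_chains,
    )


def incremental_log_likelihood_delta(
    X: np.ndarray, labels: np.ndarray, prop: np.ndarray, beta: float
) -> float:
    """Likelihood change of a move, rescoring only the affected clusters.

    Both label arrays must be dense.  Exposed so the incremental update can
    be cross-checked against a from-scratch recomputation.
    """
    mask = labels != prop
    # closure: a cluster is affected if it shares any member with the
    # affected region on either side (a cluster can gain members without
    # any of its own being relabelled)
    while True:
        a_old = np.unique(labels[mask])
        a_new = np.unique(prop[mask])
        grown = np.isin(labels, a_old) | np.isin(prop, a_new)
        if grown.sum() == mask.sum():
            break
        mask = grown
    delta = 0.0
    for k in a_old:
        delta -= cluster_log_marginal(X[labels == k].sum(axis=0), beta)
    for k in a_new:
        delta += cluster_log_marginal(X[prop == k].sum(axis=0), beta)
    return float(delta)


def _run_chain(X, labels, beta, log_s2, n_iter, rng, trace_every):
    n = X.shape[0]
    labels = _densify(labels)

    def full_score(lab):
        return _score_partition_arrays(X, lab, beta, log_s2, n)

    cur_post = full_score(labels)
    best_labels, best_post = labels.copy(), cur_post
    trace_it, trace_post, trace_k = [], [], []
    for it in range(n_iter):
        u = rng.uniform()
        if u < 0.6:
            prop, log_q_ratio = _propose_reassign(labels, rng)
        elif u < 0.8:
            prop, log_q_ratio = _propose_merge(labels, rng)
        else:
            prop, log_q_ratio = _propose_split(labels, rng)
        if prop is not None:
            prop = _densify(prop)
            dlik = incremental_log_likelihood_delta(X, labels, prop, beta)
            dprior = log_s2[int(labels.max()) + 1] - log_s2[int(prop.max()) + 1]
            if np.log(rng.uniform()) < dlik + dprior + log_q_ratio:
                labels = prop
                cur_post = cur_post + dlik + dprior
                if cur_post > best_post:
                    best_labels, best_post = labels.copy(), cur_post
        if it % trace_every == 0:
            trace_it.append(it)
            trace_post.append(cur_post)
            trace_k.append(int(labels.max()) + 1)
    # guard against float drift in the accumulated posterior
    best_post = full_score(best_labels)
    return best_labels, best_post, {
        "iteration": trace_it, "log_posterior": trace_post, "K": trace_k
    }


def _reassign_options(labels: np.ndarray, i: int) -> int:
    """Number of targets individual i can move to (other clusters + a new
    singleton unless i already is one)."""
    K = int(labels.max()) + 1
    own = labels[i]
    own_size = int((labels == own).sum())
    return (K - 1) + (0 if own_size == 1 else 1)


def _propose_reassign(labels, rng):
    n = len(labels)
    i = int(rng.integers(n))
    K = int(labels.max()) + 1
    own = labels[i]
    own_size = int((labels == own).sum())
    options = [k for k in range(K) if k != own]
    if own_size > 1:
        options.append(K)  # open a new singleton cluster
    if not options:
        return None, 0.0
    target = options[int(rng.integers(len(options)))]
    prop = labels.copy()
    prop[i] = target
    q_fwd = 1.0 / len(options)
    q_rev = 1.0 / _reassign_options(_densify(prop), i)
    return prop, float(np.log(q_rev) - np.log(q_fwd))


def _log_n_binary_splits(size: int) -> float:
    # unordered nonempty bipartitions of a set of `size`: 2^(size-1) - 1
    if size > 50:
        return float((size - 1) * np.log(2.0))
    return float(np.log(2.0 ** (size - 1) - 1.0))


def _propose_merge(labels, rng):
    K = int(labels.max()) + 1
    if K < 2:
        return None, 0.0
    a, b = rng.choice(K, size=2, replace=False)
    prop = labels.copy()
    prop[prop == b] = a
    merged_size = int((prop == a).sum())
    prop_d = _densify(prop)
    # reverse move: a split must pick the merged cluster and this bipartition
    splittable = int(np.sum(np.bincount(prop_d) >= 2))
    log_q_rev = -np.log(splittable) - _log_n_binary_splits(merged_size)
    log_q_fwd = -np.log(K * (K - 1) / 2)
    return prop_d, float(log_q_rev - log_q_fwd)


def _propose_split(labels, rng):
    K = int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=K)
    splittable = np.flatnonzero(sizes >= 2)
    if len(splittable) == 0:
        return None, 0.0
    c = int(splittable[int(rng.integers(len(splittable)))])
    members = np.flatnonzero(labels == c)
    while True:
        side = rng.integers(2, size=len(members))
        if 0 < side.sum() < len(members):
            break
    prop = labels.copy()
    prop[members[side == 1]] = K
    K_new = K + 1
    log_q_fwd = -np.log(len(splittable)) - _log_n_binary_splits(len(members))
    log_q_rev = -np.log(K_new * (K_new - 1) / 2)
    return prop, float(log_q_rev - log_q_fwd)


def enumerate_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    def rec(prefix, kmax):
        i = len(prefix)
        if i == n:
            yield np.array(prefix, dtype=int)
            return
        for k in range(kmax + 1):
            yield from rec(prefix + [k], max(kmax, k + 1))
    yield from rec([0], 1) if n else iter(())


def exhaustive_map(X: pd.DataFrame, beta: float = 1.0) -> Partition:
    """MAP partition by exhaustive enumeration (small n only)."""
    individuals = list(X.index)
    n = len(individuals)
    Xv = np.rint(X.to_numpy(dtype=float))
    log_s2 = _log_stirling2_table(n)
    best, best_score = None, -np.inf
    for labels in enumerate_partitions(n):
        s = _score_partition_arrays(Xv, labels, beta, log_s2, n)
        if s > best_score:
            best, best_score = labels, s
    part = Partition(individuals, best, beta=beta)
    part.log_marginal_likelihood = partition_log_marginal(X, part, beta)
    return part


def cluster_tree(X: pd.DataFrame, partition: Partition, beta: float = 1.0) -> SupportedTree:
    """Greedy agglomeration of the MAP clusters into a binary tree.

    Repeatedly merges the pair of clusters whose merge least decreases the
    summed Dirichlet-multinomial log marginal; merge heights are the
    cumulative (nonnegative) score decreases.
    """
    clusters = partition.clusters()
    names = sorted(clusters, key=lambda c: min(clusters[c]))
    Xv = X.loc[partition.individuals].to_numpy(dtype=float)
    lab = partition.labels
    sums = {
        c: Xv[lab == (c - 1)].sum(axis=0) for c in names
    }
    nodes = {c: TreeNode(name=f"cluster{c}", height=0.0) for c in names}
    scores = {c: cluster_log_marginal(sums[c], beta) for c in names}
    height = 0.0
    active = list(names)
    while len(active) > 1:
        best_pair, best_delta = None, -np.inf
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                merged = cluster_log_marginal(sums[a] + sums[b], beta)
                delta = merged - scores[a] - scores[b]
                if delta > best_delta:
                    best_delta, best_pair = delta, (a, b)
        a, b = best_pair
        height += max(0.0, -best_delta) + 1e-9
        new = TreeNode(children=[nodes[a], nodes[b]], height=height)
        key = a
        nodes[key] = new
        sums[key] = sums[a] + sums[b]
        scores[key] = cluster_log_marginal(sums[key], beta)
        active.remove(b)
    return SupportedTree(root=nodes[active[0]])


def drop_singletons(partition: Partition) -> tuple[Partition, list[str]]:
    """Remove clusters of one individual; their members leave the donor set."""
    sizes = partition.cluster_sizes()
    keep = sizes[partition.labels] > 1
    removed = [s for s, k in zip(partition.individuals, keep) if not k]
    if not removed:
        return partition, []
    if not keep.any():
        raise ValueError("no donors remain: every cluster is a singleton")
    kept_inds = [s for s, k in zip(partition.individuals, keep) if k]
    return Partition(kept_inds, partition.labels[keep], beta=partition.beta), removed


# ---------------------------------------------------------------------------
# Model-style facade
# ---------------------------------------------------------------------------

@dataclass
class DonorClusterResults:
    partition: Partition
    mcmc: MCMCResult
    X: pd.DataFrame = field(repr=False)
    beta: float = 1.0

    def tree(self) -> SupportedTree:
        return cluster_tree(self.X, self.partition, self.beta)

    def summary(self) -> str:
        lines = [
            "Donor clustering (Dirichlet-multinomial partition MCMC)",
            f"individuals: {len(self.partition.individuals)}   "
            f"clusters (MAP): {self.partition.K}   beta: {self.beta}",
            f"MAP log posterior: {self.mcmc.map_log_posterior:.3f}",
            "",
        ]
        for cid, members in sorted(self.partition.clusters().items()):
            lines.append(f"  cluster{cid}: {', '.join(members)}")
        return "\n".join(lines)


class DonorClusterModel:
    """Partition model over a chunk-count matrix (statsmodels-style)."""

    def __init__(self, X: pd.DataFrame, beta: float = 1.0):
        self.X = X
        self.beta = beta

    def fit(self, n_iter: int = 50_000, seed: int = 0, n_chains: int = 2
            ) -> DonorClusterResults:
        res = cluster_mcmc(self.X, n_iter=n_iter, beta=self.beta, seed=seed,
                           n_chains=n_chains)
        return DonorClusterResults(res.map_partition, res, self.X, self.beta)
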