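"""Continental summaries of mixture solutions and bootstrap consensus trees.

Donor clusters are grouped into regions and continents; mixture proportions
aggregate to continent totals, and the within-continent ("relative")
composition — e.g. which European sources contributed, ignoring how much of
the genome is European at all — is obtained by renormalizing the continent's
source proportions to 1.  Populations whose continent total falls below a
floor are excluded from the relative analysis (their renormalized
composition would be noise).

The similarity structure of relative compositions is summarized by Ward
hierarchical clustering on Euclidean distances, and its robustness by a
bootstrap that resamples painted chromosomes: each pseudo-individual of a
replicate population reassembles 22 painted chromosomes drawn with
replacement from the population's members, upstream of the mixture fit, so
every replicate re-runs fit → aggregate → renormalize → tree.  Branches
kept in the consensus are those recurring in strictly more than the support
threshold of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .mixture import DonorBasis, mask_and_refit, _population_vector
from .painting import PaintingResult
from .trees import SupportedTree, consensus_tree, tree_from_linkage

__all__ = [
    "ContinentMap", "RelativeAncestry", "continental_aggregate",
    "relative_composition", "ward_tree", "bootstrap_populations",
    "bootstrap_consensus", "consensus_tree",
]


@dataclass
class ContinentMap:
    """Donor cluster → region → continent lookup.

    ``cluster_region`` maps each donor cluster to a region label and
    ``region_continent`` each region to a continent (e.g. Africa, Europe,
    Asia/America).  Regions partition the clusters.
    """

    cluster_region: dict
    region_continent: dict

    def __post_init__(self) -> None:
        bad = set(self.cluster_region.values()) - set(self.region_continent)
        if bad:
            raise ValueError(f"regions without a continent: {sorted(map(str, bad))}")

    def continent_of(self, cluster) -> str:
        try:
            return self.region_continent[self.cluster_region[cluster]]
        except KeyError:
            raise KeyError(f"cluster {cluster!r} has no continent mapping") from None

    @classmethod
    def direct(cls, cluster_continent: dict) -> "ContinentMap":
        """Map clusters straight to continents (one region per cluster)."""
        return cls(
            cluster_region={c: c for c in cluster_continent},
            region_continent=dict(cluster_continent),
        )


def continental_aggregate(
    solutions: pd.DataFrame, cmap: ContinentMap
) -> pd.DataFrame:
    """Sum mixture proportions by continent (rows: populations, sum to 1)."""
    continents: dict[str, list] = {}
    for cl in solutions.columns:
        try:
            cont = cmap.continent_of(cl)
        except KeyError:
            if (solutions[cl] > 0).any():
                raise
            continue  # zero-weight clusters may be unmapped
        continents.setdefault(cont, []).append(cl)
    return pd.DataFrame(
        {cont: solutions[cols].sum(axis=1) for cont, cols in continents.items()}
    )


@dataclass
class RelativeAncestry:
    """Within-continent source proportions, renormalized to 1 per population."""

    continent: str
    proportions: pd.DataFrame = field(repr=False)
    excluded: dict = field(default_factory=dict)


def relative_composition(
    solutions: pd.DataFrame,
    cmap: ContinentMap,
    continent: str,
    min_total: float = 0.01,
) -> RelativeAncestry:
    """Restrict mixture proportions to one continent's sources and
    renormalize; exclude populations whose continent total is below
    ``min_total`` (default 1%), recording why."""
    if not (0.0 <= min_total < 1.0):
        raise ValueError("min_total must lie in [0, 1)")
    cols = [c for c in solutions.columns if cmap.continent_of(c) == continent]
    if not cols:
        raise ValueError(f"no donor clusters map to continent {continent!r}")
    sub = solutions[cols]
    totals = sub.sum(axis=1)
    excluded = {
        str(p): f"{continent} ancestry {totals[p]:.4f} < {min_total}"
        for p in solutions.index
        if totals[p] < min_total
    }
    keep = [p for p in solutions.index if str(p) not in excluded]
    if not keep:
        raise ValueError("every population falls below min_total")
    rel = sub.loc[keep].div(totals.loc[keep], axis=0)
    return RelativeAncestry(continent=continent, proportions=rel, excluded=excluded)


def ward_tree(rel: RelativeAncestry | pd.DataFrame) -> SupportedTree:
    """Ward hierarchical clustering of populations (Euclidean distances).

    Uses the squared-Euclidean Ward update (the "ward.D2" convention, as in
    SciPy).  Populations are sorted lexicographically first so ties in the
    merge criterion break deterministically by name.
    """
    mat = rel.proportions if isinstance(rel, RelativeAncestry) else rel
    if len(mat) < 2:
        raise ValueError("need at least 2 populations to build a tree")
    mat = mat.sort_index()
    Z = linkage(mat.to_numpy(dtype=float), method="ward")
    return tree_from_linkage(Z, [str(i) for i in mat.index])


def bootstrap_populations(
    paintings: PaintingResult,
    n_reps: int,
    seed: int = 0,
    weight: str = "sites",
    hap_level: bool = False,
) -> list[pd.DataFrame]:
    """Replicate population copying vectors by resampling painted chromosomes.

    Each replicate rebuilds every population of size n as n
    pseudo-individuals; a pseudo-individual takes, for every chromosome,
    the painted chromosome (both haplotypes of one member together, or each
    haplotype independently when ``hap_level``) of a member drawn uniformly
    with replacement.  Member vectors are normalized and averaged into the
    replicate population vector.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    w = paintings._weights(weight)  # (2*n_targets, n_chroms, n_groups)
    n_chroms = len(paintings.chroms)
    pops = list(pd.unique(pd.Series(paintings.target_populations)))
    member_idx = {
        p: np.flatnonzero(np.asarray(paintings.target_populations) == p)
        for p in pops
    }
    reps: list[pd.DataFrame] = []
    for _ in range(n_reps):
        rows = {}
        for p in pops:
            idx = member_idx[p]
            nm = len(idx)
            ch = np.arange(n_chroms)[None, :]
            if hap_level:
                draw0 = idx[rng.integers(nm, size=(nm, n_chroms))]
                draw1 = idx[rng.integers(nm, size=(nm, n_chroms))]
                per_chrom = w[2 * draw0, ch, :] + w[2 * draw1 + 1, ch, :]
                ind_tot = per_chrom.sum(axis=1)
            else:
                draw = idx[rng.integers(nm, size=(nm, n_chroms))]
                per_chrom = w[2 * draw, ch, :] + w[2 * draw + 1, ch, :]
                ind_tot = per_chrom.sum(axis=1)
            ind_vec = ind_tot / ind_tot.sum(axis=1, keepdims=True)
            v = ind_vec.mean(axis=0)
            rows[p] = v / v.sum()
        reps.append(pd.DataFrame(rows, index=paintings.groups).T)
    return reps


def bootstrap_consensus(
    paintings: PaintingResult,
    basis: DonorBasis,
    cmap: ContinentMap,
    continent: str,
    n_reps: int = 1000,
    seed: int = 0,
    threshold: float = 0.8,
    masked=(),
    min_total: float = 0.01,
    weight: str = "sites",
) -> tuple[SupportedTree, list[SupportedTree]]:
    """Bootstrap consensus tree of within-continent relative compositions.

    Per replicate: resample painted chromosomes into pseudo-populations,
    refit the mixture for each, aggregate to continents, renormalize within
    ``continent``, and build the Ward tree; then keep branches recurring in
    strictly more than ``threshold`` of the replicate trees.
    """
    reps = bootstrap_populations(paintings, n_reps, seed=seed, weight=weight)
    trees: list[SupportedTree] = []
    for rep in reps:
        sols = {}
        for pop, vec in rep.iterrows():
            sols[pop] = mask_and_refit(vec, basis, masked).proportions
        sols_df = pd.DataFrame(sols).T
        rel = relative_composition(sols_df, cmap, continent, min_total=min_total)
        trees.append(ward_tree(rel))
    return consensus_tree(trees, threshold=threshold), trees


def observed_relative_composition(
    paintings: PaintingResult,
    basis: DonorBasis,
    cmap: ContinentMap,
    continent: str,
    masked=(),
    min_total: float = 0.01,
    weight: str = "sites",
) -> RelativeAncestry:
    """Relative composition of the observed (non-resampled) populations."""
    pops = list(pd.unique(pd.Series(paintings.target_populations)))
    sols = {}
    for p in pops:
        members = [s for s, q in zip(paintings.targets,
                                     paintings.target_populations) if q == p]
        vec = _population_vector(paintings.subset_targets(members), weight)
        sols[p] = mask_and_refit(vec, basis, masked).proportions
    sols_df = pd.DataFrame(sols).T
    return relative_composition(sols_df, cmap, continent, min_total=min_total)
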