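"""Chromosome painting under the Li–Stephens haplotype copying model.

A target haplotype is modelled as an imperfect mosaic of a set of donor
haplotypes.  The hidden state at each SNP is the donor haplotype currently
being copied; across an inter-site genetic distance ``g`` (Morgans) the
chain stays on its donor with probability ``exp(-Ne*g)`` and otherwise
switches to a donor drawn from the prior (switching back to the same donor
is allowed and is not a chunk boundary).  Emissions match the copied allele
with probability ``1 - theta`` and mismatch with probability ``theta``; a
missing target allele is uninformative.

``Ne`` is the recombination scaling constant (switch rate per Morgan) and
``theta`` the per-site mutation (miscopy) rate.  The shipped defaults,
Ne = 267 and theta = 0.00043, suit dense genome-wide SNP panels; both can
be re-estimated from data by expectation–maximization
(:func:`estimate_params_em`), which is the recommended practice whenever
the marker density differs from that regime.

Forward–backward recursions run in linear space with per-site scaling; the
scaling factors give the log-likelihood.  The painting of a target yields,
per donor group: the expected number of copied sites, the expected genetic
length copied (Morgans), and the expected number of contiguous copied
segments ("chunks"), all computed from site posteriors and pairwise
transition posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq


@dataclass
class CopyingModelParams:
    """Parameters of the copying HMM.

    ne : recombination scaling constant (> 0); multiplies Morgans.
    theta : per-site miscopy probability, in (0, 0.5).
    donor_prior : optional per-donor-haplotype prior weights (sum to 1);
        uniform when omitted.
    """

    ne: float = 267.0
    theta: float = 0.00043
    donor_prior: np.ndarray | None = None

    def validate(self, n_donors: int | None = None) -> None:
        if not (self.ne > 0):
            raise ValueError("ne must be > 0")
        if not (0.0 < self.theta < 0.5):
            raise ValueError("theta must lie in (0, 0.5)")
        if self.donor_prior is not None:
            w = np.asarray(self.donor_prior, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("donor_prior must be nonnegative and sum to 1")
            if n_donors is not None and len(w) != n_donors:
                raise ValueError("donor_prior length must equal donor count")

    def prior(self, k: int) -> np.ndarray:
        if self.donor_prior is None:
            return np.full(k, 1.0 / k)
        return np.asarray(self.donor_prior, dtype=float)


def _emissions(target: np.ndarray, donors: np.ndarray, theta: float) -> np.ndarray:
    """(L, k) emission matrix; missing target or donor alleles emit 1."""
    t = target[:, None]
    match = donors.T == t
    e = np.where(match, 1.0 - theta, theta)
    e[(t < 0).repeat(donors.shape[0], axis=1)] = 1.0
    e[donors.T < 0] = 1.0
    return e


def _forward_backward(e: np.ndarray, g: np.ndarray, ne: float, prior: np.ndarray):
    """Scaled forward–backward for the structured copying transition.

    Parameters: ``e`` (L, k) emissions, ``g`` (L-1,) inter-site Morgans.
    Returns (gamma, alpha, bhat, scales, r) where ``gamma`` are site
    posteriors, ``alpha`` the scaled forward variables, ``bhat`` the scaled
    backward variables, ``scales`` the per-site normalizers and ``r`` the
    per-interval stay probabilities.
    """
    L, k = e.shape
    r = np.exp(-ne * g)
    alpha = np.empty((L, k))
    scales = np.empty(L)
    a = prior * e[0]
    scales[0] = a.sum()
    alpha[0] = a / scales[0]
    for l in range(1, L):
        a = e[l] * (r[l - 1] * alpha[l - 1] + (1.0 - r[l - 1]) * prior)
        scales[l] = a.sum()
        alpha[l] = a / scales[l]
    bhat = np.empty((L, k))
    bhat[-1] = 1.0
    for l in range(L - 2, -1, -1):
        w = e[l + 1] * bhat[l + 1]
        bhat[l] = (r[l] * w + (1.0 - r[l]) * (prior @ w)) / scales[l + 1]
    gamma = alpha * bhat
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, alpha, bhat, scales, r


@dataclass
class HaplotypePainting:
    """Painting of one target haplotype on one chromosome."""

    donor_groups: list
    expected_copied_sites: pd.Series
    expected_chunk_count: pd.Series
    expected_copied_morgans: pd.Series
    log_likelihood: float
    posteriors: np.ndarray | None = None  # (L, k) per-site donor posteriors
    viterbi_path: np.ndarray | None = None  # site -> donor index

    def copying_vector(self, weight: str = "sites") -> pd.Series:
        w = (
            self.expected_copied_sites
            if weight == "sites"
            else self.expected_copied_morgans
        )
        return w / w.sum()


def paint_haplotype(
    target: np.ndarray,
    donors: np.ndarray,
    donor_groups,
    gpos: np.ndarray,
    params: CopyingModelParams | None = None,
    return_posteriors: bool = False,
    return_viterbi: bool = False,
) -> HaplotypePainting:
    """Paint one target haplotype against a donor haplotype set.

    ``donors`` is a (k, L) matrix, ``donor_groups`` a length-k sequence of
    group labels, ``gpos`` the per-site genetic position (Morgans, one
    chromosome, strictly increasing).
    """
    params = params or CopyingModelParams()
    donors = np.asarray(donors)
    target = np.asarray(target)
    k = donors.shape[0]
    if k == 0:
        raise ValueError("donor set is empty")
    if donors.shape[1] != target.shape[0] or len(gpos) != target.shape[0]:
        raise ValueError("target, donors and gpos must share the site axis")
    g = np.diff(np.asarray(gpos, dtype=float))
    if not np.all(np.isfinite(g)) or (g <= 0).any():
        raise ValueError("genetic positions must be finite and strictly increasing")
    params.validate(k)
    prior = params.prior(k)
    e = _emissions(target, donors, params.theta)
    gamma, alpha, bhat, scales, r = _forward_backward(e, g, params.ne, prior)
    stats = _group_statistics(
        gamma, alpha, bhat, scales, r, e, prior, gpos, donor_groups
    )
    vit = _viterbi(e, g, params.ne, prior) if return_viterbi else None
    return HaplotypePainting(
        donor_groups=stats["groups"],
        expected_copied_sites=stats["sites"],
        expected_chunk_count=stats["chunks"],
        expected_copied_morgans=stats["morgans"],
        log_likelihood=float(np.log(scales).sum()),
        posteriors=gamma if return_posteriors else None,
        viterbi_path=vit,
    )


def _group_statistics(gamma, alpha, bhat, scales, r, e, prior, gpos, donor_groups):
    L, k = gamma.shape
    # expected switch-in events per donor (transitions where donor identity
    # changes); switches back to the same donor do not open a new chunk
    switch_in = np.zeros(k)
    for l in range(L - 1):
        inflow = (1.0 - r[l]) * prior * e[l + 1] * bhat[l + 1] / scales[l + 1]
        switch_in += inflow * (1.0 - alpha[l])
    chunk_by_donor = gamma[0] + switch_in
    g = np.diff(np.asarray(gpos, dtype=float))
    w = np.zeros(L)
    if L > 1:
        w[:-1] += g / 2.0
        w[1:] += g / 2.0
    groups = list(pd.unique(pd.Series(donor_groups)))
    gidx = pd.Series(donor_groups)
    sites_tot = gamma.sum(axis=0)
    morgans_tot = (gamma * w[:, None]).sum(axis=0)
    agg = lambda v: pd.Series(
        {grp: v[np.flatnonzero((gidx == grp).to_numpy())].sum() for grp in groups}
    )
    return {
        "groups": groups,
        "sites": agg(sites_tot),
        "chunks": agg(chunk_by_donor),
        "morgans": agg(morgans_tot),
    }


def _viterbi(e, g, ne, prior) -> np.ndarray:
    L, k = e.shape
    r = np.exp(-ne * g)
    logp = np.log(prior)
    loge = np.log(np.maximum(e, 1e-300))
    V = logp + loge[0]
    ptr = np.empty((L, k), dtype=np.int64)
    ptr[0] = np.arange(k)
    for l in range(1, L):
        stay = np.log(r[l - 1] + (1 - r[l - 1]) * prior) + V
        jump_src = np.argmax(V)
        jump = np.log((1 - r[l - 1]) * prior) + V[jump_src]
        use_stay = stay >= jump
        V = np.where(use_stay, stay, jump) + loge[l]
        ptr[l] = np.where(use_stay, np.arange(k), jump_src)
    path = np.empty(L, dtype=np.int64)
    path[-1] = int(np.argmax(V))
    for l in range(L - 1, 0, -1):
        path[l - 1] = ptr[l, path[l]]
    return path


# ---------------------------------------------------------------------------
# Panel-level painting
# ---------------------------------------------------------------------------

@dataclass
class PaintingResult:
    """Per-chromosome painting expectations for a set of target samples.

    Arrays are indexed ``[target_haplotype, chromosome, donor_group]``; the
    two haplotypes of target sample ``i`` occupy rows ``2*i`` and ``2*i+1``.
    Per-chromosome results are kept separate so that leave-one-chromosome-out
    jackknifing and chromosome bootstrap resampling can operate on them.
    """

    targets: list[str]
    target_populations: list[str]
    groups: list
    chroms: list
    copied_sites: np.ndarray     # (2*n_targets, n_chroms, n_groups)
    chunk_counts: np.ndarray
    copied_morgans: np.ndarray
    log_likelihood: np.ndarray   # (2*n_targets, n_chroms)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def _weights(self, weight: str) -> np.ndarray:
        if weight == "sites":
            return self.copied_sites
        if weight == "morgans":
            return self.copied_morgans
        raise ValueError("weight must be 'sites' or 'morgans'")

    def individual_weights(
        self, weight: str = "sites", chrom_idx: np.ndarray | None = None
    ) -> pd.DataFrame:
        """Summed copying weights per individual (both haplotypes), over the
        selected chromosomes (all by default)."""
        w = self._weights(weight)
        if chrom_idx is not None:
            w = w[:, np.asarray(chrom_idx, dtype=int), :]
        per_hap = w.sum(axis=1)
        per_ind = per_hap.reshape(self.n_targets, 2, -1).sum(axis=1)
        return pd.DataFrame(per_ind, index=self.targets, columns=self.groups)

    def copying_vectors(
        self,
        level: str = "individual",
        weight: str = "sites",
        chrom_idx: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Normalized copying vectors (rows sum to 1).

        ``level="individual"`` normalizes each individual's summed weights;
        ``level="population"`` averages member individual vectors and
        renormalizes.
        """
        totals = self.individual_weights(weight, chrom_idx)
        sums = totals.sum(axis=1)
        if (sums <= 0).any():
            bad = list(totals.index[sums <= 0])
            raise ValueError(f"zero copying totals for {bad}")
        ind = totals.div(sums, axis=0)
        if level == "individual":
            return ind
        if level != "population":
            raise ValueError("level must be 'individual' or 'population'")
        ind = ind.copy()
        ind["__pop"] = self.target_populations
        pop = ind.groupby("__pop").mean()
        pop.index.name = None
        return pop.div(pop.sum(axis=1), axis=0)

    def chunk_count_matrix(self, level: str = "individual") -> pd.DataFrame:
        """Rounded integer expected chunk counts (clustering input)."""
        per_ind = self.chunk_counts.sum(axis=1).reshape(self.n_targets, 2, -1).sum(axis=1)
        df = pd.DataFrame(
            np.rint(per_ind).astype(np.int64), index=self.targets, columns=self.groups
        )
        if level == "individual":
            return df
        df["__pop"] = self.target_populations
        out = df.groupby("__pop").sum()
        out.index.name = None
        return out

    def subset_targets(self, sample_ids: list[str]) -> "PaintingResult":
        idx = [self.targets.index(s) for s in sample_ids]
        rows = np.array([r for i in idx for r in (2 * i, 2 * i + 1)], dtype=int)
        return PaintingResult(
            targets=[self.targets[i] for i in idx],
            target_populations=[self.target_populations[i] for i in idx],
            groups=self.groups,
            chroms=self.chroms,
            copied_sites=self.copied_sites[rows],
            chunk_counts=self.chunk_counts[rows],
            copied_morgans=self.copied_morgans[rows],
            log_likelihood=self.log_likelihood[rows],
        )


def paint_panel(
    panel,
    targets: list[str] | None = None,
    donor_grouping: dict | None = None,
    params: CopyingModelParams | None = None,
    leave_self_out: bool = False,
    exclude_own_group: bool = False,
) -> PaintingResult:
    """Paint the two haplotypes of each target sample against a donor set.

    ``donor_grouping`` maps donor sample id -> group label (default: every
    donor-role sample, grouped by its population label).  In recipient mode
    targets must be disjoint from donors; in donor-vs-donor mode pass
    ``leave_self_out=True`` so each target's own haplotypes (and with
    ``exclude_own_group`` its whole group) are excluded from its donor set.
    """
    params = params or CopyingModelParams()
    if donor_grouping is None:
        donor_grouping = {
            s: panel.population_of(s) for s in panel.samples_with_role("donor")
        }
    if targets is None:
        targets = panel.samples_with_role("recipient") or list(donor_grouping)
    overlap = set(targets) & set(donor_grouping)
    if overlap and not leave_self_out:
        raise ValueError(
            "targets overlap the donor set; use leave_self_out=True for "
            "donor-vs-donor painting"
        )
    donor_samples = list(donor_grouping)
    donor_rows = np.array(
        [r for s in donor_samples for r in panel.haplotype_rows(s)], dtype=int
    )
    donor_sample_of_row = np.repeat(np.array(donor_samples, dtype=object), 2)
    row_groups = np.repeat(
        np.array([donor_grouping[s] for s in donor_samples], dtype=object), 2
    )
    groups = list(pd.unique(row_groups))
    n_groups = len(groups)
    chroms = panel.chromosomes
    gpos = panel.gpos()
    if np.isnan(gpos).any():
        raise ValueError("panel has no genetic map attached")
    n_t = len(targets)
    shape = (2 * n_t, len(chroms), n_groups)
    copied_sites = np.zeros(shape)
    chunk_counts = np.zeros(shape)
    copied_morgans = np.zeros(shape)
    loglik = np.zeros((2 * n_t, len(chroms)))
    group_index = {g: i for i, g in enumerate(groups)}
    for ci, chrom in enumerate(chroms):
        sidx = panel.chromosome_sites(chrom)
        D_all = panel.alleles[donor_rows][:, sidx]
        g_chr = gpos[sidx]
        for ti, sample in enumerate(targets):
            h0, h1 = panel.haplotype_rows(sample)
            if exclude_own_group and sample in donor_grouping:
                mask = row_groups != donor_grouping[sample]
            elif sample in donor_grouping:
                mask = donor_sample_of_row != sample
            else:
                mask = np.ones(len(donor_rows), dtype=bool)
            if not mask.any():
                raise ValueError(f"empty donor set for target {sample!r}")
            D = D_all[mask]
            grp = row_groups[mask]
            for hj, hrow in enumerate((h0, h1)):
                res = paint_haplotype(
                    panel.alleles[hrow, sidx], D, grp, g_chr, params
                )
                r = 2 * ti + hj
                for grp_name, v in res.expected_copied_sites.items():
                    copied_sites[r, ci, group_index[grp_name]] = v
                for grp_name, v in res.expected_chunk_count.items():
                    chunk_counts[r, ci, group_index[grp_name]] = v
                for grp_name, v in res.expected_copied_morgans.items():
                    copied_morgans[r, ci, group_index[grp_name]] = v
                loglik[r, ci] = res.log_likelihood
    return PaintingResult(
        targets=list(targets),
        target_populations=[panel.population_of(s) for s in targets],
        groups=groups,
        chroms=chroms,
        copied_sites=copied_sites,
        chunk_counts=chunk_counts,
        copied_morgans=copied_morgans,
        log_likelihood=loglik,
    )


def copying_vectors(
    result: PaintingResult, level: str = "individual", weight: str = "sites"
) -> pd.DataFrame:
    """Copying vectors from a painting result (rows sum to 1)."""
    return result.copying_vectors(level=level, weight=weight)


# ---------------------------------------------------------------------------
# EM estimation of (Ne, theta)
# ---------------------------------------------------------------------------

def _em_expectations(target, donors, gpos, ne, theta, prior):
    """One E-step on one (target haplotype, chromosome).

    Returns (expected mismatches, observed emitting sites, expected
    recombination events, per-interval distances)."""
    e = _emissions(target, donors, theta)
    gamma, alpha, bhat, scales, r = _forward_backward(
        e, np.diff(gpos), ne, prior
    )
    obs = target >= 0
    mism = (donors.T != target[:, None]) & obs[:, None] & (donors.T >= 0)
    e_mismatch = float(gamma[mism].sum())
    n_obs = int(obs.sum())
    L = len(target)
    e_recomb = 0.0
    for l in range(L - 1):
        inflow = (1.0 - r[l]) * prior * e[l + 1] * bhat[l + 1] / scales[l + 1]
        e_recomb += float(inflow.sum())
    return e_mismatch, n_obs, e_recomb


def _solve_ne(intervals: np.ndarray, expected_switches: float) -> float:
    """Ne such that the expected number of switch intervals matches.

    Solves sum_l (1 - exp(-Ne * g_l)) = E over the pooled interval list.
    """
    total = len(intervals)
    if expected_switches <= 0:
        return 1e-6
    if expected_switches >= total:
        return 1e6
    f = lambda log_ne: np.sum(1.0 - np.exp(-np.exp(log_ne) * intervals)) - expected_switches
    return float(np.exp(brentq(f, np.log(1e-8), np.log(1e8), xtol=1e-10)))


def estimate_params_em(
    panel,
    populations: list[str] | None = None,
    chroms: list | None = None,
    n_iter: int = 10,
    init: CopyingModelParams | None = None,
    donor_grouping: dict | None = None,
) -> CopyingModelParams:
    """Estimate (Ne, theta) by expectation–maximization.

    EM runs independently for every selected (population, chromosome) pair:
    each donor individual of the population is painted leave-self-out
    against the full donor set on that chromosome; theta updates to the
    expected mismatch fraction and Ne to the value matching the expected
    switch count.  The returned parameters are the arithmetic mean of the
    per-pair estimates after ``n_iter`` iterations (default 10).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if donor_grouping is None:
        donor_grouping = {
            s: panel.population_of(s) for s in panel.samples_with_role("donor")
        }
    donor_samples = list(donor_grouping)
    if populations is None:
        populations = list(pd.unique([panel.population_of(s) for s in donor_samples]))
    if chroms is None:
        chroms = panel.chromosomes
    units = [
        (p, c)
        for p in populations
        for c in chroms
        if any(panel.population_of(s) == p for s in panel.sample_ids)
    ]
    if not units:
        raise ValueError("empty EM subset: no (population, chromosome) pairs")
    init = init or CopyingModelParams()
    gpos = panel.gpos()
    donor_rows_all = np.array(
        [r for s in donor_samples for r in panel.haplotype_rows(s)], dtype=int
    )
    donor_sample_of_row = np.repeat(np.array(donor_samples, dtype=object), 2)
    estimates = []
    for pop, chrom in units:
        sidx = panel.chromosome_sites(chrom)
        g_chr = gpos[sidx]
        intervals = np.diff(g_chr)
        # targets may be donors (painted leave-self-out) or any other
        # samples of the selected population painted against the donor set
        targets = [s for s in panel.sample_ids if panel.population_of(s) == pop]
        ne, theta = init.ne, init.theta
        for _ in range(n_iter):
            tot_mis = tot_obs = tot_rec = 0.0
            pooled_intervals = []
            for sample in targets:
                mask = donor_sample_of_row != sample
                D = panel.alleles[donor_rows_all[mask]][:, sidx]
                prior = np.full(D.shape[0], 1.0 / D.shape[0])
                for hrow in panel.haplotype_rows(sample):
                    m, n, rec = _em_expectations(
                        panel.alleles[hrow, sidx], D, g_chr, ne, theta, prior
                    )
                    tot_mis += m
                    tot_obs += n
                    tot_rec += rec
                    pooled_intervals.append(intervals)
            theta = min(max(tot_mis / max(tot_obs, 1.0), 1e-8), 0.499)
            ne = _solve_ne(np.concatenate(pooled_intervals), tot_rec)
        estimates.append((ne, theta))
    ne_mean = float(np.mean([e[0] for e in estimates]))
    theta_mean = float(np.mean([e[1] for e in estimates]))
    return CopyingModelParams(ne=ne_mean, theta=theta_mean)


# ---------------------------------------------------------------------------
# Model-style facade
# ---------------------------------------------------------------------------

class ChromosomePainter:
    """Copying-model over a haplotype panel.

    Thin model object bundling a panel with copying parameters; ``paint``
    runs the painting and ``fit_em`` re-estimates (Ne, theta).
    """

    def __init__(self, panel, params: CopyingModelParams | None = None):
        self.panel = panel
        self.params = params or CopyingModelParams()

    def fit_em(self, populations=None, chroms=None, n_iter: int = 10) -> CopyingModelParams:
        self.params = estimate_params_em(
            self.panel, populations=populations, chroms=chroms,
            n_iter=n_iter, init=self.params,
        )
        return self.params

    def paint(self, targets=None, donor_grouping=None, leave_self_out=False,
              exclude_own_group=False) -> PaintingResult:
        return paint_panel(
            self.panel, targets=targets, donor_grouping=donor_grouping,
            params=self.params, leave_self_out=leave_self_out,
            exclude_own_group=exclude_own_group,
        )
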