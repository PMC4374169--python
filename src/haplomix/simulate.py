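"""Synthetic phased panels: structured donor pools and admixed recipients.

The generator provides ground truth for every downstream stage without any
external genotype data.  Donor populations are differentiated by a
Balding–Nichols beta perturbation of shared ancestral allele frequencies,
controlled by a single ``divergence`` scalar (0 = identical frequencies).
Admixed recipients are built by walking the genetic map and copying tracts
from donor haplotypes, with ancestry switch points laid down as a Poisson
process whose rate per Morgan equals the number of generations since
admixture — the standard exponential-tract model of recent admixture.

Haplotypes can optionally carry background linkage disequilibrium: after a
few independently drawn founders, each additional haplotype of a population
is a mosaic copy of the previously generated ones.  Without this, sites are
independent given the population frequencies and a copying HMM has no
haplotype structure to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, merge_panels


def _pop_names(n: int) -> list[str]:
    if n <= 26:
        return [chr(ord("A") + i) for i in range(n)]
    return [f"P{i}" for i in range(n)]


@dataclass
class DonorPoolSpec:
    """Specification of a structured donor haplotype pool.

    ``divergence`` is the Balding–Nichols F: per-population allele
    frequencies are beta-distributed around a shared ancestral frequency
    with variance F·p(1−p).  ``chrom_lengths_morgans`` gives the genetic
    length of each chromosome; sites are spread over chromosomes in
    proportion to length.  ``bg_copy_rate`` (switch points per Morgan), if
    set, turns on the within-population copying process that induces
    background linkage; ``n_founders`` haplotypes per population are drawn
    site-wise first and the rest copy mosaics of earlier haplotypes with
    per-site miscopy probability ``bg_miscopy``.
    """

    n_pops: int
    haps_per_pop: int
    n_sites: int
    chrom_lengths_morgans: list = field(default_factory=lambda: [1.0])
    divergence: float = 0.1
    seed: int = 0
    bg_copy_rate: float | None = None
    bg_miscopy: float = 0.02
    n_founders: int = 4

    def validate(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if self.haps_per_pop < 2:
            raise ValueError("haps_per_pop must be >= 2")
        if self.haps_per_pop % 2:
            raise ValueError("haps_per_pop must be even (2 per diploid sample)")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must lie in [0, 1]")
        if not self.chrom_lengths_morgans or any(
            l <= 0 for l in self.chrom_lengths_morgans
        ):
            raise ValueError("chrom_lengths_morgans must be positive lengths")


@dataclass
class AdmixtureSpec:
    """Mixing proportions and time depth of the simulated admixture event."""

    proportions: dict
    generations_since_admixture: float
    n_recipients: int
    seed: int = 0
    theta_sim: float = 0.0  # per-site miscopy while copying a donor tract
    population: str = "ADMIXED"

    def validate(self) -> None:
        vals = np.array(list(self.proportions.values()), dtype=float)
        if len(vals) == 0 or (vals < 0).any():
            raise ValueError("proportions must be nonnegative and nonempty")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1 (got {vals.sum()!r})")
        if self.generations_since_admixture <= 0:
            raise ValueError("generations_since_admixture must be > 0")
        if self.n_recipients < 1:
            raise ValueError("n_recipients must be >= 1")
        if not (0.0 <= self.theta_sim < 0.5):
            raise ValueError("theta_sim must lie in [0, 0.5)")


@dataclass(frozen=True)
class TractRecord:
    """Ground-truth ancestry tract in 0-based half-open site coordinates."""

    recipient_hap_id: str
    chrom: object
    start_site: int  # chromosome-local site index
    end_site: int
    source_pop: str


def _site_table(spec: DonorPoolSpec, rng: np.random.Generator) -> pd.DataFrame:
    lengths = np.asarray(spec.chrom_lengths_morgans, dtype=float)
    counts = np.maximum(1, np.round(spec.n_sites * lengths / lengths.sum())).astype(int)
    # adjust rounding drift onto the longest chromosome
    counts[np.argmax(lengths)] += spec.n_sites - counts.sum()
    rows = []
    for c, (length, cnt) in enumerate(zip(lengths, counts), start=1):
        g = np.sort(rng.uniform(0.0, length, size=cnt))
        g = np.maximum.accumulate(g + np.arange(cnt) * 1e-12)
        bp = (g * 1e8).astype(np.int64) + 1  # 1 cM ~ 1 Mb
        bp = np.maximum.accumulate(bp + np.arange(cnt))  # strictly increasing
        rows.append(pd.DataFrame({"chrom": c, "pos": bp, "gpos": g}))
    return pd.concat(rows, ignore_index=True)


def simulate_donor_pool(spec: DonorPoolSpec) -> HaplotypePanel:
    """Generate a phased donor panel with population structure.

    Returns a panel of ``n_pops * haps_per_pop`` haplotypes whose genetic
    map positions increase strictly along each chromosome.  Deterministic
    in ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sites = _site_table(spec, rng)
    L = len(sites)
    p_anc = rng.uniform(0.05, 0.95, size=L)
    F = spec.divergence
    freqs = np.empty((spec.n_pops, L))
    for k in range(spec.n_pops):
        if F == 0.0:
            freqs[k] = p_anc
        elif F == 1.0:
            freqs[k] = (rng.uniform(size=L) < p_anc).astype(float)
        else:
            lam = (1.0 - F) / F
            freqs[k] = rng.beta(p_anc * lam, (1.0 - p_anc) * lam)
    pops = _pop_names(spec.n_pops)
    haps = np.empty((spec.n_pops * spec.haps_per_pop, L), dtype=np.int8)
    chrom_idx = [np.flatnonzero(sites["chrom"].to_numpy() == c) for c in
                 pd.unique(sites["chrom"])]
    gpos = sites["gpos"].to_numpy()
    for k in range(spec.n_pops):
        block = slice(k * spec.haps_per_pop, (k + 1) * spec.haps_per_pop)
        pool = np.empty((spec.haps_per_pop, L), dtype=np.int8)
        n_iid = (
            spec.haps_per_pop
            if spec.bg_copy_rate is None
            else min(max(2, spec.n_founders), spec.haps_per_pop)
        )
        pool[:n_iid] = (rng.uniform(size=(n_iid, L)) < freqs[k]).astype(np.int8)
        for h in range(n_iid, spec.haps_per_pop):
            for idx in chrom_idx:
                pool[h, idx] = _mosaic_copy(
                    pool[:h][:, idx], gpos[idx], spec.bg_copy_rate,
                    spec.bg_miscopy, rng,
                )
        haps[block] = pool
    sample_ids = [
        f"{p}{i}" for p in pops for i in range(spec.haps_per_pop // 2)
    ]
    populations = [p for p in pops for _ in range(spec.haps_per_pop // 2)]
    return HaplotypePanel(
        alleles=haps,
        sample_ids=sample_ids,
        populations=populations,
        roles=["donor"] * len(sample_ids),
        sites=sites,
    )


def _mosaic_copy(templates, gpos, rate, miscopy, rng) -> np.ndarray:
    """Copy one chromosome as a mosaic of template haplotypes."""
    L = len(gpos)
    out = np.empty(L, dtype=np.int8)
    cur = rng.integers(templates.shape[0])
    start = 0
    g0, g1 = gpos[0], gpos[-1]
    breaks = np.sort(rng.uniform(g0, g1, size=rng.poisson(rate * (g1 - g0))))
    cut_sites = np.searchsorted(gpos, breaks, side="left")
    for cut in list(cut_sites) + [L]:
        if cut > start:
            out[start:cut] = templates[cur, start:cut]
        start = cut
        cur = rng.integers(templates.shape[0])
    flip = rng.uniform(size=L) < miscopy
    out[flip] = 1 - out[flip]
    return out


def simulate_admixed(
    panel: HaplotypePanel, spec: AdmixtureSpec
) -> tuple[HaplotypePanel, list[TractRecord]]:
    """Build admixed recipients by copying tracts from donor haplotypes.

    Each recipient haplotype walks the genetic map laying down ancestry
    switch points as a Poisson process of rate ``generations_since_admixture``
    per Morgan; each tract draws its source population from
    ``spec.proportions`` and copies a uniformly chosen donor haplotype of
    that population (with per-site miscopy ``theta_sim``).  Returns the
    recipient panel (on the donor panel's site set) and the ground-truth
    tract records, which tile each chromosome exactly.
    """
    spec.validate()
    unknown = set(spec.proportions) - set(panel.populations)
    if unknown:
        raise ValueError(f"unknown source population(s): {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    pops = list(spec.proportions.keys())
    probs = np.array([spec.proportions[p] for p in pops], dtype=float)
    pop_arr = np.asarray(panel.populations)
    pop_hap_rows = {
        p: np.flatnonzero(np.repeat(pop_arr == p, 2)) for p in pops
    }
    chrom_ids = panel.chromosomes
    chrom_idx = {c: panel.chromosome_sites(c) for c in chrom_ids}
    gpos = panel.gpos()
    n_haps = 2 * spec.n_recipients
    out = np.empty((n_haps, panel.n_sites), dtype=np.int8)
    tracts: list[TractRecord] = []
    sample_ids = [f"{spec.population}{i}" for i in range(spec.n_recipients)]
    for h in range(n_haps):
        hap_id = f"{sample_ids[h // 2]}_{h % 2}"
        for c in chrom_ids:
            idx = chrom_idx[c]
            g = gpos[idx]
            g0, g1 = g[0], g[-1]
            n_break = rng.poisson(spec.generations_since_admixture * (g1 - g0))
            breaks = np.sort(rng.uniform(g0, g1, size=n_break))
            cuts = np.searchsorted(g, breaks, side="left")
            bounds = np.concatenate([[0], cuts, [len(idx)]])
            sources = rng.choice(len(pops), size=len(bounds) - 1, p=probs)
            prev_end = 0
            for s, a, b in zip(sources, bounds[:-1], bounds[1:]):
                if b <= a:
                    continue  # empty tract between adjacent sites
                src = pops[s]
                donor_row = rng.choice(pop_hap_rows[src])
                seg = panel.alleles[donor_row, idx[a]:idx[a] + (b - a)]
                out[h, idx[a]:idx[a] + (b - a)] = seg
                tracts.append(TractRecord(hap_id, c, int(a), int(b), src))
                prev_end = b
            assert prev_end == len(idx)
        if spec.theta_sim > 0:
            flip = rng.uniform(size=panel.n_sites) < spec.theta_sim
            row = out[h]
            obs = row >= 0
            row[flip & obs] = 1 - row[flip & obs]
    recipients = HaplotypePanel(
        alleles=out,
        sample_ids=sample_ids,
        populations=[spec.population] * spec.n_recipients,
        roles=["recipient"] * spec.n_recipients,
        sites=panel.sites.copy(),
    )
    return recipients, tracts


def write_truth_table(tracts: list[TractRecord], path) -> None:
    """Write ground-truth tracts as a TSV (0-based half-open site indices)."""
    df = pd.DataFrame(
        [
            (t.recipient_hap_id, t.chrom, t.start_site, t.end_site, t.source_pop)
            for t in tracts
        ],
        columns=["recipient_hap_id", "chrom", "start_site", "end_site", "source_pop"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> list[TractRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TractRecord(r.recipient_hap_id, r.chrom, int(r.start_site),
                    int(r.end_site), r.source_pop)
        for r in df.itertuples(index=False)
    ]


def simulate_copying_targets(
    panel: HaplotypePanel,
    n_targets: int,
    ne: float,
    theta: float,
    seed: int = 0,
    population: str = "TGT",
) -> HaplotypePanel:
    """Generate target haplotypes directly from the copying model.

    Each target haplotype is a mosaic of the panel's haplotypes: the copied
    template switches (uniformly, possibly to itself) at Poisson rate ``ne``
    per Morgan and each copied allele is flipped with probability ``theta``.
    Useful for parameter-recovery checks of the painting EM.  ``n_targets``
    counts haplotypes and must be even (two per diploid sample).
    """
    if n_targets < 2 or n_targets % 2:
        raise ValueError("n_targets must be an even count >= 2")
    rng = np.random.default_rng(seed)
    gpos = panel.gpos()
    chrom_idx = [panel.chromosome_sites(c) for c in panel.chromosomes]
    out = np.empty((n_targets, panel.n_sites), dtype=np.int8)
    for h in range(n_targets):
        for idx in chrom_idx:
            out[h, idx] = _mosaic_copy(
                panel.alleles[:, idx], gpos[idx], ne, theta, rng
            )
    ids = [f"{population}{i}" for i in range(n_targets // 2)]
    return HaplotypePanel(
        alleles=out,
        sample_ids=ids,
        populations=[population] * len(ids),
        roles=["recipient"] * len(ids),
        sites=panel.sites.copy(),
    )


def true_ancestry_fractions(
    tracts: list[TractRecord], panel: HaplotypePanel, weight: str = "morgans"
) -> pd.Series:
    """Genome-wide true ancestry fractions pooled over all tract records.

    ``weight="morgans"`` weights each tract by its genetic length (half-open
    span between its first site and the site after its last); ``"sites"``
    weights by site count.
    """
    gpos = panel.gpos()
    chrom_idx = {c: panel.chromosome_sites(c) for c in panel.chromosomes}
    totals: dict[str, float] = {}
    for t in tracts:
        idx = chrom_idx[t.chrom]
        if weight == "sites":
            w = t.end_site - t.start_site
        else:
            hi = gpos[idx[t.end_site - 1]]
            lo = gpos[idx[t.start_site]]
            w = hi - lo + 1e-12
        totals[t.source_pop] = totals.get(t.source_pop, 0.0) + w
    s = pd.Series(totals, dtype=float)
    return s / s.sum()


def simulate_admixed_panel(
    donor_spec: DonorPoolSpec, admix_spec: AdmixtureSpec
) -> tuple[HaplotypePanel, list[TractRecord]]:
    """Convenience: donor pool + recipients merged into one panel."""
    donors = simulate_donor_pool(donor_spec)
    recip, tracts = simulate_admixed(donors, admix_spec)
    return merge_panels(donors, recip), tracts


def write_genetic_map_for_panel(panel: HaplotypePanel, path) -> None:
    """Emit a HapMap-format map (chrom, position, rate cM/Mb, cM) matching
    the panel's site genetic positions exactly."""
    rows = []
    for c in panel.chromosomes:
        idx = panel.chromosome_sites(c)
        pos = panel.sites["pos"].to_numpy()[idx]
        cm = panel.gpos()[idx] * 100.0
        rate = np.zeros_like(cm)
        if len(cm) > 1:
            rate[:-1] = np.diff(cm) / (np.diff(pos) / 1e6)
        rows.append(pd.DataFrame(
            {"chrom": c, "position": pos, "rate_cM_Mb": rate, "cM": cm}
        ))
    pd.concat(rows, ignore_index=True).to_csv(path, sep=" ", index=False)
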