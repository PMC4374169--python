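"""Reference synthetic scenarios exercising the whole pipeline.

These bundle the generator settings used throughout the test suite and the
reproduction script, so every stage runs against the same study conditions.

The *standard admixture scenario*: three donor populations (Balding–Nichols
divergence 0.15, 20 haplotypes each, with background linkage from a
within-population copying process) on 22 chromosomes of 0.1 Morgan each
carrying 1,000 SNPs in total; 20 admixed recipients draw ancestry
(0.2, 0.3, 0.5) from the three populations 20 generations before sampling.
The 0.1-Morgan chromosomes put roughly 20 SNPs on an average ancestry
tract, matching the segment granularity of dense genome-wide panels at
desk scale.  A variant adds a fourth, unadmixed population that acts as a
masked surrogate donor.

The *two-bloc scenario*: recipients in two blocs whose European ancestry
comes from disjoint European donor-population pairs, used to test that
bootstrap consensus trees of relative European composition separate the
blocs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import (AncestryMixtureModel, DonorBasis, build_donor_basis)
from .painting import ChromosomePainter, CopyingModelParams, PaintingResult
from .panel import HaplotypePanel, merge_panels
from .simulate import (AdmixtureSpec, DonorPoolSpec, TractRecord,
                       simulate_admixed, simulate_donor_pool,
                       true_ancestry_fractions)
from .summaries import ContinentMap

N_CHROMS = 22
CHROM_LENGTH_M = 0.1
STANDARD_ALPHA = {"A": 0.2, "B": 0.3, "C": 0.5}


@dataclass
class Scenario:
    panel: HaplotypePanel            # donors + recipients, shared site set
    donors: HaplotypePanel
    recipients: HaplotypePanel
    tracts: list[TractRecord]
    true_alpha: pd.Series
    donor_pops: list[str]
    recipient_pops: list[str] = field(default_factory=list)
    masked: list[str] = field(default_factory=list)


def _donor_spec(n_pops: int, seed: int, n_sites: int = 1000,
                haps_per_pop: int = 20, divergence: float = 0.15) -> DonorPoolSpec:
    return DonorPoolSpec(
        n_pops=n_pops,
        haps_per_pop=haps_per_pop,
        n_sites=n_sites,
        chrom_lengths_morgans=[CHROM_LENGTH_M] * N_CHROMS,
        divergence=divergence,
        seed=seed,
        bg_copy_rate=30.0,   # within-pop mosaic copying: background LD
        bg_miscopy=0.02,
        n_founders=4,
    )


def standard_scenario(
    seed: int = 0,
    n_recipients: int = 20,
    with_surrogate: bool = False,
    generations: float = 20.0,
) -> Scenario:
    """The standard three-population admixture recovery scenario."""
    n_pops = 4 if with_surrogate else 3
    donors = simulate_donor_pool(_donor_spec(n_pops, seed))
    aspec = AdmixtureSpec(
        proportions=dict(STANDARD_ALPHA),
        generations_since_admixture=generations,
        n_recipients=n_recipients,
        seed=seed + 1,
    )
    recipients, tracts = simulate_admixed(donors, aspec)
    return Scenario(
        panel=merge_panels(donors, recipients),
        donors=donors,
        recipients=recipients,
        tracts=tracts,
        true_alpha=pd.Series(STANDARD_ALPHA),
        donor_pops=list(dict.fromkeys(donors.populations)),
        recipient_pops=["ADMIXED"],
        masked=(["D"] if with_surrogate else []),
    )


@dataclass
class RecoveryRun:
    params: CopyingModelParams
    donor_paintings: PaintingResult
    recipient_paintings: PaintingResult
    basis: DonorBasis
    results: object  # AncestryMixtureResults

    @property
    def alpha_hat(self) -> pd.Series:
        return self.results.proportions.iloc[0]


def run_recovery(
    scenario: Scenario,
    em: bool = True,
    em_populations: list[str] | None = None,
    em_chroms: list | None = None,
    jackknife: bool = False,
    individual_level: bool = False,
    self_copy: str = "keep",
) -> RecoveryRun:
    """Paint the scenario and decompose recipient ancestry.

    Follows the full analysis path: (Ne, theta) by EM on a subset (one
    donor population, three chromosomes, 10 iterations by default), donors
    painted leave-self-out against each other to build the donor-cluster
    basis (clusters = true populations here), recipients painted against
    all donors, mixture fitted with optional surrogate masking.
    """
    painter = ChromosomePainter(scenario.panel)
    if em:
        painter.fit_em(
            populations=em_populations or scenario.donor_pops[:1],
            chroms=em_chroms or scenario.panel.chromosomes[:3],
            n_iter=10,
        )
    donor_grouping = {
        s: scenario.panel.population_of(s)
        for s in scenario.panel.samples_with_role("donor")
    }
    donor_paintings = painter.paint(
        targets=list(donor_grouping), donor_grouping=donor_grouping,
        leave_self_out=True,
    )
    recipient_paintings = painter.paint(
        targets=scenario.panel.samples_with_role("recipient"),
        donor_grouping=donor_grouping,
    )
    donor_vectors = donor_paintings.copying_vectors(level="individual")
    basis = build_donor_basis(
        donor_vectors, donor_grouping, self_copy=self_copy
    )
    model = AncestryMixtureModel(
        recipient_paintings, basis, mask=scenario.masked
    )
    results = model.fit(jackknife=jackknife, individual_level=individual_level)
    return RecoveryRun(
        params=painter.params,
        donor_paintings=donor_paintings,
        recipient_paintings=recipient_paintings,
        basis=basis,
        results=results,
    )


# ---------------------------------------------------------------------------
# Two-bloc colonial scenario
# ---------------------------------------------------------------------------

BLOC_DONOR_POPS = ["AF1", "AF2", "EU1", "EU2", "EU3", "EU4", "AS1"]
BLOC_RECIPIENTS = {
    # bloc one: European ancestry from EU1/EU2
    "R1": {"AF1": 0.20, "AF2": 0.10, "EU1": 0.45, "EU2": 0.25},
    "R2": {"AF1": 0.15, "AF2": 0.15, "EU1": 0.30, "EU2": 0.40},
    # bloc two: European ancestry from EU3/EU4
    "R3": {"AF1": 0.20, "AF2": 0.10, "EU3": 0.45, "EU4": 0.25},
    "R4": {"AF1": 0.15, "AF2": 0.15, "EU3": 0.30, "EU4": 0.40},
}
BLOC_CONTINENTS = ContinentMap.direct(
    {"AF1": "Africa", "AF2": "Africa",
     "EU1": "Europe", "EU2": "Europe", "EU3": "Europe", "EU4": "Europe",
     "AS1": "Asia/America"}
)
BLOC_SPLIT = ({"R1", "R2"}, {"R3", "R4"})


def bloc_scenario(seed: int = 0, n_per_pop: int = 8,
                  generations: float = 20.0) -> Scenario:
    """Two recipient blocs with disjoint European donor usage."""
    donors = simulate_donor_pool(_donor_spec(len(BLOC_DONOR_POPS), seed))
    # rename the generator's A..G populations to the scenario's labels
    rename = dict(zip(sorted(set(donors.populations)), BLOC_DONOR_POPS))
    donors.populations = [rename[p] for p in donors.populations]
    panel = donors
    recip_panels = []
    tracts: list[TractRecord] = []
    for i, (pop, props) in enumerate(BLOC_RECIPIENTS.items()):
        aspec = AdmixtureSpec(
            proportions=props,
            generations_since_admixture=generations,
            n_recipients=n_per_pop,
            seed=seed + 100 + i,
            population=pop,
        )
        rp, tr = simulate_admixed(donors, aspec)
        recip_panels.append(rp)
        tracts.extend(tr)
    recipients = recip_panels[0]
    for rp in recip_panels[1:]:
        recipients = merge_panels(recipients, rp)
    return Scenario(
        panel=merge_panels(donors, recipients),
        donors=donors,
        recipients=recipients,
        tracts=tracts,
        true_alpha=pd.DataFrame(BLOC_RECIPIENTS).fillna(0.0).T.stack(),
        donor_pops=BLOC_DONOR_POPS,
        recipient_pops=list(BLOC_RECIPIENTS),
    )
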