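"""Ancestry decomposition of copying vectors by non-negative least squares.

A recipient's copying vector c (proportions of genome copied from each
donor group, summing to 1) is decomposed as a mixture of donor-cluster
copying vectors: minimise ||c - C a||_2 subject to a >= 0, where the
columns of C are the clusters' own copying vectors inferred the same way.
The active-set NNLS solution is renormalized to sum to 1 (the support is
unchanged by this), giving mixture proportions over potential donor
clusters.

Surrogate masking deals with donor groups that stand in for strongly
drifted unsampled sources: the masked coordinates are deleted from the
target and from every basis column (all renormalized) before fitting, so
direct copying from the surrogate no longer drives the fit while the
surrogate's column remains available as a mixture component.

Uncertainty comes from a leave-one-chromosome-out jackknife over the
per-chromosome paintings (22 replicates for a human autosomal panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .painting import PaintingResult

_DUST = 1e-12


@dataclass
class DonorBasis:
    """Donor-cluster copying vectors as the columns of a mixture basis.

    ``matrix`` is (n_coordinates, n_clusters) with rows indexed by donor
    group coordinate and columns by cluster; every column sums to 1.
    """

    matrix: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        col_sums = self.matrix.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-8):
            raise ValueError("basis columns must each sum to 1")
        if self.matrix.shape[1] < 2:
            raise ValueError("basis needs at least 2 donor-cluster columns")

    @property
    def clusters(self) -> list:
        return list(self.matrix.columns)

    @property
    def coordinates(self) -> list:
        return list(self.matrix.index)

    def masked(self, masked_groups) -> "DonorBasis | pd.DataFrame":
        """Basis with the masked coordinates deleted and columns renormalized
        (all-zero columns are left at zero)."""
        m = self.matrix.drop(index=list(masked_groups))
        sums = m.sum(axis=0)
        out = m.copy()
        nz = sums > 0
        out.loc[:, nz] = m.loc[:, nz].div(sums[nz], axis=1)
        b = object.__new__(DonorBasis)
        b.matrix = out
        return b


def build_donor_basis(
    donor_vectors: pd.DataFrame,
    cluster_assignment: dict,
    self_copy: str = "keep",
) -> DonorBasis:
    """Mean member copying vector per non-singleton cluster.

    ``donor_vectors``: individuals × donor-group coordinates (rows sum
    to 1).  ``cluster_assignment`` maps individual -> cluster label; when
    the coordinates coincide with the cluster labels,
    ``self_copy="zero-and-renormalize"`` zeroes each column's own-cluster
    entry and renormalizes.  Singleton clusters are excluded.
    """
    if self_copy not in ("keep", "zero-and-renormalize"):
        raise ValueError("self_copy must be 'keep' or 'zero-and-renormalize'")
    members: dict = {}
    for ind, cl in cluster_assignment.items():
        members.setdefault(cl, []).append(ind)
    cols = {}
    for cl, inds in members.items():
        if len(inds) < 2:
            continue  # singleton clusters do not form basis columns
        v = donor_vectors.loc[inds].mean(axis=0)
        if self_copy == "zero-and-renormalize" and cl in v.index:
            v = v.copy()
            v.loc[cl] = 0.0
        v = v / v.sum()
        cols[cl] = v
    if len(cols) < 2:
        raise ValueError("fewer than 2 non-singleton clusters; cannot build basis")
    return DonorBasis(matrix=pd.DataFrame(cols))


@dataclass
class MixtureSolution:
    """Nonnegative mixture proportions over donor clusters (sum to 1)."""

    proportions: pd.Series
    residual_norm: float
    masked_groups: list = field(default_factory=list)
    jackknife_se: pd.Series | None = None

    def __post_init__(self) -> None:
        a = self.proportions
        if (a < -1e-12).any() or abs(a.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must be nonnegative and sum to 1")


#: Weight of the sum-to-one row appended to the NNLS system.  Large enough
#: that the solution is effectively the simplex-constrained least squares
#: optimum; the residual deviation from 1 is removed by renormalization.
_SUM_WEIGHT = 100.0


def fit_mixture(target: pd.Series, basis: DonorBasis,
                sum_weight: float = _SUM_WEIGHT) -> MixtureSolution:
    """Solve min ||c - C a||_2, a >= 0, with a pushed onto the simplex.

    The sum-to-one condition enters as a heavily weighted extra equation
    (the usual augmented-NNLS device for mixture proportions); the
    active-set solution is then renormalized exactly to sum 1.
    """
    C = basis.matrix
    c = target.reindex(C.index)
    if c.isna().any():
        missing = list(c.index[c.isna()])
        raise ValueError(f"target lacks donor-group coordinates {missing[:5]}")
    A = np.vstack([C.to_numpy(dtype=float),
                   np.full(C.shape[1], sum_weight)])
    b = np.append(c.to_numpy(dtype=float), sum_weight)
    a, _ = nnls(A, b)
    a[np.abs(a) < _DUST] = 0.0
    total = a.sum()
    if total <= 0:
        raise ValueError(
            "NNLS returned the zero solution; the target is orthogonal to "
            "the donor basis — inspect the basis columns"
        )
    a = a / total
    fitted = C.to_numpy(dtype=float) @ a
    resid = float(np.linalg.norm(c.to_numpy(dtype=float) - fitted))
    return MixtureSolution(
        proportions=pd.Series(a, index=C.columns), residual_norm=resid
    )


def mask_and_refit(
    target: pd.Series, basis: DonorBasis, masked
) -> MixtureSolution:
    """Delete masked donor-group coordinates, renormalize, refit.

    The masked clusters' own columns stay in the basis, so they may still
    receive mixture weight; only their direct copying signal is removed.
    """
    masked = list(masked)
    if not masked:
        return fit_mixture(target, basis)
    unknown = set(masked) - set(basis.coordinates)
    if unknown:
        raise ValueError(f"masked groups not among coordinates: {sorted(unknown)}")
    t = target.drop(index=masked)
    if t.sum() <= 0:
        raise ValueError("masking removes all of the target's copying mass")
    t = t / t.sum()
    sol = fit_mixture(t, basis.masked(masked))
    sol.masked_groups = masked
    return sol


def jackknife_se(
    paintings: PaintingResult,
    members: list[str],
    basis: DonorBasis,
    masked=(),
    weight: str = "sites",
) -> tuple[pd.Series, pd.DataFrame]:
    """Leave-one-chromosome-out jackknife SEs of the mixture proportions.

    For each chromosome j the population copying vector is recomputed from
    the remaining chromosomes and the mixture refitted; the SE per cluster
    is sqrt((n-1)/n * sum_j (a_j - abar)^2) with n the chromosome count.
    Returns (SE series, leave-one-out estimates as a chrom × cluster frame).
    """
    n = len(paintings.chroms)
    if n < 2:
        raise ValueError("jackknife needs at least 2 chromosomes")
    sub = paintings.subset_targets(members)
    loo = {}
    for j, chrom in enumerate(paintings.chroms):
        keep = np.array([k for k in range(n) if k != j], dtype=int)
        vec = _population_vector(sub, weight, keep)
        sol = mask_and_refit(vec, basis, masked)
        loo[chrom] = sol.proportions
    loo_df = pd.DataFrame(loo).T
    mean = loo_df.mean(axis=0)
    se = np.sqrt((n - 1) / n * ((loo_df - mean) ** 2).sum(axis=0))
    return se, loo_df


def _population_vector(
    sub: PaintingResult, weight: str, chrom_idx=None
) -> pd.Series:
    ind = sub.copying_vectors(level="individual", weight=weight,
                              chrom_idx=chrom_idx)
    v = ind.mean(axis=0)
    return v / v.sum()


def individual_ancestry(
    individual_vectors: pd.DataFrame, basis: DonorBasis, masked=()
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-individual mixture fits plus their mean.

    ``individual_vectors``: individuals × donor-group coordinates.  Returns
    (per-individual proportions frame, mean of the individual solutions).
    """
    if len(individual_vectors) == 0:
        raise ValueError("no individuals given")
    rows = {}
    for ind, vec in individual_vectors.iterrows():
        rows[ind] = mask_and_refit(vec, basis, masked).proportions
    per_ind = pd.DataFrame(rows).T
    return per_ind, per_ind.mean(axis=0)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class AncestryMixtureModel:
    """Mixture decomposition of recipient paintings against a donor basis.

    Parameters
    ----------
    paintings
        :class:`~haplomix.painting.PaintingResult` for the recipient
        samples (per-chromosome expectations retained).
    basis
        Donor-cluster copying-vector basis.
    mask
        Donor-group coordinates whose direct copying is masked before
        fitting (surrogate-donor treatment).
    weight
        ``"sites"`` or ``"morgans"`` copying weights.
    """

    def __init__(
        self,
        paintings: PaintingResult,
        basis: DonorBasis,
        mask=(),
        weight: str = "sites",
    ):
        self.paintings = paintings
        self.basis = basis
        self.mask = list(mask)
        self.weight = weight
        pops = pd.unique(pd.Series(paintings.target_populations))
        self._members = {
            p: [s for s, q in zip(paintings.targets,
                                  paintings.target_populations) if q == p]
            for p in pops
        }

    def fit(self, jackknife: bool = True,
            individual_level: bool = True) -> "AncestryMixtureResults":
        pop_solutions: dict = {}
        ses: dict = {}
        ind_fits: dict = {}
        for pop, members in self._members.items():
            sub = self.paintings.subset_targets(members)
            vec = _population_vector(sub, self.weight)
            sol = mask_and_refit(vec, self.basis, self.mask)
            if jackknife and len(self.paintings.chroms) >= 2:
                se, _ = jackknife_se(
                    self.paintings, members, self.basis, self.mask, self.weight
                )
                sol.jackknife_se = se
                ses[pop] = se
            pop_solutions[pop] = sol
            if individual_level:
                iv = sub.copying_vectors(level="individual", weight=self.weight)
                per_ind, _ = individual_ancestry(iv, self.basis, self.mask)
                ind_fits[pop] = per_ind
        return AncestryMixtureResults(
            model=self,
            population_solutions=pop_solutions,
            jackknife_ses=ses,
            individual_proportions=ind_fits,
        )


@dataclass
class AncestryMixtureResults:
    """Fitted mixture proportions with jackknife uncertainties."""

    model: AncestryMixtureModel
    population_solutions: dict
    jackknife_ses: dict
    individual_proportions: dict

    @property
    def proportions(self) -> pd.DataFrame:
        """Population × donor-cluster mixture proportions."""
        return pd.DataFrame(
            {p: s.proportions for p, s in self.population_solutions.items()}
        ).T

    @property
    def bse(self) -> pd.DataFrame:
        """Jackknife standard errors aligned with :attr:`proportions`."""
        if not self.jackknife_ses:
            return pd.DataFrame(index=self.proportions.index,
                                columns=self.proportions.columns, dtype=float)
        return pd.DataFrame(self.jackknife_ses).T.reindex(
            self.proportions.index
        )

    def individual_means(self) -> pd.DataFrame:
        """Population means of the per-individual solutions."""
        return pd.DataFrame(
            {p: df.mean(axis=0) for p, df in self.individual_proportions.items()}
        ).T

    def summary(self) -> str:
        prop, se = self.proportions, self.bse
        lines = [
            "Ancestry mixture decomposition (NNLS, proportions sum to 1)",
            f"donor clusters: {len(prop.columns)}"
            + (f"   masked: {', '.join(map(str, self.model.mask))}"
               if self.model.mask else ""),
            f"chromosomes: {len(self.model.paintings.chroms)}   "
            f"weight: {self.model.weight}",
            "",
        ]
        header = f"{'population':<16}" + "".join(
            f"{str(c):>18}" for c in prop.columns
        )
        lines.append(header)
        for p in prop.index:
            cells = []
            for c in prop.columns:
                v = prop.loc[p, c]
                s = se.loc[p, c] if not se.empty else np.nan
                cells.append(
                    f"{v:.3f} ({s:.3f})" if np.isfinite(s) else f"{v:.3f}"
                )
            lines.append(f"{str(p):<16}" + "".join(f"{x:>18}" for x in cells))
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: population, cluster, proportion, se."""
        prop = self.proportions.stack()
        se = self.bse.stack() if not self.bse.empty else None
        out = prop.rename("proportion").reset_index()
        out.columns = ["population", "cluster", "proportion"]
        if se is not None and len(se):
            out["se"] = se.to_numpy()
        return out
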