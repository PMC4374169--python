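"""NNLS mixture decomposition, masking, jackknife, individual fits."""

import numpy as np
import pandas as pd
import pytest

from haplomix.mixture import (
    AncestryMixtureModel,
    DonorBasis,
    build_donor_basis,
    fit_mixture,
    individual_ancestry,
    jackknife_se,
    mask_and_refit,
)
from haplomix.painting import PaintingResult

from oracles import jackknife_se_closed_form, simplex_grid_best


def basis_from(cols: dict) -> DonorBasis:
    m = pd.DataFrame(cols, dtype=float)
    return DonorBasis(matrix=m.div(m.sum(axis=0), axis=1))


@pytest.fixture
def toy_basis():
    return basis_from({
        "A": {"A": 0.8, "B": 0.1, "C": 0.1},
        "B": {"A": 0.15, "B": 0.7, "C": 0.15},
        "C": {"A": 0.05, "B": 0.15, "C": 0.8},
    })


class TestBasis:
    def test_columns_sum_to_one(self, toy_basis):
        assert np.allclose(toy_basis.matrix.sum(axis=0), 1.0)

    def test_singleton_clusters_excluded(self):
        vecs = pd.DataFrame(
            {"A": [0.7, 0.6, 0.1, 0.2, 0.5],
             "B": [0.2, 0.3, 0.8, 0.7, 0.3],
             "C": [0.1, 0.1, 0.1, 0.1, 0.2]},
            index=["i1", "i2", "i3", "i4", "i5"],
        )
        assign = {"i1": "A", "i2": "A", "i3": "B", "i4": "B", "i5": "C"}
        basis = build_donor_basis(vecs, assign, self_copy="keep")
        assert set(basis.clusters) == {"A", "B"}  # singleton C excluded
        # with only one non-singleton cluster no basis can be built
        with pytest.raises(ValueError, match="non-singleton"):
            build_donor_basis(
                vecs, {"i1": "A", "i2": "A", "i3": "B", "i4": "C", "i5": "D"}
            )

    def test_self_copy_modes_differ_only_on_diagonal(self):
        vecs = pd.DataFrame(
            {"A": [0.8, 0.7, 0.2, 0.25], "B": [0.2, 0.3, 0.8, 0.75]},
            index=["i1", "i2", "i3", "i4"],
        )
        assign = {"i1": "A", "i2": "A", "i3": "B", "i4": "B"}
        keep = build_donor_basis(vecs, assign, self_copy="keep")
        zero = build_donor_basis(vecs, assign, self_copy="zero-and-renormalize")
        assert zero.matrix.loc["A", "A"] == 0.0
        assert zero.matrix.loc["B", "B"] == 0.0
        # off-diagonal entries just get renormalized, staying proportional
        assert zero.matrix.loc["B", "A"] == pytest.approx(1.0)
        assert keep.matrix.loc["A", "A"] > 0


class TestFit:
    def test_exact_basis_column_recovered(self, toy_basis):
        target = toy_basis.matrix["B"]
        sol = fit_mixture(target, toy_basis)
        assert sol.proportions["B"] == pytest.approx(1.0, abs=1e-8)
        assert sol.residual_norm == pytest.approx(0.0, abs=1e-8)

    def test_constructed_exact_mixture_recovered(self, toy_basis):
        target = 0.3 * toy_basis.matrix["A"] + 0.7 * toy_basis.matrix["B"]
        sol = fit_mixture(target, toy_basis)
        assert sol.proportions["A"] == pytest.approx(0.3, abs=1e-6)
        assert sol.proportions["B"] == pytest.approx(0.7, abs=1e-6)
        assert sol.proportions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_matches_simplex_grid_search(self):
        """Active-set NNLS ties the dense grid oracle in fitted-vector norm."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            C = rng.dirichlet(np.ones(4), size=3).T  # 4 coords x 3 cols
            c = rng.dirichlet(np.ones(4))
            basis = DonorBasis(matrix=pd.DataFrame(
                C, index=list("wxyz"), columns=list("abc")
            ))
            sol = fit_mixture(pd.Series(c, index=list("wxyz")), basis)
            fitted = C @ sol.proportions.to_numpy()
            ours = np.linalg.norm(c - fitted)
            grid = simplex_grid_best(C, c, step=0.001)
            assert ours <= grid + 1e-3

    def test_duplicated_column_leaves_fitted_vector_unchanged(self, toy_basis):
        target = 0.4 * toy_basis.matrix["A"] + 0.6 * toy_basis.matrix["C"]
        m2 = toy_basis.matrix.copy()
        m2["B2"] = m2["B"]
        dup = DonorBasis(matrix=m2)
        s1 = fit_mixture(target, toy_basis)
        s2 = fit_mixture(target, dup)
        f1 = toy_basis.matrix.to_numpy() @ s1.proportions.to_numpy()
        f2 = m2.to_numpy() @ s2.proportions.reindex(m2.columns).to_numpy()
        assert np.allclose(f1, f2, atol=1e-8)

    def test_nonnegativity_and_sum(self, toy_basis):
        rng = np.random.default_rng(2)
        for _ in range(25):
            target = pd.Series(rng.dirichlet(np.ones(3)),
                               index=toy_basis.coordinates)
            sol = fit_mixture(target, toy_basis)
            assert (sol.proportions >= 0).all()
            assert sol.proportions.sum() == pytest.approx(1.0, abs=1e-8)


class TestMasking:
    def test_empty_mask_is_identity(self, toy_basis):
        target = pd.Series([0.3, 0.4, 0.3], index=list("ABC"))
        a = fit_mixture(target, toy_basis)
        b = mask_and_refit(target, toy_basis, [])
        assert np.allclose(a.proportions, b.proportions)

    def test_vacuous_mask_changes_nothing(self):
        basis = basis_from({
            "A": {"A": 0.8, "B": 0.2, "Z": 0.0},
            "B": {"A": 0.25, "B": 0.75, "Z": 0.0},
        })
        target = pd.Series({"A": 0.5, "B": 0.5, "Z": 0.0})
        a = fit_mixture(target, basis)
        b = mask_and_refit(target, basis, ["Z"])
        assert np.allclose(
            a.proportions.to_numpy(), b.proportions.to_numpy(), atol=1e-8
        )

    def test_masking_heavy_coordinate_reduces_that_groups_weight(self):
        # group G copies overwhelmingly from coordinate G; the target also
        # has G mass, so unmasked fitting credits G heavily
        basis = basis_from({
            "G": {"G": 0.9, "H": 0.05, "I": 0.05},
            "H": {"G": 0.1, "H": 0.8, "I": 0.1},
            "I": {"G": 0.1, "H": 0.1, "I": 0.8},
        })
        target = pd.Series({"G": 0.5, "H": 0.3, "I": 0.2})
        full = fit_mixture(target, basis)
        masked = mask_and_refit(target, basis, ["G"])
        assert masked.proportions["G"] < full.proportions["G"]
        assert masked.masked_groups == ["G"]

    def test_masking_everything_rejected(self, toy_basis):
        target = pd.Series({"A": 1.0, "B": 0.0, "C": 0.0})
        with pytest.raises(ValueError, match="mass"):
            mask_and_refit(target, toy_basis, ["A"])


def painting_with_two_chroms(chrom_weights):
    """1 target sample, len(chrom_weights) chroms, 2 donor groups."""
    w = np.asarray(chrom_weights, dtype=float)  # (n_chroms, 2)
    n_chroms = w.shape[0]
    copied = np.zeros((2, n_chroms, 2))
    copied[0] = w / 2
    copied[1] = w / 2
    return PaintingResult(
        targets=["T0"], target_populations=["P"], groups=["A", "B"],
        chroms=list(range(1, n_chroms + 1)),
        copied_sites=copied, chunk_counts=np.ones_like(copied),
        copied_morgans=copied * 0.01,
        log_likelihood=np.zeros((2, n_chroms)),
    )


@pytest.fixture
def identity_basis():
    return DonorBasis(matrix=pd.DataFrame(
        np.eye(2), index=["A", "B"], columns=["A", "B"]
    ))


class TestJackknife:
    def test_closed_form_two_chromosomes(self, identity_basis):
        # leave-one-out vectors (0.4, 0.6) and (0.6, 0.4) -> SE = 0.1
        res = painting_with_two_chroms([[0.6, 0.4], [0.4, 0.6]])
        se, loo = jackknife_se(res, ["T0"], identity_basis)
        assert sorted(loo["A"].round(6)) == [0.4, 0.6]
        assert se["A"] == pytest.approx(0.1)
        assert se["B"] == pytest.approx(0.1)
        assert se["A"] == pytest.approx(
            jackknife_se_closed_form([0.4, 0.6])
        )

    def test_constant_replicates_zero_se(self, identity_basis):
        res = painting_with_two_chroms([[0.5, 0.5]] * 4)
        se, _ = jackknife_se(res, ["T0"], identity_basis)
        assert np.allclose(se, 0.0)

    def test_invariant_to_chromosome_order(self, identity_basis):
        weights = [[0.7, 0.3], [0.5, 0.5], [0.2, 0.8]]
        a, _ = jackknife_se(painting_with_two_chroms(weights), ["T0"],
                            identity_basis)
        b, _ = jackknife_se(painting_with_two_chroms(weights[::-1]), ["T0"],
                            identity_basis)
        assert np.allclose(a, b)

    def test_single_chromosome_rejected(self, identity_basis):
        res = painting_with_two_chroms([[0.5, 0.5]])
        with pytest.raises(ValueError, match="2 chromosomes"):
            jackknife_se(res, ["T0"], identity_basis)


class TestIndividualAncestry:
    def test_identical_individuals_match_population_fit(self, toy_basis):
        vec = pd.Series([0.4, 0.35, 0.25], index=list("ABC"))
        frame = pd.DataFrame([vec] * 3, index=["i1", "i2", "i3"])
        per_ind, mean = individual_ancestry(frame, toy_basis)
        pop = fit_mixture(vec, toy_basis)
        for i in per_ind.index:
            assert np.allclose(per_ind.loc[i], pop.proportions, atol=1e-10)
        assert np.allclose(mean, pop.proportions, atol=1e-10)

    def test_empty_individual_set_rejected(self, toy_basis):
        with pytest.raises(ValueError):
            individual_ancestry(pd.DataFrame(columns=list("ABC")), toy_basis)


class TestEndToEndRecovery:
    def test_population_alpha_within_tolerance(self, standard_run):
        """Painting + NNLS recovers the generating admixture proportions."""
        sc, run = standard_run
        alpha = run.alpha_hat
        for pop, a in sc.true_alpha.items():
            assert abs(alpha[pop] - a) <= 0.05

    def test_masked_surrogate_degrades_little(self, standard_run, surrogate_run):
        _, run3 = standard_run
        sc4, run4 = surrogate_run
        a3, a4 = run3.alpha_hat, run4.alpha_hat
        assert a4["D"] == pytest.approx(0.0, abs=1e-8)
        for pop in ("A", "B", "C"):
            assert abs(a4[pop] - a3[pop]) <= 0.02

    def test_individual_proportions_track_variation(self, standard_run):
        """Individuals vary around alpha; fits correlate with truth."""
        sc, run = standard_run
        from haplomix.simulate import true_ancestry_fractions

        per_hap = {}
        for t in sc.tracts:
            samp = t.recipient_hap_id.rsplit("_", 1)[0]
            per_hap.setdefault(samp, []).append(t)
        true_a = pd.Series({
            s: true_ancestry_fractions(ts, sc.panel).get("A", 0.0)
            for s, ts in per_hap.items()
        })
        fit_a = run.results.individual_proportions["ADMIXED"]["A"]
        joined = pd.concat([true_a, fit_a], axis=1, keys=["true", "fit"]).dropna()
        r = np.corrcoef(joined["true"], joined["fit"])[0, 1]
        assert r >= 0.8

    def test_jackknife_ses_are_small_positive(self, standard_run):
        _, run = standard_run
        se = run.results.bse
        assert (se.to_numpy() >= 0).all()
        assert se.to_numpy().max() < 0.1  # 22 chromosomes, stable fit

    def test_summary_mentions_masking_and_se(self, surrogate_run):
        _, run = surrogate_run
        # refit with jackknife for the summary path
        text = run.results.summary()
        assert "masked: D" in text
        assert "NNLS" in text
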