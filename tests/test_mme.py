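"""Mixed-model equations: assembly against hand oracles, PCG against dense
solves, GEBV evaluation, and the C22 prediction-error block."""

import numpy as np
import pandas as pd
import pytest

from ssrrm.basis import LegendreBasis
from ssrrm.data import CovarianceComponents, Pedigree, PhenotypeTable
from ssrrm.kinship import RelationshipSet
from ssrrm.mme import (
    ConvergenceError,
    assemble_mme,
    gebv_at_age,
    pev_block_c22,
    solve_pcg,
)


def _one_record_system():
    ped = Pedigree(pd.DataFrame([(1, 0, 0)], columns=["animal", "sire", "dam"]))
    phen = PhenotypeTable(
        pd.DataFrame(
            [(1, 25, 3.0, 0, 6)],
            columns=["animal", "age_months", "value", "herd_year", "birth_month"],
        )
    )
    comps = CovarianceComponents(
        V_g=np.diag([2.0, 1.0, 0.5]),
        V_p=np.diag([1.0, 0.5, 0.2]),
        sigma_e2=np.full(6, 4.0),
    )
    basis = LegendreBasis(order=4)
    return ped, phen, comps, basis


class TestAssembly:
    def test_single_record_additive_block_hand_oracle(self):
        """One founder, one record: the additive diagonal block must equal
        V_g^-1 + phi phi' / sigma_e2 (A^-1 = 1 for a founder)."""
        ped, phen, comps, basis = _one_record_system()
        system = assemble_mme(phen, ped, basis, comps)
        phi = basis.row(25, order=2)
        nf = system.n_fixed
        block = system.lhs.toarray()[nf : nf + 3, nf : nf + 3]
        expected = np.linalg.inv(comps.V_g) + np.outer(phi, phi) / 4.0
        np.testing.assert_allclose(block, expected, atol=1e-12)
        # and the pe block: V_p^-1 + phi phi' / sigma_e2
        pe_block = system.lhs.toarray()[nf + 3 :, nf + 3 :]
        np.testing.assert_allclose(
            pe_block, np.linalg.inv(comps.V_p) + np.outer(phi, phi) / 4.0, atol=1e-12
        )

    def test_record_order_invariance(self, small_dataset, small_filtered):
        panel, phen = small_filtered
        basis = LegendreBasis(order=4)
        comps = small_dataset.components
        s1 = assemble_mme(phen, small_dataset.pedigree, basis, comps)
        shuffled = PhenotypeTable(
            phen.frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        s2 = assemble_mme(shuffled, small_dataset.pedigree, basis, comps)
        assert abs(s1.lhs - s2.lhs).max() < 1e-9
        np.testing.assert_allclose(s1.rhs, s2.rhs, atol=1e-9)

    def test_lhs_symmetric_and_full_rank(self, small_model):
        lhs = small_model.system_.lhs
        assert abs(lhs - lhs.T).max() < 1e-10
        w = np.linalg.eigvalsh(lhs.toarray())
        assert w.min() > 0


class TestPCG:
    def test_matches_dense_solve(self, small_model):
        """Fully converged PCG agrees with a dense direct solve."""
        system = small_model.system_
        x_dense = np.linalg.solve(system.lhs.toarray(), system.rhs)
        sol = solve_pcg(system, tol=1e-26, max_iter=50_000)
        x_pcg = np.concatenate([sol.b_hat, sol.a_hat.ravel(), sol.pe_hat.ravel()])
        rel = np.linalg.norm(x_pcg - x_dense) / np.linalg.norm(x_dense)
        assert rel < 1e-6
        # the production stopping rule (1e-14 squared-ratio) is looser
        x_def = small_model.solution_
        x_d = np.concatenate([x_def.b_hat, x_def.a_hat.ravel(), x_def.pe_hat.ravel()])
        assert np.linalg.norm(x_d - x_dense) / np.linalg.norm(x_dense) < 1e-3

    def test_zero_rhs_gives_zero(self, small_model):
        import dataclasses

        system = dataclasses.replace(
            small_model.system_, rhs=np.zeros_like(small_model.system_.rhs)
        )
        sol = solve_pcg(system)
        assert np.all(sol.b_hat == 0) and np.all(sol.a_hat == 0)

    def test_preconditioner_reduces_iterations(self, small_model):
        system = small_model.system_
        with_p = solve_pcg(system, tol=1e-20, precondition=True)
        without = solve_pcg(system, tol=1e-20, precondition=False, max_iter=100_000)
        assert with_p.n_iter < without.n_iter
        np.testing.assert_allclose(with_p.a_hat, without.a_hat, atol=1e-5)

    def test_exit_criterion_honored(self, small_model):
        hist = small_model.solution_.convergence_history
        assert hist[-1] <= 1e-14
        assert all(c > 1e-14 for c in hist[:-1])

    def test_max_iter_exceeded_raises(self, small_model):
        with pytest.raises(ConvergenceError):
            solve_pcg(small_model.system_, tol=1e-30, max_iter=3)


class TestGEBV:
    def test_intercept_only_coefficients(self, small_model):
        sol = small_model.solution_
        import copy

        s = copy.deepcopy(sol)
        s.a_hat[:] = 0.0
        s.a_hat[:, 0] = 2.0
        basis = small_model.basis_
        for age in (0, 17, 60):
            g = gebv_at_age(s, basis, age)
            np.testing.assert_allclose(g, 2.0 * np.sqrt(0.5), atol=1e-12)

    def test_linear_term_vanishes_at_midpoint(self, small_model):
        import copy

        s = copy.deepcopy(small_model.solution_)
        s.a_hat[:] = 0.0
        s.a_hat[:, 1] = 1.0
        g = gebv_at_age(s, small_model.basis_, 30.0)  # x = 0
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_trajectory_matches_polynomial_evaluation(self, small_model):
        """GEBV over an age grid equals Phi @ a_hat by direct Legendre
        evaluation (independent of the basis class)."""
        from numpy.polynomial import legendre as npleg

        sol = small_model.solution_
        ages = np.arange(0, 61, 5, dtype=float)
        x = 2 * ages / 60 - 1
        phi = np.column_stack(
            [
                np.sqrt((2 * k + 1) / 2)
                * npleg.legval(x, np.eye(3)[k])
                for k in range(3)
            ]
        )
        expected = sol.a_hat @ phi.T
        got = np.column_stack(
            [gebv_at_age(sol, small_model.basis_, a) for a in ages]
        )
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_unknown_animal_raises(self, small_model):
        with pytest.raises(KeyError):
            gebv_at_age(small_model.solution_, small_model.basis_, 30, animals=[10**9])


class TestC22:
    def test_matches_dense_inverse_subset(self, small_model, small_filtered):
        panel, _ = small_filtered
        system = small_model.system_
        C22 = pev_block_c22(system, panel.animal_ids)
        full = np.linalg.inv(system.lhs.toarray())
        idx = system.pedigree.indices(panel.animal_ids)
        cols = (system.n_fixed + (idx[:, None] * 3 + np.arange(3))).ravel()
        np.testing.assert_allclose(C22, full[np.ix_(cols, cols)], atol=1e-8)

    def test_pev_bounded_by_prior_variance(self, small_model, small_filtered):
        """0 < phi' C22_ll phi <= sigma2_ut: prediction error cannot exceed
        the prior additive variance at any age."""
        panel, _ = small_filtered
        C22 = pev_block_c22(small_model.system_, panel.animal_ids)
        comps = small_model.components_
        basis = small_model.basis_
        n_g = panel.n_animals
        blocks = C22.reshape(n_g, 3, n_g, 3)
        for age in (10, 30, 50):
            phi = basis.row(age, order=2)
            s2 = phi @ comps.V_g @ phi
            pev = np.einsum("a,iaib,b->i", phi, blocks[:, :, :, :], phi)
            diag = np.array([phi @ blocks[i, :, i, :] @ phi for i in range(n_g)])
            assert np.all(diag > 0)
            assert np.all(diag <= s2 * (1 + 1e-8))

    def test_size_guard(self, small_model, small_filtered):
        panel, _ = small_filtered
        with pytest.raises(ValueError, match="guard"):
            pev_block_c22(small_model.system_, panel.animal_ids, max_dim=10)

    def test_extra_record_shrinks_pev(self, small_dataset, small_filtered):
        """Adding a near-noise-free record for one genotyped animal lowers its
        coefficient-level PEV diagonal."""
        panel, phen = small_filtered
        animal = int(panel.animal_ids[0])
        basis = LegendreBasis(order=4)
        comps = small_dataset.components
        base = assemble_mme(phen, small_dataset.pedigree, basis, comps)
        C0 = pev_block_c22(base, [animal])
        extra = pd.DataFrame(
            [(animal, 30, 100.0, phen.frame["herd_year"].iloc[0],
              phen.frame["birth_month"].iloc[0])],
            columns=["animal", "age_months", "value", "herd_year", "birth_month"],
        )
        phen2 = PhenotypeTable(pd.concat([phen.frame, extra], ignore_index=True))
        aug = assemble_mme(phen2, small_dataset.pedigree, basis, comps)
        C1 = pev_block_c22(aug, [animal])
        assert np.all(np.diag(C1) < np.diag(C0) + 1e-12)
        assert np.trace(C1) < np.trace(C0)


def test_pedigree_only_reduction_matches_dense_gls(small_dataset, small_filtered):
    """With no genomic information the solver reproduces a classical pedigree
    RRM solved by a dense oracle built independently (dense kron products)."""
    import scipy.sparse as sp

    from ssrrm.kinship import build_A_inverse
    from ssrrm.mme import build_design

    _, phen = small_filtered
    ped = small_dataset.pedigree
    basis = LegendreBasis(order=4)
    comps = small_dataset.components
    system = assemble_mme(phen, ped, basis, comps, relationships=None)
    sol = solve_pcg(system, tol=1e-26, max_iter=50_000)

    # dense oracle: explicit design matrices and kron priors
    d = build_design(phen, ped, basis, comps)
    n_ped, n_phen = len(ped), len(d.phen_ids)
    Z1 = np.zeros((len(d.y), 3 * n_ped))
    Z2 = np.zeros((len(d.y), 3 * n_phen))
    for r in range(len(d.y)):
        Z1[r, 3 * d.rec_animal[r] : 3 * d.rec_animal[r] + 3] = d.phi_rand[r]
        Z2[r, 3 * d.rec_pe[r] : 3 * d.rec_pe[r] + 3] = d.phi_rand[r]
    W = np.hstack([d.X.toarray(), Z1, Z2])
    R_inv = np.diag(d.rinv)
    A_inv = build_A_inverse(ped).toarray()
    prior = np.zeros((W.shape[1], W.shape[1]))
    nf = d.n_fixed
    prior[nf : nf + 3 * n_ped, nf : nf + 3 * n_ped] = np.kron(
        A_inv, np.linalg.inv(comps.V_g)
    )
    prior[nf + 3 * n_ped :, nf + 3 * n_ped :] = np.kron(
        np.eye(n_phen), np.linalg.inv(comps.V_p)
    )
    lhs = W.T @ R_inv @ W + prior
    x = np.linalg.solve(lhs, W.T @ R_inv @ d.y)
    got = np.concatenate([sol.b_hat, sol.a_hat.ravel(), sol.pe_hat.ravel()])
    assert np.linalg.norm(got - x) / np.linalg.norm(x) < 1e-6


def test_gebv_contrasts_invariant_to_constraint_choice(small_dataset, small_filtered):
    """Re-coding the herd-year baseline permutes X but leaves GEBV contrasts
    unchanged."""
    _, phen = small_filtered
    ped = small_dataset.pedigree
    basis = LegendreBasis(order=4)
    comps = small_dataset.components
    sol1 = solve_pcg(assemble_mme(phen, ped, basis, comps), tol=1e-26, max_iter=50_000)
    # relabel herd-years so a different level becomes the dropped baseline
    relabeled = phen.frame.copy()
    relabeled["herd_year"] = -relabeled["herd_year"]
    sol2 = solve_pcg(
        assemble_mme(PhenotypeTable(relabeled), ped, basis, comps),
        tol=1e-26,
        max_iter=50_000,
    )
    g1 = gebv_at_age(sol1, basis, 30)
    g2 = gebv_at_age(sol2, basis, 30)
    np.testing.assert_allclose(g1 - g1.mean(), g2 - g2.mean(), atol=1e-6)
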