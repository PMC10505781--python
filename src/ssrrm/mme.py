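"""Assembly and solution of the random-regression single-step MME.

The model for a record of animal ``l`` at age ``t`` is

    y = HY_i + M_j + sum_k phi_k(t) b_k + sum_k phi_k(t) u_lk
        + sum_k phi_k(t) pe_lk + e,

with heterogeneous residual variances by age class.  Stacking records,
``y = X b + Z1 a + Z2 p + e`` and Henderson's equations are

    [X'R-1X         X'R-1Z1                X'R-1Z2        ] [b]   [X'R-1y ]
    [Z1'R-1X  Z1'R-1Z1 + H-1 (x) Vg-1      Z1'R-1Z2       ] [a] = [Z1'R-1y]
    [Z2'R-1X        Z2'R-1Z1        Z2'R-1Z2 + I (x) Vp-1 ] [p]   [Z2'R-1y]

in animal-major coefficient ordering (the three regression coefficients of
animal 1, then animal 2, ...), so the Kronecker products are
``kron(H_inv, Vg_inv)`` and ``kron(I, Vp_inv)``.  Identifiability comes from
dropping the first herd-year and first birth-month level; the constant
Legendre covariate phi_0 carries the datum.  GEBV contrasts are invariant
to that choice.

The system is solved by Jacobi-preconditioned conjugate gradients with the
convergence criterion ||rhs - lhs x||^2 / ||rhs||^2 <= tol.  The additive
block of the inverse coefficient matrix (C22, the prediction error
(co)variances of the genotyped animals' regression coefficients) is
extracted with a sparse LU factorization at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd  # noqa: F401  (level maps in build_design)
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .basis import LegendreBasis
from .data import CovarianceComponents, Pedigree, PhenotypeTable
from .kinship import RelationshipSet, build_A_inverse

DENSE_GUARD = 50_000  # refuse C22 extraction above this system dimension


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass
class DesignInfo:
    """Record-level design arrays shared by the solver and the Gibbs sampler."""

    y: np.ndarray
    rinv: np.ndarray
    rec_class: np.ndarray
    X: sp.csr_matrix
    fixed_labels: list[str]
    phi_fix: np.ndarray
    phi_rand: np.ndarray
    rec_animal: np.ndarray  # pedigree position per record
    rec_pe: np.ndarray  # position in phen_ids per record
    phen_ids: np.ndarray
    hy_levels: np.ndarray
    bm_levels: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def build_design(
    phenos: PhenotypeTable,
    pedigree: Pedigree,
    basis: LegendreBasis,
    comps: CovarianceComponents,
    fixed_order: int = 4,
) -> DesignInfo:
    """Build X (drop-first herd-year/birth-month dummies + fixed regression),
    the random-regression covariates, and the residual scaling per record."""
    phenos.check_against_pedigree(pedigree)
    df = phenos.frame
    ages = df["age_months"].to_numpy()
    y = df["value"].to_numpy(dtype=float)
    k = comps.order
    phi_fix = basis.design(ages, order=fixed_order)
    phi_rand = basis.design(ages, order=k - 1)
    rec_class = comps.residual_class(ages)
    rinv = 1.0 / comps.sigma_e2[rec_class]

    hy_levels = np.array(sorted(df["herd_year"].unique()))
    bm_levels = np.array(sorted(df["birth_month"].unique()))
    hy_pos = {v: i for i, v in enumerate(hy_levels)}
    bm_pos = {v: i for i, v in enumerate(bm_levels)}
    n_rec = len(df)
    n_hy = max(len(hy_levels) - 1, 0)
    n_bm = max(len(bm_levels) - 1, 0)
    n_fixed = n_hy + n_bm + fixed_order + 1

    rows, cols, vals = [], [], []
    labels = (
        [f"herd_year:{v}" for v in hy_levels[1:]]
        + [f"birth_month:{v}" for v in bm_levels[1:]]
        + [f"fixed_reg:phi{j}" for j in range(fixed_order + 1)]
    )
    hy_col = df["herd_year"].map(hy_pos).to_numpy() - 1  # -1 = dropped level
    bm_col = df["birth_month"].map(bm_pos).to_numpy() - 1
    for r in range(n_rec):
        if hy_col[r] >= 0:
            rows.append(r)
            cols.append(hy_col[r])
            vals.append(1.0)
        if bm_col[r] >= 0:
            rows.append(r)
            cols.append(n_hy + bm_col[r])
            vals.append(1.0)
    reg0 = n_hy + n_bm
    for j in range(fixed_order + 1):
        rows.extend(range(n_rec))
        cols.extend([reg0 + j] * n_rec)
        vals.extend(phi_fix[:, j])
    X = sp.coo_matrix((vals, (rows, cols)), shape=(n_rec, n_fixed)).tocsr()

    phen_ids = np.array(sorted(df["animal"].unique()))
    pe_pos = {int(a): i for i, a in enumerate(phen_ids)}
    rec_animal = pedigree.indices(df["animal"].to_numpy())
    rec_pe = np.array([pe_pos[int(a)] for a in df["animal"]], dtype=np.int64)
    return DesignInfo(
        y=y,
        rinv=rinv,
        rec_class=rec_class,
        X=X,
        fixed_labels=labels,
        phi_fix=phi_fix,
        phi_rand=phi_rand,
        rec_animal=rec_animal,
        rec_pe=rec_pe,
        phen_ids=phen_ids,
        hy_levels=hy_levels,
        bm_levels=bm_levels,
    )


def _regression_incidence(
    positions: np.ndarray, phi: np.ndarray, n_units: int
) -> sp.csr_matrix:
    """Incidence matrix placing phi-covariates into animal-major blocks."""
    n_rec, k = phi.shape
    rows = np.repeat(np.arange(n_rec), k)
    cols = (positions[:, None] * k + np.arange(k)[None, :]).ravel()
    return sp.coo_matrix(
        (phi.ravel(), (rows, cols)), shape=(n_rec, n_units * k)
    ).tocsr()


# ---------------------------------------------------------------------------
# System
# ---------------------------------------------------------------------------


@dataclass
class MMESystem:
    lhs: sp.csr_matrix
    rhs: np.ndarray
    design: DesignInfo
    pedigree: Pedigree
    basis: LegendreBasis
    comps: CovarianceComponents
    n_fixed: int
    k: int

    @property
    def n_ped(self) -> int:
        return len(self.pedigree)

    @property
    def n_phen(self) -> int:
        return len(self.design.phen_ids)

    @property
    def dim(self) -> int:
        return self.lhs.shape[0]

    def additive_slice(self) -> slice:
        return slice(self.n_fixed, self.n_fixed + self.k * self.n_ped)


@dataclass
class MMESolution:
    b_hat: np.ndarray
    a_hat: np.ndarray  # (n_ped, k), pedigree order
    pe_hat: np.ndarray  # (n_phen, k)
    convergence_history: list[float]
    ped_ids: np.ndarray
    phen_ids: np.ndarray
    fixed_labels: list[str] = field(default_factory=list)

    @property
    def n_iter(self) -> int:
        return len(self.convergence_history)


def assemble_mme(
    phenos: PhenotypeTable,
    pedigree: Pedigree,
    basis: LegendreBasis,
    comps: CovarianceComponents,
    relationships: RelationshipSet | None = None,
    fixed_order: int = 4,
) -> MMESystem:
    """Assemble LHS/RHS. Without ``relationships`` the model is pedigree-only
    (H^-1 reduces to A^-1)."""
    design = build_design(phenos, pedigree, basis, comps, fixed_order=fixed_order)
    k = comps.order
    n_ped = len(pedigree)
    n_phen = len(design.phen_ids)
    H_inv = relationships.H_inv if relationships is not None else build_A_inverse(pedigree)

    Z1 = _regression_incidence(design.rec_animal, design.phi_rand, n_ped)
    Z2 = _regression_incidence(design.rec_pe, design.phi_rand, n_phen)
    W = sp.hstack([design.X, Z1, Z2]).tocsr()
    Rinv = sp.diags(design.rinv)
    data_part = (W.T @ Rinv @ W).tocsr()

    Vg_inv = np.linalg.inv(comps.V_g)
    Vp_inv = np.linalg.inv(comps.V_p)
    prior = sp.block_diag(
        [
            sp.csr_matrix((design.n_fixed, design.n_fixed)),
            sp.kron(H_inv, Vg_inv),
            sp.kron(sp.identity(n_phen, format="csr"), Vp_inv),
        ],
        format="csr",
    )
    lhs = (data_part + prior).tocsr()
    rhs = W.T @ (design.rinv * design.y)

    # estimability guard: every retained fixed-effect column must touch data
    col_counts = np.diff(design.X.tocsc().indptr)
    if np.any(col_counts == 0):
        bad = [design.fixed_labels[i] for i in np.flatnonzero(col_counts == 0)]
        raise ValueError(f"fixed-effect levels without records: {bad}")

    return MMESystem(
        lhs=lhs,
        rhs=rhs,
        design=design,
        pedigree=pedigree,
        basis=basis,
        comps=comps,
        n_fixed=design.n_fixed,
        k=k,
    )


def solve_pcg(
    system: MMESystem,
    tol: float = 1e-14,
    max_iter: int = 20_000,
    precondition: bool = True,
) -> MMESolution:
    """Preconditioned conjugate gradients on the assembled system.

    Convergence criterion: the squared ratio of norms
    ``||rhs - lhs x||^2 / ||rhs||^2 <= tol`` (Jacobi preconditioner).
    """
    A, b = system.lhs, system.rhs
    bnorm2 = float(b @ b)
    if bnorm2 == 0.0:
        x = np.zeros_like(b)
        return _split_solution(system, x, [0.0])
    m_inv = 1.0 / A.diagonal() if precondition else np.ones_like(b)
    x = np.zeros_like(b)
    r = b.copy()
    z = m_inv * r
    p = z.copy()
    rz = float(r @ z)
    history: list[float] = []
    for _ in range(max_iter):
        Ap = A @ p
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        crit = float(r @ r) / bnorm2
        history.append(crit)
        if crit <= tol:
            return _split_solution(system, x, history)
        z = m_inv * r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise ConvergenceError(
        f"PCG did not reach {tol:g} in {max_iter} iterations "
        f"(last criterion {history[-1]:.3g})"
    )


def _split_solution(
    system: MMESystem, x: np.ndarray, history: list[float]
) -> MMESolution:
    nf, k = system.n_fixed, system.k
    n_ped, n_phen = system.n_ped, system.n_phen
    a = x[nf : nf + k * n_ped].reshape(n_ped, k)
    pe = x[nf + k * n_ped :].reshape(n_phen, k)
    return MMESolution(
        b_hat=x[:nf],
        a_hat=a,
        pe_hat=pe,
        convergence_history=history,
        ped_ids=system.pedigree.ids,
        phen_ids=system.design.phen_ids,
        fixed_labels=system.design.fixed_labels,
    )


def gebv_at_age(
    solution: MMESolution,
    basis: LegendreBasis,
    age: float,
    animals=None,
) -> np.ndarray:
    """GEBV(t) = phi(t)' a_hat_l for the requested animals (default: all)."""
    k = solution.a_hat.shape[1]
    phi = basis.row(age, order=k - 1)
    if animals is None:
        return solution.a_hat @ phi
    pos = {int(a): i for i, a in enumerate(solution.ped_ids)}
    try:
        idx = np.array([pos[int(a)] for a in animals], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"animal absent from solution: {exc}") from None
    return solution.a_hat[idx] @ phi


def pev_block_c22(
    system: MMESystem,
    genotyped_ids,
    max_dim: int = DENSE_GUARD,
) -> np.ndarray:
    """Additive-coefficient block of LHS^-1 for the genotyped animals.

    Returns the (k n_g) x (k n_g) prediction-error (co)variance matrix in
    animal-major ordering, computed by sparse LU solves against unit
    right-hand sides.  Refuses systems larger than ``max_dim`` -- large-scale
    sparse-inversion machinery is out of scope for this package.
    """
    if system.dim > max_dim:
        raise ValueError(
            f"system dimension {system.dim} exceeds the C22 guard ({max_dim})"
        )
    idx = system.pedigree.indices(genotyped_ids)
    k = system.k
    cols = (
        system.n_fixed + (idx[:, None] * k + np.arange(k)[None, :]).ravel()
    )
    lu = spla.splu(system.lhs.tocsc())
    E = np.zeros((system.dim, len(cols)))
    E[cols, np.arange(len(cols))] = 1.0
    sol = lu.solve(E)
    C22 = sol[cols]
    return 0.5 * (C22 + C22.T)  # symmetrize roundoff
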