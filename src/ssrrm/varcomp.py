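"""Bayesian estimation of the RRM variance components by Gibbs sampling.

The model is the pedigree-only random regression model (no genomic
information): additive coefficient vectors with covariance ``A (x) V_g``,
permanent-environment vectors with ``I (x) V_p`` and age-class heterogeneous
residuals.  The sampler alternates

* location parameters from their full conditionals -- fixed effects one
  scalar at a time, additive and permanent-environment coefficients one
  k-vector (animal) at a time, using the sparse A^-1 neighbor structure;
* ``V_g | a`` from an inverse-Wishart with scale ``S0 + U' A^-1 U``;
* ``V_p | pe`` from an inverse-Wishart with scale ``S0 + P' P``;
* each residual class variance from a scaled inverse chi-square.

Single-site (per-animal block) location sampling has the same stationary
distribution as a joint draw and keeps the per-iteration cost linear in the
number of records, which is what makes dense-free chains feasible on one
CPU; the sweep is JIT-compiled with numba when available.

Priors default to weakly-informative proper choices: inverse-Wishart with
identity scale matrix and ``df = k + 2`` for V_g and V_p, and a
scaled inverse chi-square with ``df = 1`` and scale 1 for the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import LegendreBasis
from .data import CovarianceComponents, Pedigree, PhenotypeTable, default_residual_bounds
from .kinship import build_A_inverse
from .mme import DesignInfo, build_design

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "GibbsPriors",
    "PosteriorChain",
    "gibbs_rrm",
    "heritability_at_age",
    "genetic_correlation",
]


@dataclass
class GibbsPriors:
    """Weak proper priors; all configurable."""

    vg_scale: np.ndarray | None = None  # default I_k
    vg_df: float | None = None  # default k + 2
    vp_scale: np.ndarray | None = None
    vp_df: float | None = None
    e_df: float = 1.0
    e_scale: float = 1.0

    def resolved(self, k: int) -> "GibbsPriors":
        return GibbsPriors(
            vg_scale=np.eye(k) if self.vg_scale is None else np.asarray(self.vg_scale),
            vg_df=float(k + 2) if self.vg_df is None else float(self.vg_df),
            vp_scale=np.eye(k) if self.vp_scale is None else np.asarray(self.vp_scale),
            vp_df=float(k + 2) if self.vp_df is None else float(self.vp_df),
            e_df=self.e_df,
            e_scale=self.e_scale,
        )


@dataclass
class PosteriorChain:
    """Kept posterior samples of (V_g, V_p, sigma_e2)."""

    V_g: np.ndarray  # (S, k, k)
    V_p: np.ndarray  # (S, k, k)
    sigma_e2: np.ndarray  # (S, C)
    class_bounds: np.ndarray
    burn_in: int
    thinning: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.V_g.shape[0]

    def posterior_mean(self) -> CovarianceComponents:
        return CovarianceComponents(
            V_g=self.V_g.mean(axis=0),
            V_p=self.V_p.mean(axis=0),
            sigma_e2=self.sigma_e2.mean(axis=0),
            class_bounds=self.class_bounds,
            provenance="gibbs_posterior_mean",
        )

    def credible_interval(self, which: str, level: float = 0.90) -> np.ndarray:
        """Equal-tail interval for diag entries ('V_g','V_p') or 'sigma_e2'."""
        lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
        arr = getattr(self, which)
        if arr.ndim == 3:
            arr = np.diagonal(arr, axis1=1, axis2=2)
        return np.quantile(arr, [lo, hi], axis=0)

    def to_tsv(self, path) -> None:
        import pandas as pd

        k = self.V_g.shape[1]
        cols = {}
        for i in range(k):
            for j in range(i, k):
                cols[f"Vg_{i}{j}"] = self.V_g[:, i, j]
                cols[f"Vp_{i}{j}"] = self.V_p[:, i, j]
        for c in range(self.sigma_e2.shape[1]):
            cols[f"sigma_e2_{c}"] = self.sigma_e2[:, c]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# numba sweep
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_numba(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _location_sweep(
    beta,
    U,
    P,
    e,
    rinv,
    x_indptr,
    x_rows,
    x_vals,
    phi,
    an_indptr,
    an_order,
    ped_to_pe,
    ai_indptr,
    ai_idx,
    ai_val,
    Wg,
    Wp,
    xtx_chol,
):
    """One Gibbs sweep over all location parameters; updates in place.

    Fixed effects are drawn jointly (their precision Cholesky ``xtx_chol``
    is precomputed per iteration); each phenotyped animal's additive and
    permanent-environment coefficient vectors are drawn as one joint
    2k-block.  Blocking matters: the likelihood only sees u_l + pe_l (both
    multiply the same covariates), so scalar updates random-walk along that
    ridge and let the variance draws run away.
    """
    n_fixed = beta.shape[0]
    k = U.shape[1]
    # fixed effects: joint draw beta ~ N((X'RX)^-1 X'R r, (X'RX)^-1)
    rhs_f = np.zeros(n_fixed)
    for j in range(n_fixed):
        acc = 0.0
        for t in range(x_indptr[j], x_indptr[j + 1]):
            r = x_rows[t]
            acc += x_vals[t] * rinv[r] * e[r]
        rhs_f[j] = acc
    # rhs currently uses residuals with old beta still subtracted; add X'R X beta_old
    # via the identity X'R(e + X b_old) = X'R e + (X'RX) b_old
    rhs_f += (xtx_chol @ xtx_chol.T) @ beta
    half = np.linalg.solve(xtx_chol, rhs_f)
    mean_f = np.linalg.solve(xtx_chol.T, half)
    new_f = mean_f + np.linalg.solve(xtx_chol.T, np.random.standard_normal(n_fixed))
    d_f = new_f - beta
    for j in range(n_fixed):
        if d_f[j] != 0.0:
            for t in range(x_indptr[j], x_indptr[j + 1]):
                e[x_rows[t]] -= x_vals[t] * d_f[j]
        beta[j] = new_f[j]
    # animal blocks: joint (u_l, pe_l) for phenotyped, u_l alone otherwise
    n_ped = U.shape[0]
    for l in range(n_ped):
        q = ped_to_pe[l]
        # data contributions (phenotyped animals only)
        D = np.zeros((k, k))
        rhs_d = np.zeros(k)
        old_u = U[l].copy()
        if q >= 0:
            old_p = P[q].copy()
            for t in range(an_indptr[l], an_indptr[l + 1]):
                r = an_order[t]
                w = rinv[r]
                both = 0.0
                for a in range(k):
                    both += phi[r, a] * (old_u[a] + old_p[a])
                resid = e[r] + both
                for a in range(k):
                    rhs_d[a] += phi[r, a] * w * resid
                    for b in range(k):
                        D[a, b] += phi[r, a] * phi[r, b] * w
        # pedigree prior terms for u_l
        prior_rhs = np.zeros(k)
        a_ll = 0.0
        for t in range(ai_indptr[l], ai_indptr[l + 1]):
            j = ai_idx[t]
            v = ai_val[t]
            if j == l:
                a_ll = v
            else:
                for a in range(k):
                    s = 0.0
                    for b in range(k):
                        s += Wg[a, b] * U[j, b]
                    prior_rhs[a] -= v * s
        if q >= 0:
            prec = np.zeros((2 * k, 2 * k))
            rhs = np.zeros(2 * k)
            for a in range(k):
                for b in range(k):
                    prec[a, b] = D[a, b] + a_ll * Wg[a, b]
                    prec[a, k + b] = D[a, b]
                    prec[k + a, b] = D[a, b]
                    prec[k + a, k + b] = D[a, b] + Wp[a, b]
                rhs[a] = rhs_d[a] + prior_rhs[a]
                rhs[k + a] = rhs_d[a]
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            z = np.random.standard_normal(2 * k)
            new = mean + np.linalg.solve(L.T, z)
            du = np.empty(k)
            dsum = np.empty(k)
            for a in range(k):
                du[a] = new[a] - old_u[a]
                dsum[a] = du[a] + (new[k + a] - old_p[a])
                U[l, a] = new[a]
                P[q, a] = new[k + a]
            for t in range(an_indptr[l], an_indptr[l + 1]):
                r = an_order[t]
                s = 0.0
                for a in range(k):
                    s += phi[r, a] * dsum[a]
                e[r] -= s
        else:
            prec = a_ll * Wg
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, prior_rhs)
            z = np.random.standard_normal(k)
            new = mean + np.linalg.solve(L.T, z)
            for a in range(k):
                U[l, a] = new[a]


def _grouped_records(codes: np.ndarray, n_groups: int):
    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes, minlength=n_groups)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, order


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def gibbs_rrm(
    phenos: PhenotypeTable,
    pedigree: Pedigree,
    basis: LegendreBasis,
    priors: GibbsPriors | None = None,
    n_iter: int = 20_000,
    burn_in: int = 5_000,
    thinning: int = 10,
    seed: int = 0,
    order: int = 3,
    fixed_order: int = 4,
    n_residual_classes: int = 6,
    verbose: bool = False,
) -> PosteriorChain:
    """Run the Gibbs chain on the pedigree-only RRM; reproducible under seed."""
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    k = order
    priors = (priors or GibbsPriors()).resolved(k)
    bounds = default_residual_bounds(n_residual_classes)
    # start components: crude phenotypic split
    v0 = float(np.var(phenos.frame["value"]))
    start = CovarianceComponents(
        V_g=np.eye(k) * v0 / 4.0,
        V_p=np.eye(k) * v0 / 4.0,
        sigma_e2=np.full(n_residual_classes, v0 / 2.0),
        class_bounds=bounds,
    )
    design: DesignInfo = build_design(
        phenos, pedigree, basis, start, fixed_order=fixed_order
    )
    A_inv = build_A_inverse(pedigree).tocsr()
    n_ped, n_phen = len(pedigree), len(design.phen_ids)
    n_classes = n_residual_classes
    n_c = np.bincount(design.rec_class, minlength=n_classes).astype(float)

    Xc = design.X.tocsc()
    an_indptr, an_order = _grouped_records(design.rec_animal, n_ped)
    # pedigree position -> phenotyped index (-1 for animals without records)
    ped_to_pe = np.full(n_ped, -1, dtype=np.int64)
    ped_to_pe[pedigree.indices(design.phen_ids)] = np.arange(n_phen)

    rng = np.random.default_rng([17, int(seed)])
    _seed_numba(int(seed) % (2**31 - 1))

    V_g = start.V_g.copy()
    V_p = start.V_p.copy()
    sigma2 = start.sigma_e2.copy()
    beta = np.zeros(design.n_fixed)
    U = np.zeros((n_ped, k))
    P = np.zeros((n_phen, k))
    y = design.y
    phi = np.ascontiguousarray(design.phi_rand)

    keep_g, keep_p, keep_e = [], [], []
    import scipy.sparse as sp

    x_indptr = Xc.indptr.astype(np.int64)
    x_rows = Xc.indices.astype(np.int64)
    x_vals = Xc.data.astype(np.float64)
    ai_indptr = A_inv.indptr.astype(np.int64)
    ai_idx = A_inv.indices.astype(np.int64)
    ai_val = A_inv.data.astype(np.float64)
    for it in range(n_iter):
        rinv = 1.0 / sigma2[design.rec_class]
        # exact residual recompute guards against incremental drift
        e = (
            y
            - design.X @ beta
            - np.einsum("rk,rk->r", phi, U[design.rec_animal])
            - np.einsum("rk,rk->r", phi, P[design.rec_pe])
        )
        xtx = (design.X.T @ sp.diags(rinv) @ design.X).toarray()
        xtx_chol = np.linalg.cholesky(xtx)
        _location_sweep(
            beta,
            U,
            P,
            e,
            rinv,
            x_indptr,
            x_rows,
            x_vals,
            phi,
            an_indptr,
            an_order,
            ped_to_pe,
            ai_indptr,
            ai_idx,
            ai_val,
            np.linalg.inv(V_g),
            np.linalg.inv(V_p),
            xtx_chol,
        )
        # variance draws
        sse = np.bincount(design.rec_class, weights=e * e, minlength=n_classes)
        df_e = priors.e_df + n_c
        sigma2 = (priors.e_df * priors.e_scale + sse) / rng.chisquare(df_e)
        S_a = U.T @ (A_inv @ U)
        V_g = stats.invwishart.rvs(
            df=priors.vg_df + n_ped, scale=priors.vg_scale + S_a, random_state=rng
        )
        S_p = P.T @ P
        V_p = stats.invwishart.rvs(
            df=priors.vp_df + n_phen, scale=priors.vp_scale + S_p, random_state=rng
        )
        if it >= burn_in and (it - burn_in) % thinning == 0:
            keep_g.append(V_g.copy())
            keep_p.append(V_p.copy())
            keep_e.append(sigma2.copy())
        if verbose and (it + 1) % 100 == 0:  # pragma: no cover
            print(f"iter {it + 1}: diag Vg={np.diag(V_g)}, sigma2={sigma2}")

    return PosteriorChain(
        V_g=np.array(keep_g),
        V_p=np.array(keep_p),
        sigma_e2=np.array(keep_e),
        class_bounds=bounds,
        burn_in=burn_in,
        thinning=thinning,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Derived functions of age
# ---------------------------------------------------------------------------


def heritability_at_age(
    comps: CovarianceComponents, basis: LegendreBasis, age: float
) -> float:
    """h2(t) = phi' V_g phi / (phi' V_g phi + phi' V_p phi + sigma_e2(t))."""
    phi = basis.row(age, order=comps.order - 1)
    vg = float(phi @ comps.V_g @ phi)
    vp = float(phi @ comps.V_p @ phi)
    ve = float(comps.residual_variance(age))
    return vg / (vg + vp + ve)


def genetic_correlation(
    comps: CovarianceComponents, basis: LegendreBasis, age1: float, age2: float
) -> float:
    """r_g(t1, t2) = phi1' V_g phi2 / sqrt(phi1' V_g phi1 * phi2' V_g phi2)."""
    k = comps.order - 1
    p1 = basis.row(age1, order=k)
    p2 = basis.row(age2, order=k)
    v1 = float(p1 @ comps.V_g @ p1)
    v2 = float(p2 @ comps.V_g @ p2)
    if v1 <= 0.0 or v2 <= 0.0:
        raise ValueError("age-specific additive variance is zero; correlation undefined")
    return float(p1 @ comps.V_g @ p2) / np.sqrt(v1 * v2)
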