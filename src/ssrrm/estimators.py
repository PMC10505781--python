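"""scikit-learn-style estimators over the single-step RRM pipeline.

These classes follow the sklearn contract (``get_params``/``set_params``
via ``BaseEstimator``, fitted attributes with trailing underscores, fit
returning self) so they compose with sklearn tooling, while the heavy
lifting lives in the functional modules (:mod:`ssrrm.kinship`,
:mod:`ssrrm.mme`, :mod:`ssrrm.varcomp`, :mod:`ssrrm.gwas`).  The "X" of
each estimator is the domain container the method consumes (a
:class:`~ssrrm.data.PhenotypeTable`, a pedigree, a genotype panel) rather
than a rectangular feature matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import gwas as gwas_mod
from .basis import LegendreBasis
from .data import CovarianceComponents, GenotypePanel, Pedigree, PhenotypeTable
from .kinship import RelationshipSet
from .mme import assemble_mme, gebv_at_age, pev_block_c22, solve_pcg
from .preprocess import filter_phenotypes, filter_snps
from .varcomp import GibbsPriors, gibbs_rrm

__all__ = [
    "SNPFilter",
    "PhenotypeFilter",
    "GibbsVarianceComponents",
    "SingleStepRRM",
    "LongitudinalGWAS",
]


class SNPFilter(BaseEstimator):
    """Transformer applying the marker edits (MAF and call-rate floors)."""

    def __init__(self, maf_min: float = 0.05, call_rate_min: float = 0.90):
        self.maf_min = maf_min
        self.call_rate_min = call_rate_min

    def fit(self, X: GenotypePanel, y=None):
        _, self.report_ = filter_snps(X, self.maf_min, self.call_rate_min)
        return self

    def transform(self, X: GenotypePanel) -> GenotypePanel:
        panel, self.report_ = filter_snps(X, self.maf_min, self.call_rate_min)
        return panel

    def fit_transform(self, X: GenotypePanel, y=None) -> GenotypePanel:
        return self.transform(X)


class PhenotypeFilter(BaseEstimator):
    """Transformer applying the record edits (outliers + animal eligibility)."""

    def __init__(
        self,
        sd_mult: float = 5.0,
        min_records: int = 3,
        early_age: int = 10,
        late_age: int = 30,
    ):
        self.sd_mult = sd_mult
        self.min_records = min_records
        self.early_age = early_age
        self.late_age = late_age

    def fit(self, X: PhenotypeTable, y=None):
        _, self.report_ = self._run(X)
        return self

    def _run(self, X):
        return filter_phenotypes(
            X,
            sd_mult=self.sd_mult,
            min_records=self.min_records,
            early_age=self.early_age,
            late_age=self.late_age,
        )

    def transform(self, X: PhenotypeTable) -> PhenotypeTable:
        table, self.report_ = self._run(X)
        return table

    def fit_transform(self, X: PhenotypeTable, y=None) -> PhenotypeTable:
        return self.transform(X)


class GibbsVarianceComponents(BaseEstimator):
    """Gibbs-sampling estimator of the RRM variance components.

    Fitted attributes: ``chain_`` (kept samples), ``components_`` (posterior
    means as :class:`CovarianceComponents`), ``V_g_``, ``V_p_``,
    ``sigma_e2_``.
    """

    def __init__(
        self,
        n_iter: int = 20_000,
        burn_in: int = 5_000,
        thinning: int = 10,
        seed: int = 0,
        order: int = 3,
        fixed_order: int = 4,
        n_residual_classes: int = 6,
        priors: GibbsPriors | None = None,
        t_min: float = 0.0,
        t_max: float = 60.0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thinning = thinning
        self.seed = seed
        self.order = order
        self.fixed_order = fixed_order
        self.n_residual_classes = n_residual_classes
        self.priors = priors
        self.t_min = t_min
        self.t_max = t_max

    def fit(self, X: PhenotypeTable, y=None, *, pedigree: Pedigree):
        basis = LegendreBasis(
            order=max(self.fixed_order, self.order - 1),
            t_min=self.t_min,
            t_max=self.t_max,
        )
        self.chain_ = gibbs_rrm(
            X,
            pedigree,
            basis,
            priors=self.priors,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thinning=self.thinning,
            seed=self.seed,
            order=self.order,
            fixed_order=self.fixed_order,
            n_residual_classes=self.n_residual_classes,
        )
        self.components_ = self.chain_.posterior_mean()
        self.V_g_ = self.components_.V_g
        self.V_p_ = self.components_.V_p
        self.sigma_e2_ = self.components_.sigma_e2
        return self


class SingleStepRRM(BaseEstimator):
    """Single-step GBLUP random regression model.

    ``fit`` assembles and solves the MME for a phenotype table given a
    pedigree, an optional (filtered) genotype panel and the variance
    components; ``predict`` returns GEBV at requested ages.

    Fitted attributes: ``solution_`` (all MME solutions), ``coef_additive_``
    (n_ped x k), ``coef_pe_``, ``fixed_effects_``, ``relationships_``,
    ``system_``, ``n_iter_``, and lazily ``c22_`` (coefficient-level PEV of
    the genotyped animals).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        tune: bool = True,
        tune_order: str = "tune_then_blend",
        centering: str = "observed",
        fixed_order: int = 4,
        order: int = 3,
        tol: float = 1e-14,
        max_iter: int = 20_000,
        t_min: float = 0.0,
        t_max: float = 60.0,
    ):
        self.alpha = alpha
        self.tune = tune
        self.tune_order = tune_order
        self.centering = centering
        self.fixed_order = fixed_order
        self.order = order
        self.tol = tol
        self.max_iter = max_iter
        self.t_min = t_min
        self.t_max = t_max

    def fit(
        self,
        X: PhenotypeTable,
        y=None,
        *,
        pedigree: Pedigree,
        genotypes: GenotypePanel | None = None,
        components: CovarianceComponents,
    ):
        if components.order != self.order:
            raise ValueError(
                f"components are order {components.order}, estimator expects "
                f"{self.order}"
            )
        self.basis_ = LegendreBasis(
            order=max(self.fixed_order, self.order - 1),
            t_min=self.t_min,
            t_max=self.t_max,
        )
        self.relationships_ = (
            None
            if genotypes is None
            else RelationshipSet.from_data(
                pedigree,
                genotypes,
                alpha=self.alpha,
                tune=self.tune,
                tune_order=self.tune_order,
                centering=self.centering,
            )
        )
        self.system_ = assemble_mme(
            X,
            pedigree,
            self.basis_,
            components,
            relationships=self.relationships_,
            fixed_order=self.fixed_order,
        )
        self.solution_ = solve_pcg(
            self.system_, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_additive_ = self.solution_.a_hat
        self.coef_pe_ = self.solution_.pe_hat
        self.fixed_effects_ = self.solution_.b_hat
        self.n_iter_ = self.solution_.n_iter
        self.components_ = components
        self.pedigree_ = pedigree
        self.panel_ = genotypes
        return self

    def predict(self, ages, animals=None) -> np.ndarray:
        """GEBV for ``animals`` (default all) at each age; shape (n, n_ages)."""
        check_is_fitted(self, "solution_")
        ages = np.atleast_1d(ages)
        out = np.column_stack(
            [gebv_at_age(self.solution_, self.basis_, a, animals=animals) for a in ages]
        )
        return out

    def c22(self) -> np.ndarray:
        check_is_fitted(self, "solution_")
        if self.panel_ is None:
            raise ValueError("C22 for genotyped animals needs a genotype panel")
        if not hasattr(self, "c22_"):
            self.c22_ = pev_block_c22(self.system_, self.panel_.animal_ids)
        return self.c22_


class LongitudinalGWAS(BaseEstimator):
    """Back-solved SNP tests over a list of ages from a fitted SingleStepRRM.

    Fitted attributes: ``results_`` (:class:`~ssrrm.gwas.GwasResult`),
    ``m_eff_``, ``threshold_neglog10_``.
    """

    def __init__(
        self,
        ages=gwas_mod.DEFAULT_AGES,
        alpha: float = 0.05,
        per_chromosome_meff: bool = True,
    ):
        self.ages = ages
        self.alpha = alpha
        self.per_chromosome_meff = per_chromosome_meff

    def fit(self, X: SingleStepRRM, y=None):
        """``X`` is a fitted :class:`SingleStepRRM` with a genotype panel."""
        check_is_fitted(X, "solution_")
        if X.panel_ is None or X.relationships_ is None:
            raise ValueError("the model was fitted without genomic information")
        self.results_ = gwas_mod.run_longitudinal_gwas(
            X.panel_,
            X.relationships_,
            X.solution_,
            X.system_,
            X.components_,
            X.basis_,
            ages=self.ages,
            alpha=self.alpha,
            per_chromosome_meff=self.per_chromosome_meff,
            C22=X.c22(),
        )
        self.m_eff_ = self.results_.m_eff
        self.threshold_neglog10_ = self.results_.threshold_neglog10
        return self
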