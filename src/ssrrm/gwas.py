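"""Longitudinal single-step GWAS: back-solved SNP effects and tests.

Given GEBV at age ``t`` for the genotyped animals, the three-step
procedure is

1. ``GEBV_t = Phi_t a_hat`` (age-specific breeding values);
2. SNP effects ``beta_t = q W' G^-1 GEBV_t`` with the centered marker
   matrix ``W`` and the VanRaden weighting factor
   ``q = 1 / (2 sum_o p_o (1 - p_o))``;
3. sampling variances from the prediction error (co)variances of the
   regression coefficients:

       var(beta_t) = diag[ q^2 (1-alpha)^2 W' G^-1 (G s2_ut - C22_t) G^-1 W ]

   where ``s2_ut = phi_t' V_g phi_t`` is the additive variance at age t and
   ``C22_t = Phi_t C22 Phi_t'`` collapses each animal-pair block of the
   coefficient-level PEV matrix to age t.

Two-sided P-values are ``2 (1 - Phi_N(|beta/se|))`` evaluated through the
log survival function so extreme signals do not underflow.  Multiple
testing uses the eigenvalue-based effective number of independent SNPs
(per chromosome, summed) and the Sidak-style genome-wide threshold
``-log10[1 - (1 - alpha)^(1/M_eff)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import LegendreBasis
from .data import CovarianceComponents, GenotypePanel
from .kinship import RelationshipSet
from .mme import MMESolution, MMESystem, gebv_at_age, pev_block_c22

__all__ = [
    "GwasResult",
    "snp_effects_at_age",
    "collapse_c22",
    "snp_variance_at_age",
    "snp_pvalues",
    "variance_explained",
    "effective_num_snp",
    "liji_meff",
    "significance_threshold",
    "run_longitudinal_gwas",
]


def snp_effects_at_age(
    panel: GenotypePanel, rel: RelationshipSet, gebv_t: np.ndarray
) -> np.ndarray:
    """beta_t = q W' G_adj^-1 GEBV_t (one entry per SNP)."""
    gebv_t = np.asarray(gebv_t, dtype=float)
    if len(gebv_t) != panel.n_animals:
        raise ValueError("GEBV vector length does not match the genotyped panel")
    W = panel.centered_matrix(rel.centering_freq)
    return rel.q * (W.T @ (rel.G_adj_inv @ gebv_t))


def collapse_c22(C22: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Collapse coefficient-level PEV blocks to one age:
    (C22_t)_{lj} = phi' C22[l-block, j-block] phi."""
    k = len(phi)
    n_g = C22.shape[0] // k
    if C22.shape != (n_g * k, n_g * k):
        raise ValueError("C22 is not square with whole animal-major blocks")
    blocks = C22.reshape(n_g, k, n_g, k)
    return np.einsum("a,iajb,b->ij", phi, blocks, phi)


def snp_variance_at_age(
    panel: GenotypePanel,
    rel: RelationshipSet,
    C22: np.ndarray,
    basis: LegendreBasis,
    age: float,
    comps: CovarianceComponents,
) -> np.ndarray:
    """Sampling variance of each back-solved SNP effect at one age."""
    k = comps.order
    phi = basis.row(age, order=k - 1)
    sigma2_ut = float(phi @ comps.V_g @ phi)
    if sigma2_ut <= 0.0:
        raise ValueError("additive variance at this age is zero")
    Ct22 = collapse_c22(C22, phi)
    W = panel.centered_matrix(rel.centering_freq)
    B = rel.G_adj_inv @ W  # n_g x m
    scale = (rel.q * (1.0 - rel.alpha)) ** 2
    var = scale * (
        sigma2_ut * np.einsum("ij,ij->j", W, B) - np.einsum("ij,ij->j", B, Ct22 @ B)
    )
    floor = -1e-8 * max(float(np.abs(var).max()), scale * sigma2_ut)
    if np.any(var < floor):
        raise ValueError(
            f"{int((var < floor).sum())} SNP variances are negative beyond "
            "tolerance; C22 and the variance components are inconsistent"
        )
    return np.clip(var, 0.0, None)


def snp_pvalues(
    effects: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal P-values and underflow-safe -log10(P)."""
    variances = np.asarray(variances, dtype=float)
    if np.any(variances <= 0.0):
        raise ValueError("non-positive SNP-effect variance")
    z = np.abs(np.asarray(effects, dtype=float)) / np.sqrt(variances)
    p = 2.0 * stats.norm.sf(z)
    neg_log10 = -(np.log(2.0) + stats.norm.logsf(z)) / np.log(10.0)
    return p, neg_log10


def variance_explained(
    effects: np.ndarray, freq: np.ndarray, sigma2_ut: float
) -> np.ndarray:
    """Percent of the age-t additive variance per SNP: 100*2p(1-p)b^2/s2_ut."""
    if sigma2_ut <= 0.0:
        raise ValueError("sigma2_ut must be positive")
    freq = np.asarray(freq, dtype=float)
    return 100.0 * 2.0 * freq * (1.0 - freq) * np.asarray(effects) ** 2 / sigma2_ut


def liji_meff(eigenvalues: np.ndarray) -> float:
    """Effective number of tests from correlation-matrix eigenvalues:
    M_eff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ]."""
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    lam = np.round(lam, 9)  # integer eigenvalues (perfect LD blocks) stay integral
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def effective_num_snp(
    dosages: np.ndarray,
    chrom: np.ndarray | None = None,
    per_chromosome: bool = True,
) -> float:
    """Li-Ji effective number of independent SNPs.

    ``dosages`` is the (possibly mean-imputed) n x m dosage matrix. With
    ``per_chromosome`` the estimator is applied within each chromosome and
    summed (the tractable mode for large panels); the full-matrix mode is
    exact and suits small panels.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 SNPs")
    sd = X.std(axis=0)
    if np.any(sd == 0.0):
        raise ValueError("constant-genotype SNP: correlation undefined; filter first")
    if per_chromosome and chrom is not None:
        total = 0.0
        for c in np.unique(chrom):
            sel = np.asarray(chrom) == c
            sub = X[:, sel]
            if sub.shape[1] == 1:
                total += 1.0
                continue
            lam = np.linalg.eigvalsh(np.corrcoef(sub, rowvar=False))
            total += liji_meff(lam)
        return total
    lam = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
    return liji_meff(lam)


def significance_threshold(m_eff: float, alpha: float = 0.05) -> float:
    """Sidak-style genome-wide threshold -log10[1 - (1 - alpha)^(1/M_eff)]."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    # log-space evaluation: 1-(1-a)^(1/m) = -expm1(log(1-a)/m)
    return float(-np.log10(-np.expm1(np.log1p(-alpha) / m_eff)))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

DEFAULT_AGES = (10, 20, 30, 40, 50, 60)


@dataclass
class GwasResult:
    """Per-SNP, per-age effects and tests plus the global threshold."""

    table: pd.DataFrame  # snp_id chrom pos age effect se p neg_log10_p pct_var
    summary: pd.DataFrame  # snp_id chrom pos min_p ages_significant class
    ages: tuple
    m_eff: float
    threshold_neglog10: float
    sigma2_ut: dict = field(default_factory=dict)

    def at_age(self, age) -> pd.DataFrame:
        return self.table[self.table["age"] == age].reset_index(drop=True)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for age in self.ages:
            self.at_age(age).to_csv(out / f"gwas_age{age:02d}.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "gwas_summary.tsv", sep="\t", index=False)


def run_longitudinal_gwas(
    panel: GenotypePanel,
    rel: RelationshipSet,
    solution: MMESolution,
    system: MMESystem,
    comps: CovarianceComponents,
    basis: LegendreBasis,
    ages=DEFAULT_AGES,
    alpha: float = 0.05,
    per_chromosome_meff: bool = True,
    C22: np.ndarray | None = None,
) -> GwasResult:
    """Back-solve SNP effects, variances and P-values at each requested age.

    SNPs are classified as ``persistent`` (significant at every requested
    age), ``transient`` (at >= 1 but not all), or ``null``.
    """
    ages = tuple(ages)
    if len(ages) == 0:
        raise ValueError("need at least one age")
    if C22 is None:
        C22 = pev_block_c22(system, panel.animal_ids)
    m_eff = effective_num_snp(
        panel.imputed_dosages(),
        chrom=panel.snp_map["chrom"].to_numpy(),
        per_chromosome=per_chromosome_meff,
    )
    threshold = significance_threshold(m_eff, alpha=alpha)
    k = comps.order
    rows = []
    sigma2_ut = {}
    for age in ages:
        phi = basis.row(age, order=k - 1)
        s2 = float(phi @ comps.V_g @ phi)
        sigma2_ut[age] = s2
        gebv_t = gebv_at_age(solution, basis, age, animals=panel.animal_ids)
        eff = snp_effects_at_age(panel, rel, gebv_t)
        var = snp_variance_at_age(panel, rel, C22, basis, age, comps)
        p, nlp = snp_pvalues(eff, np.where(var > 0, var, np.nan))
        pct = variance_explained(eff, panel.allele_freq, s2)
        df = panel.snp_map.copy()
        df["age"] = age
        df["effect"] = eff
        df["se"] = np.sqrt(var)
        df["p"] = p
        df["neg_log10_p"] = nlp
        df["pct_var"] = pct
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)

    sig = table.assign(sig=table["neg_log10_p"] >= threshold)
    per_snp = sig.groupby("snp_id", sort=False).agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        min_p=("p", "min"),
        max_neg_log10_p=("neg_log10_p", "max"),
        ages_significant=("sig", "sum"),
    )
    n_ages = len(ages)
    per_snp["class"] = np.select(
        [per_snp["ages_significant"] == n_ages, per_snp["ages_significant"] > 0],
        ["persistent", "transient"],
        default="null",
    )
    summary = per_snp.reset_index()
    return GwasResult(
        table=table,
        summary=summary,
        ages=ages,
        m_eff=m_eff,
        threshold_neglog10=threshold,
        sigma2_ut=sigma2_ut,
    )
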