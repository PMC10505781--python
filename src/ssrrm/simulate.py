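"""Synthetic data with the exact statistical structure the pipeline assumes.

The generator emulates the kind of dataset the analysis targets: a
multi-generation pedigree with a genotyped subset, additive-genetic
regression coefficient vectors drawn from MVN(0, V_g (x) A), permanent
environment coefficients from MVN(0, V_p (x) I), irregular per-animal age
schedules of repeated records between 0 and 60 months, herd-year and
birth-month fixed effects, and age-heterogeneous residual noise.  Genotypes
come from gene dropping: founder gametes are Bernoulli draws at base
frequencies and descendants inherit one random allele per parent (unlinked
by default; an optional one-crossover-per-chromosome block mode creates LD
so that the effective number of independent SNPs drops below the SNP count).

Truth (coefficients, variance components, QTL list) is retained so every
downstream stage can be tested against known generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import LegendreBasis
from .data import (
    CovarianceComponents,
    GenotypePanel,
    Pedigree,
    PhenotypeTable,
    default_residual_bounds,
)
from .kinship import tabular_A

__all__ = [
    "SimulationConfig",
    "TrueEffects",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
]


def _default_V_g() -> np.ndarray:
    return np.array([[9.0, 0.9, 0.0], [0.9, 1.0, 0.1], [0.0, 0.1, 0.25]])


def _default_V_p() -> np.ndarray:
    return np.array([[4.0, 0.0, 0.0], [0.0, 0.5, 0.0], [0.0, 0.0, 0.1]])


def _default_residuals() -> np.ndarray:
    # noisier early measurements; heritability rises with age
    return np.array([8.0, 6.0, 5.0, 4.0, 4.0, 4.0])


def _default_fixed_curve() -> np.ndarray:
    # concave growth curve on the normalized Legendre basis:
    # mean height ~87 at birth to ~148 at 60 months
    return np.array([180.0, 25.0, -6.0, 0.0, 0.0])


@dataclass
class SimulationConfig:
    """Stated world of the generator; defaults are the default scenario.

    Scale parameters (pedigree size, SNP count) default to a desk-scale
    version of a national-evaluation dataset; variance parameters default to
    a growth-type trait whose heritability rises from ~0.3 to ~0.5 across
    the age range.
    """

    n_founders: int = 60
    n_generations: int = 5
    offspring_per_mating: int = 2
    dams_per_sire: int = 4  # polygynous (dairy-like) matings; 1 = monogamous
    genotyping_rule: str = "last_k_generations"  # all | last_k_generations | random_fraction
    genotyping_k: int = 2
    genotyping_fraction: float = 0.5
    phenotyping_rule: str = "females"  # females | nonfounders | all
    n_snp: int = 1000
    n_chromosomes: int = 5
    maf_low: float = 0.05
    maf_high: float = 0.5
    linkage: str = "unlinked"  # unlinked | block
    track_inheritance: bool = False
    V_g: np.ndarray = field(default_factory=_default_V_g)
    V_p: np.ndarray = field(default_factory=_default_V_p)
    residual_variances: np.ndarray = field(default_factory=_default_residuals)
    fixed_curve: np.ndarray = field(default_factory=_default_fixed_curve)
    n_herd_years: int = 10
    herd_year_sd: float = 2.0
    birth_month_sd: float = 0.5
    age_grid: np.ndarray = field(default_factory=lambda: np.arange(0, 61))
    records_per_animal_range: tuple[int, int] = (5, 30)
    edit_compliance: float = 0.9  # share of animals forced to satisfy the data edits
    missing_rate: float = 0.0
    qtl_spec: list[tuple[int, np.ndarray]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.V_g = np.asarray(self.V_g, dtype=float)
        self.V_p = np.asarray(self.V_p, dtype=float)
        self.residual_variances = np.asarray(self.residual_variances, dtype=float)
        self.fixed_curve = np.asarray(self.fixed_curve, dtype=float)
        self.age_grid = np.asarray(self.age_grid)
        for name, V in (("V_g", self.V_g), ("V_p", self.V_p)):
            if not np.allclose(V, V.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(V).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("founder MAF bounds must satisfy 0 < low <= high <= 0.5")
        if self.age_grid.min() < 0 or self.age_grid.max() > 60:
            raise ValueError("age_grid must lie within [0, 60] months")
        lo, hi = self.records_per_animal_range
        if not (1 <= lo <= hi):
            raise ValueError("records_per_animal_range must be 1 <= lo <= hi")

    @property
    def order(self) -> int:
        return self.V_g.shape[0]

    def true_components(self) -> CovarianceComponents:
        return CovarianceComponents(
            V_g=self.V_g,
            V_p=self.V_p,
            sigma_e2=self.residual_variances,
            class_bounds=default_residual_bounds(len(self.residual_variances)),
            provenance="true_simulated",
        )


@dataclass
class TrueEffects:
    """Generating effects, aligned to pedigree order where applicable."""

    additive_coeffs: np.ndarray  # (n_ped, k) in pedigree order
    pe_ids: np.ndarray  # phenotyped animal ids
    pe_coeffs: np.ndarray  # (n_phenotyped, k)
    herd_year_effects: np.ndarray
    birth_month_effects: np.ndarray  # length 12, months 1..12
    qtl_allele_effects: list[tuple[int, np.ndarray]] = field(default_factory=list)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(config.seed)])


def _psd_factor(V: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (handles rank loss)."""
    w, E = np.linalg.eigh(np.asarray(V, dtype=float))
    return E * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree from random matings.

    Founders (generation 0) alternate sexes.  Each later generation mates
    every available dam once to a randomly drawn sire from the previous
    generation; each sire serves up to ``dams_per_sire`` dams (polygynous,
    dairy-like -- large paternal half-sib families are what identify the
    additive against the permanent-environment covariance).  Offspring
    sexes alternate.  No selection, no deliberate inbreeding.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders to form a mating")
    rng = _rng(config, 1)
    animal, sire, dam, gen, sex = [], [], [], [], []
    for i in range(config.n_founders):
        animal.append(i + 1)
        sire.append(0)
        dam.append(0)
        gen.append(0)
        sex.append("M" if i % 2 == 0 else "F")
    next_id = config.n_founders + 1
    prev = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex[i] == "M"]
        females = [i for i in prev if sex[i] == "F"]
        if len(males) == 0 or len(females) == 0:
            raise ValueError(f"generation {g - 1} lacks a sire or a dam; cannot mate")
        rng.shuffle(males)
        rng.shuffle(females)
        n_sires = max(1, -(-len(females) // config.dams_per_sire))  # ceil
        sires = [males[i % len(males)] for i in range(n_sires)]
        born = []
        child_count = 0
        for j, d in enumerate(females):
            s = sires[j // config.dams_per_sire]
            for _ in range(config.offspring_per_mating):
                animal.append(next_id)
                sire.append(animal[s])
                dam.append(animal[d])
                gen.append(g)
                sex.append("M" if child_count % 2 == 0 else "F")
                born.append(next_id - 1)
                child_count += 1
                next_id += 1
        prev = born
    frame = pd.DataFrame(
        {"animal": animal, "sire": sire, "dam": dam, "generation": gen, "sex": sex}
    )
    return Pedigree(frame)


def select_genotyped(pedigree: Pedigree, config: SimulationConfig) -> np.ndarray:
    """Animal ids of the genotyped subset according to the genotyping rule."""
    df = pedigree.frame
    if config.genotyping_rule == "all":
        return df["animal"].to_numpy()
    if config.genotyping_rule == "last_k_generations":
        gmax = int(df["generation"].max())
        keep = df["generation"] > gmax - config.genotyping_k
        return df.loc[keep, "animal"].to_numpy()
    if config.genotyping_rule == "random_fraction":
        rng = _rng(config, 2)
        n = len(df)
        k = max(1, int(round(config.genotyping_fraction * n)))
        idx = np.sort(rng.choice(n, size=k, replace=False))
        return df["animal"].to_numpy()[idx]
    raise ValueError(f"unknown genotyping rule {config.genotyping_rule!r}")


# ---------------------------------------------------------------------------
# Genotypes (gene dropping)
# ---------------------------------------------------------------------------


def _snp_map(config: SimulationConfig) -> pd.DataFrame:
    m = config.n_snp
    chrom = (np.arange(m) * config.n_chromosomes) // m + 1
    pos = np.zeros(m, dtype=np.int64)
    for c in range(1, config.n_chromosomes + 1):
        sel = chrom == c
        pos[sel] = (np.arange(sel.sum()) + 1) * 10_000
    return pd.DataFrame(
        {"snp_id": [f"snp{i + 1}" for i in range(m)], "chrom": chrom, "pos": pos}
    )


def _gamete(hap: np.ndarray, choice: np.ndarray) -> np.ndarray:
    """Transmitted gamete given per-locus haplotype choice (0/1)."""
    return np.where(choice == 0, hap[:, 0], hap[:, 1])


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> GenotypePanel:
    """Gene dropping over the full pedigree.

    Returns a panel covering *all* pedigree animals (the orchestrator
    subsets it to the genotyped animals); phased haplotypes are kept, and
    the per-locus parental-gamete choices are stored when
    ``track_inheritance`` is set, so tests can replay Mendelian transmission.
    """
    if not (0.0 < config.maf_low <= config.maf_high <= 0.5):
        raise ValueError("founder MAF bounds must lie in (0, 0.5]")
    rng = _rng(config, 3)
    n, m = len(pedigree), config.n_snp
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    hap = np.zeros((n, m, 2), dtype=np.int8)
    trans = (
        np.zeros((n, m, 2), dtype=np.int8) if config.track_inheritance else None
    )
    snp_map = _snp_map(config)
    chrom = snp_map["chrom"].to_numpy()
    sire, dam = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        for slot, parent in enumerate((sire[i], dam[i])):
            if parent < 0:
                hap[i, :, slot] = rng.random(m) < p
                continue
            if config.linkage == "unlinked":
                choice = (rng.random(m) < 0.5).astype(np.int8)
            elif config.linkage == "block":
                choice = np.empty(m, dtype=np.int8)
                for c in np.unique(chrom):
                    sel = np.flatnonzero(chrom == c)
                    phase = int(rng.integers(2))
                    cut = int(rng.integers(len(sel) + 1))
                    choice[sel[:cut]] = phase
                    choice[sel[cut:]] = 1 - phase
            else:
                raise ValueError(f"unknown linkage mode {config.linkage!r}")
            hap[i, :, slot] = _gamete(hap[parent], choice)
            if trans is not None:
                trans[i, :, slot] = choice
    dosages = hap.sum(axis=2).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[miss] = -1
    return GenotypePanel(
        animal_ids=pedigree.ids,
        dosages=dosages,
        snp_map=snp_map,
        founder_freq=p,
        haplotypes=hap,
        transmissions=trans,
    )


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------


def select_phenotyped(pedigree: Pedigree, config: SimulationConfig) -> np.ndarray:
    df = pedigree.frame
    if config.phenotyping_rule == "females" and "sex" in df.columns:
        return df.loc[df["sex"] == "F", "animal"].to_numpy()
    if config.phenotyping_rule == "nonfounders":
        return df.loc[(df["sire"] != 0) | (df["dam"] != 0), "animal"].to_numpy()
    if config.phenotyping_rule in ("all", "females"):
        # external pedigrees without a sex column phenotype everyone
        return df["animal"].to_numpy()
    raise ValueError(f"unknown phenotyping rule {config.phenotyping_rule!r}")


def simulate_effects(
    pedigree: Pedigree,
    config: SimulationConfig,
    dosages: np.ndarray | None = None,
    founder_freq: np.ndarray | None = None,
) -> TrueEffects:
    """Draw generating effects.

    Additive coefficient vectors are jointly MVN(0, V_g (x) A) via a
    factorization of the pedigree A (truth precedes genotyping, so A rather
    than H).  If QTL are specified, each QTL adds ``w_lo beta_o`` (centered
    dosage times its coefficient vector) to the animal's additive vector and
    the polygenic covariance is reduced so the total stays V_g.
    """
    rng = _rng(config, 4)
    k = config.order
    n = len(pedigree)
    V_poly = config.V_g.copy()
    qtl: list[tuple[int, np.ndarray]] = []
    if config.qtl_spec:
        if dosages is None or founder_freq is None:
            raise ValueError("qtl_spec requires dosages and founder frequencies")
        C_q = np.zeros((k, k))
        for snp_idx, beta in config.qtl_spec:
            beta = np.asarray(beta, dtype=float)
            p_o = founder_freq[snp_idx]
            C_q += 2.0 * p_o * (1.0 - p_o) * np.outer(beta, beta)
            qtl.append((int(snp_idx), beta))
        V_poly = config.V_g - C_q
        if np.linalg.eigvalsh(V_poly).min() < -1e-10:
            raise ValueError(
                "QTL effects imply more additive covariance than V_g; "
                "reduce the injected effects"
            )
    L_A = np.linalg.cholesky(tabular_A(pedigree) + 1e-10 * np.eye(n))
    U = L_A @ rng.standard_normal((n, k)) @ _psd_factor(V_poly).T
    for snp_idx, beta in qtl:
        w = dosages[:, snp_idx].astype(float) - 2.0 * founder_freq[snp_idx]
        U += np.outer(w, beta)
    phen_ids = select_phenotyped(pedigree, config)
    P = rng.standard_normal((len(phen_ids), k)) @ _psd_factor(config.V_p).T
    hy = rng.normal(0.0, config.herd_year_sd, size=config.n_herd_years)
    bm = rng.normal(0.0, config.birth_month_sd, size=12)
    return TrueEffects(
        additive_coeffs=U,
        pe_ids=phen_ids,
        pe_coeffs=P,
        herd_year_effects=hy,
        birth_month_effects=bm,
        qtl_allele_effects=qtl,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _age_schedule(
    rng: np.random.Generator, config: SimulationConfig, comply: bool
) -> np.ndarray:
    grid = np.asarray(config.age_grid)
    lo, hi = config.records_per_animal_range
    n_rec = int(rng.integers(lo, hi + 1))
    n_rec = min(n_rec, len(grid))
    if not comply:
        return np.sort(rng.choice(grid, size=n_rec, replace=False))
    # force the data-edit rules: >=3 records, one before 10 and one after 30
    n_rec = max(n_rec, 3)
    early = grid[grid < 10]
    late = grid[grid > 30]
    if len(early) == 0 or len(late) == 0:
        return np.sort(rng.choice(grid, size=n_rec, replace=False))
    picks = {int(rng.choice(early)), int(rng.choice(late))}
    rest = np.setdiff1d(grid, np.array(sorted(picks)))
    extra = rng.choice(rest, size=max(0, n_rec - len(picks)), replace=False)
    return np.sort(np.concatenate([np.array(sorted(picks)), extra]))


def simulate_phenotypes(
    pedigree: Pedigree, effects: TrueEffects, config: SimulationConfig
) -> PhenotypeTable:
    """Records y = HY + M + fixed curve + genetic + permanent env + noise."""
    rng = _rng(config, 5)
    comps = config.true_components()
    k = config.order
    fixed_order = len(config.fixed_curve) - 1
    basis = LegendreBasis(order=max(fixed_order, k - 1))
    ped_index = {int(a): i for i, a in enumerate(pedigree.ids)}
    rows = []
    for j, animal in enumerate(effects.pe_ids):
        comply = rng.random() < config.edit_compliance
        ages = _age_schedule(rng, config, comply)
        if len(ages) == 0:
            raise ValueError(f"empty age schedule for animal {animal}")
        hy_code = int(rng.integers(config.n_herd_years))
        bm_code = int(rng.integers(1, 13))
        phi_fix = basis.design(ages, order=fixed_order)
        phi_rand = basis.design(ages, order=k - 1)
        u = effects.additive_coeffs[ped_index[int(animal)]]
        pe = effects.pe_coeffs[j]
        noise = rng.normal(0.0, np.sqrt(comps.residual_variance(ages)))
        vals = (
            effects.herd_year_effects[hy_code]
            + effects.birth_month_effects[bm_code - 1]
            + phi_fix @ config.fixed_curve
            + phi_rand @ u
            + phi_rand @ pe
            + noise
        )
        for age, v in zip(ages, vals):
            rows.append((int(animal), int(age), float(v), hy_code, bm_code))
    frame = pd.DataFrame(
        rows, columns=["animal", "age_months", "value", "herd_year", "birth_month"]
    )
    return PhenotypeTable(frame)


# ---------------------------------------------------------------------------
# Orchestration and writers
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    pedigree: Pedigree
    panel: GenotypePanel  # genotyped subset
    full_panel: GenotypePanel  # all pedigree animals (truth)
    effects: TrueEffects
    phenotypes: PhenotypeTable
    components: CovarianceComponents


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset: pedigree, genotypes, truth, phenotypes."""
    pedigree = simulate_pedigree(config)
    full_panel = simulate_genotypes(pedigree, config)
    effects = simulate_effects(
        pedigree,
        config,
        dosages=full_panel.haplotypes.sum(axis=2).astype(float),
        founder_freq=full_panel.founder_freq,
    )
    phenotypes = simulate_phenotypes(pedigree, effects, config)
    genotyped = select_genotyped(pedigree, config)
    panel = full_panel.subset_animals(genotyped)
    return SimulatedDataset(
        config=config,
        pedigree=pedigree,
        panel=panel,
        full_panel=full_panel,
        effects=effects,
        phenotypes=phenotypes,
        components=config.true_components(),
    )


def write_dataset(dataset: SimulatedDataset, out_dir, plink: bool = True) -> dict:
    """Write pedigree/phenotype CSVs, genotype TSV (+ PLINK), and truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.pedigree.to_csv(out / "pedigree.csv")
    dataset.phenotypes.to_csv(out / "phenotypes.csv")
    dataset.panel.to_dosage_tsv(out / "genotypes.tsv", out / "map.tsv")
    if plink:
        dataset.panel.to_plink(out / "genotypes")
    dataset.components.to_json(out / "true_components.json")
    truth = pd.DataFrame(
        dataset.effects.additive_coeffs,
        columns=[f"u{k}" for k in range(dataset.config.order)],
    )
    truth.insert(0, "animal", dataset.pedigree.ids)
    truth.to_csv(out / "true_additive.tsv", sep="\t", index=False)
    qtl = pd.DataFrame(
        [
            (i, *beta)
            for i, beta in dataset.effects.qtl_allele_effects
        ],
        columns=["snp_index"] + [f"beta{k}" for k in range(dataset.config.order)],
    )
    qtl.to_csv(out / "true_qtl.tsv", sep="\t", index=False)
    meta = {
        "seed": dataset.config.seed,
        "n_animals": len(dataset.pedigree),
        "n_genotyped": dataset.panel.n_animals,
        "n_records": len(dataset.phenotypes),
        "n_snp": dataset.panel.n_snp,
    }
    (out / "simulation_manifest.json").write_text(json.dumps(meta, indent=2))
    return meta
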