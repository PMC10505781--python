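"""End-to-end pipeline orchestration and configuration.

A :class:`PipelineConfig` (YAML-round-trippable) carries every tunable of
the analysis; the defaults are the standard settings of the method: MAF
floor 0.05, call-rate floor 0.90, 5-SD outlier edit, >= 3 records with the
10/30-month age-window rule, blending alpha 0.05, fixed regression order 4,
random regression order 2, PCG tolerance 1e-14, and the six ages
10..60 months for the GWAS scan.

:func:`run_pipeline` executes preprocess -> kinship -> variance components
(Gibbs or fixed) -> MME solve -> GWAS, writing per-age TSVs, a summary, a
filter report and a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data import CovarianceComponents, GenotypePanel, Pedigree, PhenotypeTable
from .estimators import GibbsVarianceComponents, LongitudinalGWAS, SingleStepRRM
from .preprocess import filter_phenotypes, filter_snps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    # input files
    pedigree: str = "pedigree.csv"
    phenotypes: str = "phenotypes.csv"
    genotypes: str = "genotypes.tsv"  # dosage TSV (or PLINK prefix)
    snp_map: str = "map.tsv"
    genotype_format: str = "dosage"  # dosage | plink
    # preprocessing
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    sd_mult: float = 5.0
    min_records: int = 3
    early_age: int = 10
    late_age: int = 30
    # kinship
    alpha: float = 0.05
    tune: bool = True
    tune_order: str = "tune_then_blend"
    centering: str = "observed"
    # model
    fixed_order: int = 4
    random_order: int = 2
    n_residual_classes: int = 6
    tol: float = 1.0e-14
    max_iter: int = 20_000
    # variance components
    variance_mode: str = "gibbs"  # gibbs | fixed
    components_file: str | None = None  # JSON, required for variance_mode=fixed
    gibbs_iter: int = 20_000
    gibbs_burn_in: int = 5_000
    gibbs_thinning: int = 10
    # GWAS
    ages: list[int] = field(default_factory=lambda: [10, 20, 30, 40, 50, 60])
    gwas_alpha: float = 0.05
    plot: bool = False
    # misc
    seed: int = 0
    out_dir: str = "ssrrm_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    try:
        pedigree = Pedigree.from_csv(config.pedigree)
    except ValueError as exc:
        raise RuntimeError(f"[preprocessing] {exc}") from exc
    phenotypes = PhenotypeTable.from_csv(config.phenotypes)
    if config.genotype_format == "plink":
        panel = GenotypePanel.from_plink(config.genotypes)
    else:
        panel = GenotypePanel.from_dosage_tsv(config.genotypes, config.snp_map)
    return pedigree, phenotypes, panel


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest dictionary."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    manifest: dict = {
        "ssrrm_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": {},
    }
    try:
        pedigree, phenotypes, panel = _load_inputs(config)
        manifest["stages"]["load"] = {
            "n_pedigree": len(pedigree),
            "n_records": len(phenotypes),
            "n_genotyped": panel.n_animals,
            "n_snp": panel.n_snp,
        }

        stage = "preprocess"
        panel, snp_report = filter_snps(panel, config.maf_min, config.call_rate_min)
        phenotypes, pheno_report = filter_phenotypes(
            phenotypes,
            sd_mult=config.sd_mult,
            min_records=config.min_records,
            early_age=config.early_age,
            late_age=config.late_age,
        )
        report = {**snp_report.counts, **pheno_report.counts}
        import pandas as pd

        pd.DataFrame(sorted(report.items()), columns=["rule", "count"]).to_csv(
            out / "filter_report.tsv", sep="\t", index=False
        )
        manifest["stages"]["preprocess"] = report

        stage = "variance_components"
        if config.variance_mode == "fixed":
            if not config.components_file:
                raise ValueError("variance_mode=fixed needs components_file")
            comps = CovarianceComponents.from_json(config.components_file)
        elif config.variance_mode == "gibbs":
            vc = GibbsVarianceComponents(
                n_iter=config.gibbs_iter,
                burn_in=config.gibbs_burn_in,
                thinning=config.gibbs_thinning,
                seed=config.seed,
                order=config.random_order + 1,
                fixed_order=config.fixed_order,
                n_residual_classes=config.n_residual_classes,
            ).fit(phenotypes, pedigree=pedigree)
            vc.chain_.to_tsv(out / "gibbs_chain.tsv")
            comps = vc.components_
            comps.to_json(out / "components_posterior_mean.json")
        else:
            raise ValueError(f"unknown variance_mode {config.variance_mode!r}")
        manifest["stages"]["variance_components"] = {
            "mode": config.variance_mode,
            "V_g_diag": np.diag(comps.V_g).tolist(),
            "V_p_diag": np.diag(comps.V_p).tolist(),
            "sigma_e2": comps.sigma_e2.tolist(),
        }

        stage = "solve"
        model = SingleStepRRM(
            alpha=config.alpha,
            tune=config.tune,
            tune_order=config.tune_order,
            centering=config.centering,
            fixed_order=config.fixed_order,
            order=config.random_order + 1,
            tol=config.tol,
            max_iter=config.max_iter,
        ).fit(phenotypes, pedigree=pedigree, genotypes=panel, components=comps)
        _dump_solution(model, out / "solutions.tsv")
        manifest["stages"]["solve"] = {
            "pcg_iterations": model.n_iter_,
            "final_criterion": model.solution_.convergence_history[-1],
        }

        stage = "gwas"
        scan = LongitudinalGWAS(ages=config.ages, alpha=config.gwas_alpha).fit(model)
        scan.results_.write(out)
        if config.plot:
            _plots(scan, out)
        manifest["stages"]["gwas"] = {
            "m_eff": scan.m_eff_,
            "threshold_neglog10": scan.threshold_neglog10_,
            "n_persistent": int((scan.results_.summary["class"] == "persistent").sum()),
            "n_transient": int((scan.results_.summary["class"] == "transient").sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"[{stage}] {exc}") from exc

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1fs", manifest["elapsed_seconds"])
    return manifest


def _dump_solution(model: SingleStepRRM, path) -> None:
    import pandas as pd

    sol = model.solution_
    k = sol.a_hat.shape[1]
    add = pd.DataFrame(sol.a_hat, columns=[f"a{j}" for j in range(k)])
    add.insert(0, "animal", sol.ped_ids)
    pe = pd.DataFrame(sol.pe_hat, columns=[f"pe{j}" for j in range(k)])
    pe.insert(0, "animal", sol.phen_ids)
    merged = add.merge(pe, on="animal", how="left")
    merged.to_csv(path, sep="\t", index=False)


def _plots(scan: LongitudinalGWAS, out: Path) -> None:
    import matplotlib.pyplot as plt

    from .plots import manhattan

    for age in scan.results_.ages:
        ax = manhattan(
            scan.results_.at_age(age),
            threshold=scan.threshold_neglog10_,
            title=f"{age} months",
        )
        ax.figure.tight_layout()
        ax.figure.savefig(out / f"manhattan_age{age:02d}.png", dpi=120)
        plt.close(ax.figure)
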