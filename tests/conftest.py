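"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from ssrrm.basis import LegendreBasis
from ssrrm.estimators import SingleStepRRM
from ssrrm.preprocess import filter_phenotypes, filter_snps
from ssrrm.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """~160-animal pedigree with 80 genotyped animals and 300 SNPs."""
    cfg = SimulationConfig(
        n_founders=40,
        n_generations=3,
        offspring_per_mating=2,
        n_snp=300,
        n_chromosomes=3,
        records_per_animal_range=(4, 10),
        seed=1,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_filtered(small_dataset):
    panel, _ = filter_snps(small_dataset.panel)
    phen, _ = filter_phenotypes(small_dataset.phenotypes)
    return panel, phen


@pytest.fixture(scope="session")
def small_model(small_dataset, small_filtered):
    """Fitted single-step RRM on the small dataset with true components."""
    panel, phen = small_filtered
    return SingleStepRRM().fit(
        phen,
        pedigree=small_dataset.pedigree,
        genotypes=panel,
        components=small_dataset.components,
    )


@pytest.fixture(scope="session")
def basis():
    return LegendreBasis(order=4)


GIBBS_TRUTH = {
    "V_g": np.diag([9.0, 1.0, 0.2]),
    "V_p": np.diag([4.0, 0.5, 0.1]),
    "sigma_e2": np.array([6.0, 5.0, 4.0, 3.0, 3.0, 3.0]),
}


@pytest.fixture(scope="session")
def gibbs_truth():
    """Generating variance components of the recovery scenario."""
    return GIBBS_TRUTH


@pytest.fixture(scope="session")
def gibbs_recovery_runs(basis):
    """Five reduced-chain Gibbs runs at ~1,450 phenotyped animals each.

    Shared between the variance-component calibration tests and the
    parameter-recovery acceptance test (the chains are the expensive part).
    Chain length is reduced relative to the 20,000-iteration default to fit
    the test budget; the posterior means are what the tests consume.
    """
    from ssrrm.varcomp import gibbs_rrm

    runs = []
    for seed in range(5):
        cfg = SimulationConfig(
            n_founders=500,
            n_generations=5,
            offspring_per_mating=2,
            n_snp=10,
            n_chromosomes=1,
            V_g=GIBBS_TRUTH["V_g"],
            V_p=GIBBS_TRUTH["V_p"],
            residual_variances=GIBBS_TRUTH["sigma_e2"],
            records_per_animal_range=(5, 30),
            seed=seed,
        )
        ds = simulate_dataset(cfg)
        phen, _ = filter_phenotypes(ds.phenotypes)
        chain = gibbs_rrm(
            phen, ds.pedigree, basis, n_iter=800, burn_in=300, thinning=5, seed=seed
        )
        runs.append((chain, ds.components))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
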