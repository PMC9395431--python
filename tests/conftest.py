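import pytest

import metaboqtl as mq


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample cohort with one planted effect and adduct satellites."""
    cfg = mq.SimulationConfig(
        n_samples=300,
        n_variants=30,
        n_primary_metabolites=6,
        maf_spectrum=[(0.3, 1.0)],
        effects=[mq.PlantedEffect(3, 1, 0.5)],
        adduct_profile={
            0: [
                mq.AdductSpec(21.98194, 0.3, 0.02, "[M+Na]+"),
                mq.AdductSpec(37.95588, 0.1, 0.02, "[M+K]+"),
            ],
            2: [mq.AdductSpec(-18.01056, 0.5, 0.02, "[M+H-H2O]+")],
        },
        missing_rate=0.02,
        seed=11,
    )
    genotypes = mq.simulate_genotypes(cfg)
    covariates = mq.simulate_covariates(cfg)
    table, truth = mq.simulate_metabolome(genotypes, covariates, cfg)
    return cfg, genotypes, covariates, table, truth
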