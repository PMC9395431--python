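"""Synthetic-cohort generator: determinism, sampling oracles, round-trips."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

import metaboqtl as mq
from metaboqtl.simulate import (
    read_feature_table,
    read_mgf,
    read_vcf,
    write_feature_table,
    write_mgf,
    write_vcf,
)


def _cfg(**kw):
    base = dict(n_samples=200, n_variants=10, n_primary_metabolites=3, seed=5)
    base.update(kw)
    return mq.SimulationConfig(**base)


class TestGenotypes:
    def test_seed_determinism(self):
        a = mq.simulate_genotypes(_cfg())
        b = mq.simulate_genotypes(_cfg())
        assert_frame_equal(a.dosages, b.dosages)
        assert_frame_equal(a.variants, b.variants)

    def test_maf_within_binomial_error(self):
        """Empirical MAF at f=0.5, n=2000 stays within 3 binomial SDs."""
        g = mq.simulate_genotypes(
            _cfg(n_samples=2000, n_variants=50, maf_spectrum=[(0.5, 1.0)])
        )
        freq = g.dosages.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        sd = np.sqrt(0.5 * 0.5 / (2 * 2000))
        assert (np.abs(freq - 0.5) < 3 * sd).mean() > 0.95
        assert np.all(maf <= 0.5)

    def test_zero_frequency_is_monomorphic(self):
        g = mq.simulate_genotypes(_cfg(maf_spectrum=[(0.0, 1.0)]))
        assert (g.dosages.to_numpy() == 0).all()
        assert (g.minor_allele_counts() == 0).all()

    def test_dosage_domain(self):
        g = mq.simulate_genotypes(_cfg())
        assert set(np.unique(g.dosages.to_numpy())) <= {0.0, 1.0, 2.0}

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_samples=0),
            dict(n_variants=-1),
            dict(maf_spectrum=[(0.2, 0.5)]),
            dict(effects=[mq.PlantedEffect(99, 0, 1.0)]),
        ],
    )
    def test_invalid_config_raises(self, bad):
        with pytest.raises(ValueError):
            mq.simulate_genotypes(_cfg(**bad))


class TestMetabolome:
    def test_seed_determinism(self):
        cfg = _cfg(adduct_profile={0: [mq.AdductSpec(21.98194, 0.3)]})
        g = mq.simulate_genotypes(cfg)
        cov = mq.simulate_covariates(cfg)
        t1, _ = mq.simulate_metabolome(g, cov, cfg)
        t2, _ = mq.simulate_metabolome(g, cov, cfg)
        assert_frame_equal(t1.intensities, t2.intensities)

    def test_feature_conservation_and_truth_partition(self, small_cohort):
        cfg, _, _, table, truth = small_cohort
        n_sat = sum(len(v) for v in cfg.adduct_profile.values())
        assert table.intensities.shape[1] == cfg.n_primary_metabolites + n_sat
        ledger_feats = truth.all_features()
        assert sorted(ledger_feats) == sorted(table.features.index)
        assert len(ledger_feats) == len(set(ledger_feats))

    def test_degenerate_noise_gives_constant_columns(self):
        cfg = _cfg(
            cv_noise_sd=0.0,
            drift_slope=0.0,
            missing_rate=0.0,
            covariate_betas={},
        )
        g = mq.simulate_genotypes(cfg)
        cov = mq.simulate_covariates(cfg)
        table, _ = mq.simulate_metabolome(g, cov, cfg)
        bio = table.biological()
        assert np.allclose(bio.std(axis=0), 0.0)

    def test_satellite_tracks_primary(self):
        """Low-noise satellite at 30% abundance is rank-correlated > 0.95."""
        cfg = _cfg(
            n_samples=300,
            adduct_profile={0: [mq.AdductSpec(21.98194, 0.3, 0.01)]},
            missing_rate=0.0,
        )
        g = mq.simulate_genotypes(cfg)
        cov = mq.simulate_covariates(cfg)
        table, truth = mq.simulate_metabolome(g, cov, cfg)
        bio = table.biological()
        sat, _ = truth.satellites["met000_MH"][0]
        rho = stats.spearmanr(bio["met000_MH"], bio[sat]).statistic
        assert rho > 0.95

    def test_satellite_geometry(self, small_cohort):
        cfg, _, _, table, truth = small_cohort
        for primary, sats in truth.satellites.items():
            for sid, _ in sats:
                drt = abs(table.features.loc[sid, "rt"] - table.features.loc[primary, "rt"])
                assert drt <= cfg.rt_jitter_min + 1e-12

    def test_qc_rows_interleaved_and_complete(self, small_cohort):
        cfg, _, _, table, _ = small_cohort
        assert table.qc_mask.sum() >= cfg.n_samples // cfg.qc_interval
        assert not table.intensities.loc[table.qc_mask].isna().any().any()

    def test_misaligned_samples_raise(self):
        cfg = _cfg()
        g = mq.simulate_genotypes(cfg)
        cov = mq.simulate_covariates(cfg).iloc[:-5]
        with pytest.raises(ValueError):
            mq.simulate_metabolome(g, cov, cfg)


class TestMsms:
    def _spectra(self, **kw):
        cfg = _cfg(n_primary_metabolites=2, missing_rate=0.0, **kw)
        g = mq.simulate_genotypes(cfg)
        cov = mq.simulate_covariates(cfg)
        _, truth = mq.simulate_metabolome(g, cov, cfg)
        return mq.simulate_msms(truth, cfg), truth, cfg

    def test_every_primary_gets_scans(self):
        spectra, truth, cfg = self._spectra()
        per_feature = {pid: 0 for pid in truth.satellites}
        for s in spectra:
            per_feature[s.feature_id] += 1
        assert all(v == cfg.n_scans_per_primary for v in per_feature.values())

    def test_fully_shared_fragments_score_one(self):
        spectra, _, _ = self._spectra(related_pairs=[(0, 1, 1.0)], noise_peak_fraction=0.0)
        a = mq.consensus_spectrum([s for s in spectra if s.feature_id == "met000_MH"])
        b = mq.consensus_spectrum([s for s in spectra if s.feature_id == "met001_MH"])
        assert mq.cosine_score(a, b) > 0.99

    def test_disjoint_fragments_score_zero(self):
        spectra, _, _ = self._spectra(noise_peak_fraction=0.0)
        a = mq.consensus_spectrum([s for s in spectra if s.feature_id == "met000_MH"])
        b = mq.consensus_spectrum([s for s in spectra if s.feature_id == "met001_MH"])
        assert mq.cosine_score(a, b) == 0.0

    def test_noise_peak_injected_into_raw_scans(self):
        spectra, _, _ = self._spectra(noise_peak_fraction=1.0)
        assert all(np.any(np.abs(s.mz - 173.46) / 173.46 * 1e6 <= 30) for s in spectra)

    def test_determinism(self):
        s1, _, _ = self._spectra()
        s2, _, _ = self._spectra()
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)


class TestRoundTrips:
    def test_vcf(self, small_cohort, tmp_path):
        _, genotypes, *_ = small_cohort
        path = tmp_path / "g.vcf"
        write_vcf(genotypes, path)
        back = read_vcf(path)
        assert_frame_equal(back.dosages, genotypes.dosages)
        assert list(back.variants["pos"]) == list(genotypes.variants["pos"])

    def test_mgf(self, small_cohort, tmp_path):
        cfg, *_, truth = small_cohort
        spectra = mq.simulate_msms(truth, cfg)
        path = tmp_path / "scans.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == len(spectra)
        np.testing.assert_allclose(back[0].mz, spectra[0].mz, rtol=1e-9)
        assert back[0].feature_id == spectra[0].feature_id

    def test_feature_table_tsv(self, small_cohort, tmp_path):
        _, _, _, table, _ = small_cohort
        write_feature_table(table, tmp_path)
        back = read_feature_table(tmp_path)
        assert_frame_equal(back.intensities, table.intensities)
        assert list(back.features["mz"]) == pytest.approx(list(table.features["mz"]))
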