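"""Drift correction, CV/missingness filtering and phenotype normalization."""

import numpy as np
import pandas as pd
import pytest

import metaboqtl as mq
from metaboqtl.containers import FeatureTable


def _table(intensities, is_qc, orders, mz=None, rt=None, identity=None, batch=None):
    intensities = pd.DataFrame(intensities)
    intensities.index = [f"s{i}" for i in range(len(intensities))]
    intensities.columns = [f"f{j}" for j in range(intensities.shape[1])]
    features = pd.DataFrame(
        {
            "mz": mz or [100.0 + j for j in range(intensities.shape[1])],
            "rt": rt or [1.0] * intensities.shape[1],
            "identity": identity or [""] * intensities.shape[1],
        },
        index=intensities.columns,
    )
    samples = pd.DataFrame(
        {
            "is_qc": is_qc,
            "injection_order": orders,
            "batch": batch or ["0"] * len(is_qc),
        },
        index=intensities.index,
    )
    return FeatureTable(intensities, features, samples)


class TestDriftCorrect:
    def test_nearest_qc_scaling_by_hand(self):
        """QC anchors at injections 0/20/40 with reference 100: a sample at
        injection 5 scales by 100/100, at injection 18 by 100/200."""
        t = _table(
            [[100.0], [150.0], [150.0], [200.0], [100.0]],
            is_qc=[True, False, False, True, True],
            orders=[0, 5, 18, 20, 40],
        )
        out = mq.drift_correct(t)
        assert out.intensities.loc["s1", "f0"] == pytest.approx(150.0)
        assert out.intensities.loc["s2", "f0"] == pytest.approx(75.0)
        # QC rows retained unchanged
        assert out.intensities.loc["s0", "f0"] == 100.0

    def test_tie_broken_toward_earlier_injection(self):
        t = _table(
            [[100.0], [150.0], [200.0]],
            is_qc=[True, False, True],
            orders=[0, 10, 20],
        )
        out = mq.drift_correct(t)
        # distance 10 to both anchors; earlier one (value 100) wins
        ref = np.median([100.0, 200.0])
        assert out.intensities.loc["s1", "f0"] == pytest.approx(150.0 * ref / 100.0)

    def test_unit_factor_identity(self):
        """All QC intensities equal to the reference leave the table unchanged."""
        t = _table(
            [[100.0], [137.0], [100.0]],
            is_qc=[True, False, True],
            orders=[0, 1, 2],
        )
        out = mq.drift_correct(t)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)

    def test_single_qc_anchor_uniform_factor(self):
        t = _table(
            [[80.0], [10.0], [20.0]],
            is_qc=[True, False, False],
            orders=[0, 1, 2],
        )
        out = mq.drift_correct(t)
        # one anchor: reference is the anchor itself, so factor is 1 everywhere
        pd.testing.assert_frame_equal(out.intensities, t.intensities)

    def test_all_missing_qc_feature_left_unscaled_and_flagged(self):
        t = _table(
            [[np.nan, 100.0], [50.0, 150.0], [np.nan, 200.0]],
            is_qc=[True, False, True],
            orders=[0, 1, 2],
        )
        out = mq.drift_correct(t)
        assert out.intensities.loc["s1", "f0"] == 50.0
        assert bool(out.features.loc["f0", "drift_uncorrected"])
        assert not bool(out.features.loc["f1", "drift_uncorrected"])

    def test_missing_cells_never_increase(self, small_cohort):
        _, _, _, table, _ = small_cohort
        out = mq.drift_correct(table)
        assert out.intensities.isna().sum().sum() <= table.intensities.isna().sum().sum()

    def test_no_qc_raises(self):
        t = _table([[1.0], [2.0]], is_qc=[False, False], orders=[0, 1])
        with pytest.raises(ValueError):
            mq.drift_correct(t)


class TestQcFilter:
    def _cv_table(self, cvs, n_bio=10, missing=None):
        # two QC rows at m(1 +/- d) give CV = sqrt(2) * d exactly
        m = 1000.0
        qc1 = [m * (1 - cv / np.sqrt(2)) for cv in cvs]
        qc2 = [m * (1 + cv / np.sqrt(2)) for cv in cvs]
        bio = [[m] * len(cvs) for _ in range(n_bio)]
        rows = [qc1] + bio + [qc2]
        if missing is not None:
            for j, frac in enumerate(missing):
                k = int(round(frac * n_bio))
                for i in range(1, 1 + k):
                    rows[i][j] = np.nan
        return _table(
            rows,
            is_qc=[True] + [False] * n_bio + [True],
            orders=list(range(n_bio + 2)),
        )

    def test_cv_filter_keeps_strictly_below_threshold(self):
        """CVs {0.10, 0.25, 0.31, 0.50, 0.29} keep exactly the three <= 0.30."""
        t = self._cv_table([0.10, 0.25, 0.31, 0.50, 0.29])
        kept, log = mq.qc_filter(t)
        assert list(kept.intensities.columns) == ["f0", "f1", "f4"]
        assert set(log["feature"]) == {"f2", "f3"}
        assert (log["reason"] == "cv").all()

    def test_missing_boundary_is_strict(self):
        t = self._cv_table([0.1, 0.1, 0.1], missing=[0.30, 0.40, 0.0])
        kept, log = mq.qc_filter(t)
        # missing in exactly 30% of study samples is retained
        assert "f0" in kept.intensities.columns
        assert "f1" not in kept.intensities.columns

    def test_clean_table_unchanged(self):
        t = self._cv_table([0.05, 0.05])
        kept, log = mq.qc_filter(t)
        assert kept.intensities.shape == t.intensities.shape
        assert log.empty

    def test_idempotent(self, small_cohort):
        _, _, _, table, _ = small_cohort
        once, _ = mq.qc_filter(mq.drift_correct(table))
        twice, log2 = mq.qc_filter(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)
        assert log2.empty

    def test_no_qc_samples_warns_and_skips_cv(self):
        t = _table([[1.0], [2.0]], is_qc=[False, False], orders=[0, 1])
        with pytest.warns(UserWarning):
            kept, _ = mq.qc_filter(t)
        assert kept.intensities.shape[1] == 1


class TestNormalize:
    def _cov(self, n, constant=False):
        rng = np.random.default_rng(3)
        idx = [f"s{i + 1}" for i in range(n)]
        if constant:
            return pd.DataFrame({"age": 50.0, "sex": 0}, index=idx)
        return pd.DataFrame(
            {"age": rng.normal(50, 8, n), "sex": rng.integers(0, 2, n)}, index=idx
        )

    def _raw(self, n, values=None):
        rng = np.random.default_rng(4)
        vals = values if values is not None else np.exp(rng.normal(10, 1, n))
        rows = [[1000.0]] + [[v] for v in vals]
        return _table(rows, is_qc=[True] + [False] * n, orders=list(range(n + 1)))

    def test_output_is_standard_normal_scores(self):
        t = self._raw(1000)
        out = mq.normalize_phenotypes(t, self._cov(1000))
        col = out.values.iloc[:, 0]
        assert abs(col.mean()) < 1e-10
        assert 0.95 < col.std() < 1.05

    def test_monotone_in_residuals(self):
        """With constant covariates the output ordering equals the input ordering."""
        t = self._raw(50)
        out = mq.normalize_phenotypes(t, self._cov(50, constant=True))
        raw = t.biological().iloc[:, 0].to_numpy()
        np.testing.assert_array_equal(
            np.argsort(out.values.iloc[:, 0].to_numpy()), np.argsort(raw)
        )

    def test_scale_invariance(self):
        t = self._raw(200)
        cov = self._cov(200)
        a = mq.normalize_phenotypes(t, cov)
        t2 = t.copy()
        t2.intensities *= 537.2
        b = mq.normalize_phenotypes(t2, cov)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_planted_covariate_effect_removed(self):
        """A sex effect of 1 SD planted by the simulator leaves residual
        correlation with sex below 0.05."""
        cfg = mq.SimulationConfig(
            n_samples=500,
            n_variants=2,
            n_primary_metabolites=2,
            covariate_betas={"sex": 1.0},
            missing_rate=0.0,
            seed=9,
        )
        g = mq.simulate_genotypes(cfg)
        cov = mq.simulate_covariates(cfg)
        table, _ = mq.simulate_metabolome(g, cov, cfg)
        out = mq.normalize_phenotypes(table, cov)
        for col in out.values.columns:
            r = np.corrcoef(out.values[col], cov.loc[out.values.index, "sex"])[0, 1]
            assert abs(r) < 0.05

    def test_constant_metabolite_dropped(self):
        t = self._raw(30, values=np.full(30, 123.0))
        with pytest.warns(UserWarning):
            out = mq.normalize_phenotypes(t, self._cov(30))
        assert out.values.shape[1] == 0

    def test_zeros_treated_as_missing(self):
        vals = np.exp(np.random.default_rng(6).normal(10, 1, 40))
        vals[5] = 0.0
        t = self._raw(40, values=vals)
        out = mq.normalize_phenotypes(t, self._cov(40))
        assert np.isnan(out.values.iloc[5, 0])
        assert out.values.iloc[:, 0].notna().sum() == 39


class TestInverseNormal:
    def test_blom_scores_by_hand(self):
        # n=3, ranks 1..3 -> Phi^-1((r - 3/8) / 3.25)
        from scipy.stats import norm

        got = mq.inverse_normal(np.array([10.0, 30.0, 20.0]))
        want = norm.ppf((np.array([1, 3, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(got, want)

    def test_ties_get_average_ranks(self):
        got = mq.inverse_normal(np.array([1.0, 1.0, 2.0]))
        assert got[0] == got[1] < got[2]

    def test_nan_preserved(self):
        got = mq.inverse_normal(np.array([1.0, np.nan, 2.0]))
        assert np.isnan(got[1]) and np.isfinite(got[0])
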