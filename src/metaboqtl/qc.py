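"""Pooled-QC drift correction, feature filtering and phenotype normalization.

The phenotype chain mirrors standard metabolomics GWAS practice: natural-log
transform, z-scaling, ordinary-least-squares residualization on age, sex,
batch and ancestry PCs 1-10, then a rank-based inverse normal transform of
the residuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable, NormalizedPhenotypes

__all__ = [
    "drift_correct",
    "qc_filter",
    "inverse_normal",
    "normalize_phenotypes",
]


def drift_correct(table: FeatureTable) -> FeatureTable:
    """Scale each study sample to the nearest pooled-QC injection.

    For every non-QC sample and feature, the intensity is multiplied by
    ``reference / nearest-QC value``, where the reference is the per-feature
    median over all pooled-QC samples and "nearest" means nearest by
    injection order within the batch (ties broken toward the earlier
    injection). QC rows are retained unchanged. Features whose QC values
    are all missing are left unscaled and flagged in
    ``table.features["drift_uncorrected"]``.
    """
    out = table.copy()
    qc_mask = out.qc_mask
    if not qc_mask.any():
        raise ValueError("drift correction requires at least one pooled-QC sample")
    qc_rows = out.intensities.loc[qc_mask]
    reference = qc_rows.median(axis=0, skipna=True)
    uncorrected = reference.isna()

    for batch, idx in out.samples.groupby("batch").groups.items():
        batch_samples = out.samples.loc[idx]
        qc_in_batch = batch_samples.loc[batch_samples["is_qc"].astype(bool)]
        if qc_in_batch.empty:
            raise ValueError(f"batch {batch!r} has no pooled-QC sample")
        qc_orders = qc_in_batch["injection_order"].to_numpy()
        qc_ids = qc_in_batch.index.to_numpy()
        sort = np.argsort(qc_orders, kind="stable")
        qc_orders, qc_ids = qc_orders[sort], qc_ids[sort]

        study = batch_samples.loc[~batch_samples["is_qc"].astype(bool)]
        for sid, order in study["injection_order"].items():
            dist = np.abs(qc_orders - order)
            # ties toward the earlier injection: stable argmin on sorted orders
            nearest = qc_ids[int(np.argmin(dist))]
            qc_vals = out.intensities.loc[nearest]
            factor = reference / qc_vals
            factor[uncorrected | qc_vals.isna()] = 1.0
            out.intensities.loc[sid] = out.intensities.loc[sid] * factor

    out.features = out.features.copy()
    out.features["drift_uncorrected"] = uncorrected
    return out


def qc_filter(
    table: FeatureTable,
    cv_max: float = 0.30,
    missing_max: float = 0.30,
    detrend_qc: bool = False,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features by pooled-QC coefficient of variation and missingness.

    A feature is removed when its CV (SD/mean) across pooled-QC samples is
    strictly greater than ``cv_max``, or when it is missing in strictly
    more than ``missing_max`` of the study samples. ``detrend_qc`` removes a
    linear injection-order trend from the QC values before computing the CV
    (for tables whose QC rows still carry instrument drift). Returns the
    kept table and a removal log.
    """
    qc_mask = table.qc_mask
    qc_rows = table.intensities.loc[qc_mask]
    study = table.biological()

    if qc_rows.empty:
        warnings.warn("no pooled-QC samples: CV filter skipped")
        cv = pd.Series(np.nan, index=table.intensities.columns)
    elif detrend_qc:
        order = table.samples.loc[qc_mask, "injection_order"].to_numpy(float)
        cv = {}
        for col in qc_rows.columns:
            y = qc_rows[col].to_numpy(float)
            ok = np.isfinite(y)
            if ok.sum() >= 3:
                coef = np.polyfit(order[ok], y[ok], 1)
                resid = y[ok] - np.polyval(coef, order[ok]) + np.nanmean(y[ok])
                cv[col] = np.std(resid, ddof=1) / np.mean(resid)
            else:
                cv[col] = (
                    np.nanstd(y, ddof=1) / np.nanmean(y) if ok.sum() >= 2 else np.nan
                )
        cv = pd.Series(cv)
    else:
        cv = qc_rows.std(axis=0, ddof=1, skipna=True) / qc_rows.mean(axis=0, skipna=True)

    missing_frac = study.isna().mean(axis=0)

    drop_cv = cv > cv_max  # NaN CV never drops
    drop_missing = missing_frac > missing_max
    removed = drop_cv | drop_missing

    log = pd.DataFrame(
        {
            "feature": table.intensities.columns[removed],
            "reason": [
                "cv" if drop_cv[f] and not drop_missing[f]
                else ("missing" if drop_missing[f] and not drop_cv[f] else "cv+missing")
                for f in table.intensities.columns[removed]
            ],
            "cv": cv[removed].to_numpy(),
            "missing_frac": missing_frac[removed].to_numpy(),
        }
    )
    keep = table.intensities.columns[~removed]
    kept = FeatureTable(
        table.intensities[keep].copy(),
        table.features.loc[keep].copy(),
        table.samples.copy(),
    )
    return kept, log


def inverse_normal(values: pd.Series | np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Maps non-missing values to Phi^-1((rank - 3/8) / (n + 1/4)); ties get
    average ranks; NaN stays NaN.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n == 0:
        return out
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


def _design_matrix(covariates: pd.DataFrame, n_pcs: int = 10) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    if "age" in covariates:
        cols.append(covariates["age"].to_numpy(float))
        names.append("age")
    if "sex" in covariates:
        cols.append(covariates["sex"].to_numpy(float))
        names.append("sex")
    if "batch" in covariates:
        dummies = pd.get_dummies(covariates["batch"].astype(str), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(float))
            names.append(f"batch_{c}")
    for k in range(1, n_pcs + 1):
        name = f"PC{k}"
        if name in covariates:
            cols.append(covariates[name].to_numpy(float))
            names.append(name)
    return np.column_stack(cols), names


def normalize_phenotypes(
    table: FeatureTable,
    covariates: pd.DataFrame,
    n_pcs: int = 10,
) -> NormalizedPhenotypes:
    """Log, z-scale, residualize on covariates, then inverse-normalize.

    QC rows are excluded; zeros are treated as missing before the log
    (peak-detection semantics: a zero means no peak was integrated).
    Constant metabolites are dropped with a warning. Residualization is
    per-metabolite complete-case OLS on age, sex, batch indicators and
    ancestry PCs 1..n_pcs, via least squares (least-norm under
    collinearity).
    """
    bio = table.biological()
    missing_cov = bio.index.difference(covariates.index)
    if len(missing_cov):
        raise ValueError(f"covariates missing for samples: {list(missing_cov)[:5]}")
    cov = covariates.loc[bio.index]
    X, names = _design_matrix(cov, n_pcs=n_pcs)

    out = {}
    for col in bio.columns:
        y = bio[col].to_numpy(float)
        y = np.where(y <= 0, np.nan, y)
        y = np.log(y)
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.nanstd(y[ok]) == 0:
            warnings.warn(f"metabolite {col!r} constant or near-empty: dropped")
            continue
        z = np.full_like(y, np.nan)
        z[ok] = (y[ok] - np.mean(y[ok])) / np.std(y[ok], ddof=0)
        beta, *_ = np.linalg.lstsq(X[ok], z[ok], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[ok] = z[ok] - X[ok] @ beta
        out[col] = inverse_normal(resid)

    values = pd.DataFrame(out, index=bio.index)
    values.index.name = "sample"
    return NormalizedPhenotypes(values, covariates_used=names[1:])
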