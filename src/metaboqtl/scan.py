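"""Genome-wide association scan for metabolite levels.

Covers the effective number of tests (principal components explaining a
target share of metabolite variance), the Bonferroni threshold built from
it, and per-(variant, metabolite) additive-model association statistics
with a minor-allele-count filter. The default model is ordinary least
squares of the normalized phenotype on dosage plus covariates; supplying a
genetic relationship matrix (GRM) switches to a single-variance-component
mixed model fitted once per metabolite by eigen-rotation, followed by
per-variant generalized least squares — the model class of fastGWA-style
tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeData, NormalizedPhenotypes
from .qc import _design_matrix

__all__ = [
    "ScanThreshold",
    "effective_tests",
    "bonferroni_threshold",
    "format_threshold",
    "scan",
    "genetic_relationship_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanThreshold:
    """Discovery significance threshold alpha / M_eff."""

    alpha: float = 5e-8
    m_eff: int = 1

    def __post_init__(self) -> None:
        if self.m_eff < 1:
            raise ValueError("M_eff must be at least 1")

    @property
    def threshold(self) -> float:
        return self.alpha / self.m_eff

    def display(self) -> str:
        return format_threshold(self.threshold)


def format_threshold(x: float) -> str:
    """Round to one significant figure in scientific notation, e.g. 8E-11."""
    s = f"{x:.0E}"
    mantissa, exp = s.split("E")
    return f"{mantissa}E{int(exp)}"


def effective_tests(
    phenotypes: NormalizedPhenotypes | pd.DataFrame,
    var_target: float = 0.95,
) -> int:
    """Effective number of tests: PCs explaining ``var_target`` of variance.

    PCA runs on the column-standardized metabolite matrix (missing cells
    imputed by column median first); the result is the smallest k whose
    cumulative explained variance reaches the target. Rank deficiency
    (e.g. more metabolites than samples) is handled naturally by the SVD
    and logged.
    """
    values = phenotypes.values if isinstance(phenotypes, NormalizedPhenotypes) else phenotypes
    m = values.to_numpy(float).copy()
    if m.shape[1] < 2:
        raise ValueError("effective_tests requires at least 2 metabolites")
    med = np.nanmedian(m, axis=0)
    idx = np.where(np.isnan(m))
    m[idx] = np.take(med, idx[1])
    m = m - m.mean(axis=0)
    sd = m.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    m = m / sd
    sv = np.linalg.svd(m, compute_uv=False)
    ev = sv**2
    if np.linalg.matrix_rank(m) < min(m.shape):
        logger.info("metabolite matrix is rank deficient (rank %d)", np.linalg.matrix_rank(m))
    ratios = ev / ev.sum()
    cum = np.cumsum(ratios)
    return int(np.searchsorted(cum, var_target - 1e-12) + 1)


def bonferroni_threshold(alpha: float = 5e-8, m_eff: int = 1) -> float:
    """Exact alpha / M_eff (display rounding is presentation only)."""
    if m_eff < 1:
        raise ValueError("M_eff must be at least 1")
    return alpha / m_eff


def genetic_relationship_matrix(genotypes: GenotypeData, maf_min: float = 0.01) -> pd.DataFrame:
    """Allele-frequency-standardized dosage cross-product GRM."""
    d = genotypes.dosages.to_numpy(float)
    freq = np.nanmean(d, axis=0) / 2.0
    keep = (freq >= maf_min) & (freq <= 1 - maf_min)
    d = d[:, keep]
    freq = freq[keep]
    z = (np.nan_to_num(d, nan=0.0) - 2 * freq) / np.sqrt(2 * freq * (1 - freq))
    k = z @ z.T / z.shape[1]
    return pd.DataFrame(k, index=genotypes.dosages.index, columns=genotypes.dosages.index)


def _reml_h2(y: np.ndarray, X: np.ndarray, eigvals: np.ndarray) -> float:
    """Profile ML for the heritability ratio on eigen-rotated data."""

    def neg_ll(h2: float) -> float:
        v = h2 * eigvals + (1 - h2)
        w = 1.0 / v
        Xw = X * w[:, None]
        xtx = X.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ y)
        r = y - X @ beta
        sigma2 = float(np.sum(w * r * r)) / len(y)
        return 0.5 * (np.sum(np.log(v)) + len(y) * np.log(sigma2))

    res = optimize.minimize_scalar(neg_ll, bounds=(1e-6, 1 - 1e-6), method="bounded")
    return float(res.x)


def scan(
    genotypes: GenotypeData,
    phenotypes: NormalizedPhenotypes,
    covariates: pd.DataFrame,
    mac_min: int = 5,
    grm: pd.DataFrame | None = None,
    n_pcs: int = 10,
    include_batch: bool = False,
) -> pd.DataFrame:
    """Per-(variant, metabolite) additive association statistics.

    Variants with minor allele count below ``mac_min`` in the analyzed
    samples are excluded. The phenotype is regressed on dosage plus age,
    sex and ancestry PCs 1..n_pcs (two-sided p from the t reference with
    residual degrees of freedom). With ``grm``, the covariance is modeled
    as h2*GRM + (1-h2)*I per metabolite via eigen-rotation, then each
    variant is tested by generalized least squares. Returns a summary
    frame with columns variant, metabolite, chrom, pos, ref, alt, n, mac,
    beta, se, p.
    """
    values = phenotypes.values
    common = values.index.intersection(genotypes.dosages.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between genotypes and phenotypes")
    values = values.loc[common]
    dos = genotypes.dosages.loc[common]
    cov = covariates.loc[common].copy()
    if not include_batch and "batch" in cov:
        cov = cov.drop(columns=["batch"])
    X, _ = _design_matrix(cov, n_pcs=n_pcs)

    rot = None
    if grm is not None:
        k = grm.loc[common, common].to_numpy(float)
        eigvals, eigvecs = np.linalg.eigh(k)
        eigvals = np.clip(eigvals, 0.0, None)
        rot = (eigvals, eigvecs)

    d_np = dos.to_numpy(float)
    complete_dosage = not np.isnan(d_np).any()

    records: list[dict] = []
    var_meta = genotypes.variants
    for met in values.columns:
        y_all = values[met].to_numpy(float)
        ok_y = np.isfinite(y_all)

        if rot is not None:
            sub = ok_y
            y = y_all[sub]
            Xs = X[sub]
            # re-rotate within the complete-case subset of this metabolite
            ksub = (rot[1] * rot[0]) @ rot[1].T
            ksub = ksub[np.ix_(sub, sub)]
            evals, evecs = np.linalg.eigh(ksub)
            evals = np.clip(evals, 0.0, None)
            yr = evecs.T @ y
            Xr = evecs.T @ Xs
            h2 = _reml_h2(yr, Xr, evals)
            v = h2 * evals + (1 - h2)
            sw = 1.0 / np.sqrt(v)
            y_t = yr * sw
            X_t = Xr * sw[:, None]
            for vi, vid in enumerate(dos.columns):
                g = d_np[sub, vi]
                if not np.isfinite(g).all():
                    logger.info("variant %s: missing dosages under GRM model, skipped", vid)
                    continue
                g_r = (evecs.T @ g) * sw
                rec = _ols_record(y_t, X_t, g_r, g_raw=g)
                if rec is None:
                    continue
                if rec["mac"] < mac_min:
                    continue
                rec.update(_variant_fields(var_meta, vid, met))
                records.append(rec)
            continue

        if complete_dosage and ok_y.all():
            records.extend(
                _fwl_scan(y_all, X, d_np, dos.columns, var_meta, met, mac_min)
            )
        else:
            for vi, vid in enumerate(dos.columns):
                g = d_np[:, vi]
                sub = ok_y & np.isfinite(g)
                if sub.sum() == 0:
                    logger.info("variant %s: no called dosages, skipped", vid)
                    continue
                rec = _ols_record(y_all[sub], X[sub], g[sub], g_raw=g[sub])
                if rec is None:
                    logger.info("variant %s: singular design, skipped", vid)
                    continue
                if rec["mac"] < mac_min:
                    continue
                rec.update(_variant_fields(var_meta, vid, met))
                records.append(rec)

    cols = ["variant", "metabolite", "chrom", "pos", "ref", "alt", "n", "mac", "beta", "se", "p"]
    return pd.DataFrame(records, columns=cols)


def _variant_fields(var_meta: pd.DataFrame, vid: str, met: str) -> dict:
    row = var_meta.loc[vid]
    return {
        "variant": vid,
        "metabolite": met,
        "chrom": row["chrom"],
        "pos": int(row["pos"]),
        "ref": row["ref"],
        "alt": row["alt"],
    }


def _mac(g: np.ndarray) -> int:
    alt = float(np.nansum(g))
    return int(round(min(alt, 2 * np.isfinite(g).sum() - alt)))


def _ols_record(y: np.ndarray, X: np.ndarray, g: np.ndarray, g_raw: np.ndarray) -> dict | None:
    design = np.column_stack([g, X])
    n, p = design.shape
    if n <= p:
        return None
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        return None
    resid = y - design @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    t = beta[0] / se
    pval = 2.0 * stats.t.sf(abs(t), df)
    return {
        "n": n,
        "mac": _mac(g_raw),
        "beta": float(beta[0]),
        "se": se,
        "p": float(max(pval, 5e-324)),
    }


def _fwl_scan(
    y: np.ndarray,
    X: np.ndarray,
    d: np.ndarray,
    variant_ids,
    var_meta: pd.DataFrame,
    met: str,
    mac_min: int,
) -> list[dict]:
    """Vectorized complete-data path via Frisch-Waugh-Lovell.

    Residualizing the phenotype and every dosage column on the covariates
    once, then running per-variant simple regressions with the full-model
    degrees of freedom, reproduces the full OLS beta/SE/p exactly.
    """
    n, p_cov = X.shape
    q, _ = np.linalg.qr(X)
    y_r = y - q @ (q.T @ y)
    d_r = d - q @ (q.T @ d)

    gg = np.einsum("ij,ij->j", d_r, d_r)
    gy = d_r.T @ y_r
    df = n - p_cov - 1
    out: list[dict] = []
    yy = float(y_r @ y_r)
    for vi, vid in enumerate(variant_ids):
        mac = _mac(d[:, vi])
        if mac < mac_min:
            continue
        if gg[vi] <= 1e-12:
            logger.info("variant %s: no dosage variance after residualization", vid)
            continue
        beta = gy[vi] / gg[vi]
        rss = yy - beta * gy[vi]
        sigma2 = max(rss, 0.0) / df
        se = float(np.sqrt(sigma2 / gg[vi]))
        if se == 0:
            continue
        t = beta / se
        pval = 2.0 * stats.t.sf(abs(t), df)
        rec = {
            "n": n,
            "mac": mac,
            "beta": float(beta),
            "se": se,
            "p": float(max(pval, 5e-324)),
        }
        rec.update(_variant_fields(var_meta, vid, met))
        out.append(rec)
    return out
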