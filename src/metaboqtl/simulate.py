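"""Synthetic cohort generator with planted ground truth.

Emulates the data a metabolome genome-wide association study consumes:
biallelic genotypes over a configurable allele-frequency spectrum, latent
metabolites with planted per-allele effects and covariate effects,
adduct/in-source-fragment satellite features that co-elute with their
primary ion at fixed mass offsets, pooled-QC injections with instrument
drift and missingness, and replicate MS/MS scans with shared fragments
between structurally related compounds plus an electronic-noise fragment
near m/z 173.46.

Every generated object is reproducible from the configuration seed, and a
:class:`TruthLedger` records the planted structure so that each downstream
stage has a parameter-recovery oracle.

Effect-size convention: a planted ``beta`` is the per-allele effect in SD
units of the normalized metabolite. The generator plants effects on the
log-intensity scale and shrinks the residual noise so that the total
phenotypic variance is ~1; after log transform, covariate residualization
and inverse normalization the regression slope on dosage is then ``beta``
itself, which makes "the scan recovers beta within 2 SE" a well-posed
check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, GenotypeData, MsmsSpectrum

__all__ = [
    "AdductSpec",
    "PlantedEffect",
    "SimulationConfig",
    "TruthLedger",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_metabolome",
    "simulate_msms",
    "write_vcf",
    "write_mgf",
    "write_truth",
]

ELECTRONIC_NOISE_MZ = 173.46

# Deterministic per-stage sub-streams: adding a stage never shifts the draws
# of an earlier one.
_STAGE_KEYS = {"genotypes": 1, "covariates": 2, "metabolome": 3, "msms": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_KEYS[stage]]))


@dataclass
class PlantedEffect:
    """A true per-allele genetic effect on one metabolite."""

    variant: int
    metabolite: int
    beta: float


@dataclass
class AdductSpec:
    """One satellite feature of a primary ion.

    ``offset`` is the mass difference in Da relative to the primary [M+H]+
    feature; ``abundance`` the satellite/primary intensity ratio in (0, 1];
    ``noise_sd`` a log-scale SD of sample-to-sample deviation from perfect
    proportionality.
    """

    offset: float
    abundance: float
    noise_sd: float = 0.02
    label: str = ""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``maf_spectrum`` is a list of (minor allele frequency, proportion of
    variants) pairs whose proportions sum to 1 — a mixture that can include
    rare-in-one-population entries. ``adduct_profile`` gives, per primary
    metabolite, the satellite features to attach. ``drift_slope`` is the
    multiplicative sensitivity change per injection; pooled-QC samples are
    inserted every ``qc_interval`` injections, mirroring routine LC-MS
    practice.
    """

    n_samples: int = 1000
    n_variants: int = 100
    maf_spectrum: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.05, 0.25), (0.2, 0.5), (0.4, 0.25)]
    )
    n_primary_metabolites: int = 20
    effects: list[PlantedEffect] = field(default_factory=list)
    adduct_profile: dict[int, list[AdductSpec]] = field(default_factory=dict)
    qc_interval: int = 20
    drift_slope: float = 2e-4
    missing_rate: float = 0.05
    cv_noise_sd: float = 0.25
    seed: int = 0
    # secondary knobs (defaults are part of the study conditions)
    chrom: str = "1"
    variant_spacing: int = 100_000
    rt_jitter_min: float = 0.02
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.2, "batch": 0.1}
    )
    n_ancestry_pcs: int = 10
    left_censor: bool = False
    # MS/MS stage
    n_fragments: int = 8
    n_scans_per_primary: int = 3
    related_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    noise_peak_fraction: float = 0.5
    fragment_jitter_ppm: float = 2.0

    def validate(self) -> None:
        if min(self.n_samples, self.n_variants, self.n_primary_metabolites) <= 0:
            raise ValueError("counts must be positive")
        props = [p for _, p in self.maf_spectrum]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("maf_spectrum proportions must sum to 1")
        if any(not 0.0 <= f <= 1.0 for f, _ in self.maf_spectrum):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        for eff in self.effects:
            if not 0 <= eff.variant < self.n_variants:
                raise ValueError(f"effect variant index {eff.variant} out of range")
            if not 0 <= eff.metabolite < self.n_primary_metabolites:
                raise ValueError(
                    f"effect metabolite index {eff.metabolite} out of range"
                )
        for idx in self.adduct_profile:
            if not 0 <= idx < self.n_primary_metabolites:
                raise ValueError(f"adduct profile index {idx} out of range")


@dataclass
class TruthLedger:
    """Planted ground truth for parameter-recovery tests.

    ``satellites`` maps each primary feature id to its satellite feature
    ids with adduct labels (each satellite belongs to exactly one primary);
    ``effects`` maps (variant id, metabolite feature id) to the true beta;
    ``drift`` holds the per-sample multiplicative drift factors.
    """

    satellites: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    drift: dict[str, float] = field(default_factory=dict)
    primary_mz: dict[str, float] = field(default_factory=dict)
    primary_rt: dict[str, float] = field(default_factory=dict)

    def all_features(self) -> list[str]:
        out: list[str] = []
        for primary, sats in self.satellites.items():
            out.append(primary)
            out.extend(s for s, _ in sats)
        return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeData:
    """Draw biallelic dosages under Hardy-Weinberg sampling.

    Each variant's allele frequency is drawn from the configured spectrum;
    dosages are Binomial(2, f). Variants are laid out on one chromosome at
    ``variant_spacing`` intervals so that locus-definition windows have
    genuine coordinates to work with.
    """
    config.validate()
    rng = _stage_rng(config.seed, "genotypes")
    freqs = np.array([f for f, _ in config.maf_spectrum])
    props = np.array([p for _, p in config.maf_spectrum])
    bins = rng.choice(len(freqs), size=config.n_variants, p=props)
    f = freqs[bins]
    dosages = rng.binomial(2, f[None, :], size=(config.n_samples, config.n_variants))

    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    variant_ids = [f"var{j:05d}" for j in range(config.n_variants)]
    pos = (np.arange(config.n_variants) + 1) * config.variant_spacing
    ref = rng.choice(list("ACGT"), size=config.n_variants)
    alt_choices = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    alt = np.array([rng.choice(alt_choices[r]) for r in ref])
    variants = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "ref": ref, "alt": alt, "maf": f},
        index=pd.Index(variant_ids, name="variant"),
    )
    dos = pd.DataFrame(
        dosages.astype(float),
        index=pd.Index(sample_ids, name="sample"),
        columns=variants.index,
    )
    return GenotypeData(dos, variants)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age, sex, batch and ancestry-PC covariates for the cohort."""
    rng = _stage_rng(config.seed, "covariates")
    n = config.n_samples
    cov = pd.DataFrame(
        {
            "age": rng.normal(55, 10, n).round(1),
            "sex": rng.integers(0, 2, n),
            "batch": rng.integers(0, 2, n).astype(str),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample"),
    )
    for k in range(1, config.n_ancestry_pcs + 1):
        cov[f"PC{k}"] = rng.normal(0, 1, n)
    return cov


def _hwe_var(dosage: np.ndarray) -> float:
    return float(np.var(dosage))


def simulate_metabolome(
    genotypes: GenotypeData,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[FeatureTable, TruthLedger]:
    """Generate the LC-MS feature table with planted effects and satellites.

    Primary intensity is exp(baseline + sum(beta * dosage) + covariate
    effects + noise); satellites are the primary scaled by a relative
    abundance with lognormal noise, the same retention time up to a small
    jitter, and m/z shifted by the adduct's mass offset. A multiplicative
    drift factor is applied by injection order, pooled-QC rows are inserted
    every ``qc_interval`` injections, and missingness is applied to non-QC
    cells.
    """
    config.validate()
    if not genotypes.dosages.index.equals(covariates.index):
        raise ValueError("genotype and covariate sample sets must be aligned")
    rng = _stage_rng(config.seed, "metabolome")
    n = config.n_samples
    n_met = config.n_primary_metabolites

    cb = config.covariate_betas
    cov_term = np.zeros(n)
    cov_term += cb.get("age", 0.0) * (
        covariates["age"].to_numpy(float) - covariates["age"].mean()
    )
    cov_term += cb.get("sex", 0.0) * covariates["sex"].to_numpy(float)
    cov_term += cb.get("batch", 0.0) * (covariates["batch"] == "1").to_numpy(float)

    effects_by_met: dict[int, list[PlantedEffect]] = {}
    for eff in config.effects:
        effects_by_met.setdefault(eff.metabolite, []).append(eff)

    truth = TruthLedger()
    log_primary = np.empty((n, n_met))
    baselines = np.log(1e6) + rng.normal(0, 0.5, n_met)
    mzs = rng.uniform(90.0, 750.0, n_met)
    rts = rng.uniform(0.5, 12.0, n_met)
    for m in range(n_met):
        genetic = np.zeros(n)
        var_g = 0.0
        for eff in effects_by_met.get(m, []):
            d = genotypes.dosages.iloc[:, eff.variant].to_numpy(float)
            genetic += eff.beta * d
            var_g += eff.beta**2 * _hwe_var(d)
        # with a planted effect, residual SD completes the genetic variance
        # to ~1 so the standardized per-allele slope equals the planted beta;
        # otherwise cv_noise_sd is the log-scale noise SD directly
        if config.cv_noise_sd == 0:
            noise = np.zeros(n)
        elif var_g > 0:
            noise = rng.normal(0, np.sqrt(max(1.0 - var_g, 0.05)), n)
        else:
            noise = rng.normal(0, config.cv_noise_sd, n)
        log_primary[:, m] = baselines[m] + genetic + cov_term + noise

    feature_cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for m in range(n_met):
        pid = f"met{m:03d}_MH"
        feature_cols[pid] = np.exp(log_primary[:, m])
        meta_rows.append(
            {"feature": pid, "mz": mzs[m], "rt": rts[m], "identity": "", "mode": "pos"}
        )
        truth.satellites[pid] = []
        truth.primary_mz[pid] = float(mzs[m])
        truth.primary_rt[pid] = float(rts[m])
        for eff in effects_by_met.get(m, []):
            vid = genotypes.variants.index[eff.variant]
            truth.effects[(vid, pid)] = eff.beta
        for k, spec in enumerate(config.adduct_profile.get(m, [])):
            sid = f"met{m:03d}_sat{k}"
            sat_noise = rng.normal(0, spec.noise_sd, n)
            feature_cols[sid] = feature_cols[pid] * spec.abundance * np.exp(sat_noise)
            rt_jit = rng.normal(0, config.rt_jitter_min / 2)
            rt_jit = float(np.clip(rt_jit, -config.rt_jitter_min, config.rt_jitter_min))
            meta_rows.append(
                {
                    "feature": sid,
                    "mz": mzs[m] + spec.offset,
                    "rt": max(rts[m] + rt_jit, 0.0),
                    "identity": "",
                    "mode": "pos",
                }
            )
            truth.satellites[pid].append((sid, spec.label or f"offset{spec.offset:+.4f}"))

    features = pd.DataFrame(meta_rows).set_index("feature")
    bio = pd.DataFrame(feature_cols, index=genotypes.dosages.index)

    # interleave pooled-QC injections every qc_interval study injections
    qc_level = np.exp(baselines)  # pooled plasma: per-feature reference level
    qc_by_feature = {}
    for m in range(n_met):
        pid = f"met{m:03d}_MH"
        qc_by_feature[pid] = qc_level[m]
        for k, spec in enumerate(config.adduct_profile.get(m, [])):
            qc_by_feature[f"met{m:03d}_sat{k}"] = qc_level[m] * spec.abundance

    rows: list[pd.Series] = []
    sample_meta: list[dict] = []
    injection = 0
    n_qc = 0

    def add_qc() -> None:
        nonlocal injection, n_qc
        qid = f"QC{n_qc:03d}"
        drift = 1.0 + config.drift_slope * injection
        vals = pd.Series(
            {fid: qc_by_feature[fid] * drift * np.exp(rng.normal(0, 0.01)) for fid in bio.columns},
            name=qid,
        )
        rows.append(vals)
        sample_meta.append(
            {"sample": qid, "is_qc": True, "injection_order": injection, "batch": "0"}
        )
        truth.drift[qid] = drift
        n_qc += 1
        injection += 1

    add_qc()
    for i, sid in enumerate(bio.index):
        drift = 1.0 + config.drift_slope * injection
        rows.append(bio.loc[sid] * drift)
        sample_meta.append(
            {"sample": sid, "is_qc": False, "injection_order": injection, "batch": "0"}
        )
        truth.drift[sid] = drift
        injection += 1
        if (i + 1) % config.qc_interval == 0:
            add_qc()
    if sample_meta[-1]["is_qc"] is False:
        add_qc()

    intens = pd.DataFrame(rows)
    intens.index.name = "sample"
    samples = pd.DataFrame(sample_meta).set_index("sample")

    if config.missing_rate > 0:
        nonqc = ~samples["is_qc"].to_numpy()
        block = intens.loc[nonqc]
        if config.left_censor:
            # censor the lowest-intensity cells per feature
            k = int(round(config.missing_rate * block.shape[0]))
            for col in block.columns:
                if k > 0:
                    cut = np.partition(block[col].to_numpy(), k - 1)[k - 1]
                    block.loc[block[col] <= cut, col] = np.nan
        else:
            mask = rng.random(block.shape) < config.missing_rate
            block = block.mask(mask)
        intens.loc[nonqc] = block

    table = FeatureTable(intens, features, samples)
    return table, truth


def simulate_msms(truth: TruthLedger, config: SimulationConfig) -> list[MsmsSpectrum]:
    """Replicate MS/MS scans per primary with planted spectral structure.

    Each primary ion gets ``n_scans_per_primary`` scans. Structurally
    related primaries (``related_pairs``) share the stated fraction of
    fragment m/z values. An electronic-noise fragment near m/z 173.46 is
    injected into a ``noise_peak_fraction`` subset of scans. Fragment m/z
    jitter between replicate scans stays within ±``fragment_jitter_ppm``.
    """
    if not truth.satellites:
        raise ValueError("truth ledger has no primary features")
    rng = _stage_rng(config.seed, "msms")
    primaries = sorted(truth.satellites)

    frag_mz: dict[str, np.ndarray] = {}
    frag_int: dict[str, np.ndarray] = {}
    for pid in primaries:
        upper = min(truth.primary_mz.get(pid, 500.0), 800.0)
        frag_mz[pid] = np.sort(rng.uniform(70.0, max(upper, 80.0), config.n_fragments))
        frag_int[pid] = rng.uniform(1e3, 1e6, config.n_fragments)

    idx_of = {pid: i for i, pid in enumerate(primaries)}
    for mi, mj, frac in config.related_pairs:
        pi, pj = primaries[mi], primaries[mj]
        k = int(round(frac * config.n_fragments))
        if k > 0:
            # shared substructure: shared fragments keep m/z AND intensity
            order_i = np.argsort(frag_mz[pj], kind="stable")
            frag_mz[pj][order_i[:k]] = frag_mz[pi][:k]
            frag_int[pj][order_i[:k]] = frag_int[pi][:k]
            resort = np.argsort(frag_mz[pj], kind="stable")
            frag_mz[pj] = frag_mz[pj][resort]
            frag_int[pj] = frag_int[pj][resort]

    spectra: list[MsmsSpectrum] = []
    for pid in primaries:
        for s in range(config.n_scans_per_primary):
            jitter = rng.uniform(
                -config.fragment_jitter_ppm, config.fragment_jitter_ppm, config.n_fragments
            )
            mz = frag_mz[pid] * (1.0 + jitter * 1e-6)
            inten = frag_int[pid] * np.exp(rng.normal(0, 0.05, config.n_fragments))
            if rng.random() < config.noise_peak_fraction:
                mz = np.append(mz, ELECTRONIC_NOISE_MZ * (1 + rng.uniform(-10e-6, 10e-6)))
                inten = np.append(inten, rng.uniform(1e3, 1e4))
            spectra.append(
                MsmsSpectrum(
                    precursor_mz=truth.primary_mz.get(pid, 500.0)
                    + rng.uniform(-0.05, 0.05),
                    rt=truth.primary_rt.get(pid, 5.0) + rng.uniform(-0.05, 0.05),
                    collision_energy=25,
                    mz=mz,
                    intensity=inten,
                    feature_id=pid,
                )
            )
    return spectra


# ---------------------------------------------------------------------------
# serialization


def write_feature_table(table: FeatureTable, outdir: str | Path, stem: str = "features") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.intensities.to_csv(outdir / f"{stem}_intensities.tsv", sep="\t")
    table.features.to_csv(outdir / f"{stem}_metadata.tsv", sep="\t")
    table.samples.to_csv(outdir / f"{stem}_samples.tsv", sep="\t")


def read_feature_table(outdir: str | Path, stem: str = "features") -> FeatureTable:
    outdir = Path(outdir)
    intens = pd.read_csv(outdir / f"{stem}_intensities.tsv", sep="\t", index_col=0)
    feats = pd.read_csv(
        outdir / f"{stem}_metadata.tsv", sep="\t", index_col=0, keep_default_na=False
    )
    feats["mz"] = feats["mz"].astype(float)
    feats["rt"] = feats["rt"].astype(float)
    samples = pd.read_csv(outdir / f"{stem}_samples.tsv", sep="\t", index_col=0)
    return FeatureTable(intens, feats, samples)


def write_dosages(genotypes: GenotypeData, path: str | Path) -> None:
    genotypes.dosages.to_csv(path, sep="\t")


def write_vcf(genotypes: GenotypeData, path: str | Path) -> None:
    """Write dosages as a minimal VCF with GT calls (0 -> 0/0, 1 -> 0/1, 2 -> 1/1)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = pd.unique(genotypes.variants["chrom"])
    for c in chroms:
        header.contigs.add(str(c))
    for s in genotypes.dosages.index:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for vid, row in genotypes.variants.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(vid),
            )
            d = genotypes.dosages[vid]
            for s in genotypes.dosages.index:
                x = d.loc[s]
                if pd.isna(x):
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    x = int(x)
                    rec.samples[str(s)]["GT"] = (0, 0) if x == 0 else ((0, 1) if x == 1 else (1, 1))
            vf.write(rec)


def read_vcf(path: str | Path) -> GenotypeData:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        ids, rows, dosage_rows = [], [], []
        for rec in vf:
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            rows.append(
                {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0]}
            )
            dos = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(gt)))
            dosage_rows.append(dos)
    variants = pd.DataFrame(rows, index=pd.Index(ids, name="variant"))
    dosages = pd.DataFrame(
        np.array(dosage_rows).T, index=pd.Index(samples, name="sample"), columns=variants.index
    )
    return GenotypeData(dosages, variants)


def write_mgf(spectra: list[MsmsSpectrum], path: str | Path) -> None:
    from pyteomics import mgf

    entries = []
    for i, sp in enumerate(spectra):
        entries.append(
            {
                "m/z array": sp.mz,
                "intensity array": sp.intensity,
                "params": {
                    "title": f"{sp.feature_id or 'scan'}_{i}",
                    "pepmass": sp.precursor_mz,
                    "rtinseconds": sp.rt * 60.0,
                    "collision_energy": sp.collision_energy,
                },
            }
        )
    mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    from pyteomics import mgf

    out = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            p = entry["params"]
            pep = p["pepmass"]
            title = str(p.get("title", ""))
            out.append(
                MsmsSpectrum(
                    precursor_mz=float(pep[0] if isinstance(pep, (tuple, list)) else pep),
                    rt=float(p.get("rtinseconds", 0.0)) / 60.0,
                    collision_energy=p.get("collision_energy", "stepped"),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    feature_id=title.rsplit("_", 1)[0] if title else None,
                )
            )
    return out


def write_truth(truth: TruthLedger, path: str | Path) -> None:
    payload = {
        "satellites": truth.satellites,
        "effects": [
            {"variant": v, "metabolite": m, "beta": b} for (v, m), b in truth.effects.items()
        ],
        "drift": truth.drift,
        "primary_mz": truth.primary_mz,
        "primary_rt": truth.primary_rt,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
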