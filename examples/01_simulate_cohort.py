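"""Simulate a small cohort with planted truth and write standard formats.

Generates genotypes, covariates, an LC-MS feature table with adduct
satellites and pooled-QC injections, and replicate MS/MS scans; writes
VCF, TSV, MGF and the ground-truth ledger to ./scratch_example/.
"""

from pathlib import Path

import metaboqtl as mq
from metaboqtl.simulate import write_feature_table, write_mgf, write_truth, write_vcf

cfg = mq.SimulationConfig(
    n_samples=200,
    n_variants=50,
    n_primary_metabolites=10,
    effects=[mq.PlantedEffect(variant=7, metabolite=2, beta=0.6)],
    adduct_profile={2: [mq.AdductSpec(21.98194, 0.3, 0.02, "[M+Na]+")]},
    seed=1,
)

genotypes = mq.simulate_genotypes(cfg)
covariates = mq.simulate_covariates(cfg)
table, truth = mq.simulate_metabolome(genotypes, covariates, cfg)
spectra = mq.simulate_msms(truth, cfg)

out = Path("scratch_example")
out.mkdir(exist_ok=True)
write_vcf(genotypes, out / "genotypes.vcf")
write_feature_table(table, out)
write_mgf(spectra, out / "scans.mgf")
write_truth(truth, out / "truth.json")

print(f"samples: {cfg.n_samples}  variants: {cfg.n_variants}")
print(f"feature columns: {table.intensities.shape[1]} "
      f"({cfg.n_primary_metabolites} primaries + satellites)")
print(f"pooled-QC injections: {int(table.qc_mask.sum())}")
print(f"MS/MS scans: {len(spectra)}")
print(f"planted effect: beta={truth.effects[('var00007', 'met002_MH')]} "
      "per allele (SD units) on met002_MH")
# The files in scratch_example/ are the exact inputs a real study would
# provide: dosages (VCF), intensities+metadata (TSV) and raw scans (MGF).
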