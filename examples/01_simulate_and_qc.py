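"""Generate a structured synthetic panel, write it as a PLINK fileset, and
run call-rate QC plus LD pruning on it."""

import tempfile
from pathlib import Path

import numpy as np

from herdchar import (
    MISSING,
    BaldingNicholsSpec,
    GenotypeDataset,
    ld_prune,
    qc_filter,
    read_genotypes,
    simulate_balding_nichols,
    write_genotypes,
)

# Three populations differentiated at F_ST = 0.15, 20 diploids each.
ds = simulate_balding_nichols(
    BaldingNicholsSpec(n_pops=3, n_per_pop=20, n_loci=500, fst=0.15, seed=1)
)

# Knock out 8% of calls at a handful of SNPs to give QC something to do.
rng = np.random.default_rng(2)
g = ds.genotypes.copy()
bad_snps = rng.choice(ds.n_snps, 30, replace=False)
for j in bad_snps:
    rows = rng.choice(ds.n_samples, 5, replace=False)
    g[rows, j] = MISSING
ds = GenotypeDataset(g, ds.snps, ds.samples)

with tempfile.TemporaryDirectory() as tmp:
    write_genotypes(ds, Path(tmp) / "panel", "plink-text")
    ds = read_genotypes(Path(tmp) / "panel", "plink-text")

filtered, report = qc_filter(ds, snp_call_rate=0.95, sample_call_rate=0.95)
kept = ld_prune(filtered, window_snps=50, step_snps=5, r2_threshold=0.2)

print(f"input:   {ds.n_samples} samples x {ds.n_snps} SNPs")
print(f"qc:      removed {report.snps_removed} SNPs below 95% call rate, "
      f"{report.samples_removed} samples")
print(f"pruning: {len(kept)} SNPs retained below the r2 = 0.2 ceiling")
# SNPs genotyped in fewer than 95% of animals are dropped first, then sparse
# animals; pruning removes one member of every remaining high-LD pair.
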