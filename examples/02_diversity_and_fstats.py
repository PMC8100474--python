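"""Within-population diversity and Weir-Cockerham F-statistics, with the
target differentiation recovered from a synthetic truth."""

from herdchar import (
    BaldingNicholsSpec,
    diversity_summary,
    global_fstats,
    pairwise_fst,
    simulate_balding_nichols,
    wright_identity,
)

# Four populations simulated at a true F_ST of 0.20.
ds = simulate_balding_nichols(
    BaldingNicholsSpec(n_pops=4, n_per_pop=50, n_loci=5000, fst=0.2, seed=7)
)

print("population  n   MAF    H_O    H_E    F_IS")
for row in diversity_summary(ds):
    print(f"{row.population:<10} {row.n:3d}  {row.maf_mean:.3f}  "
          f"{row.ho_mean:.3f}  {row.he_mean:.3f}  {row.fis:+.3f}")

res = global_fstats(ds, n_boot=200, n_perm=99, seed=1)
print(f"\nF_ST = {res.fst:.3f}  (95% CI {res.ci_fst[0]:.3f}-{res.ci_fst[1]:.3f}, "
      f"p = {res.p_fst:.3f})")
print(f"F_IS = {res.fis:+.3f}   F_IT = {res.fit:.3f}")
print(f"Wright identity check: 1-(1-F_IS)(1-F_ST) = "
      f"{wright_identity(res.fis, res.fst):.3f}")

labels, mat = pairwise_fst(ds)
print("\npairwise F_ST (theta per population pair):")
for i, l in enumerate(labels):
    print(f"  {l:<6}", "  ".join(f"{mat[i, j]:.3f}" for j in range(len(labels))))
# The multi-locus theta recovers the simulated 0.20, the permutation p-value
# confirms real differentiation, and F_IT follows from Wright's identity.
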