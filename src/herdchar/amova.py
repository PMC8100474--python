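"""Three-level analysis of molecular variance on unphased SNP genotypes.

Each diploid individual contributes two allele copies per locus (gametic
coding; the within-individual level is defined by heterozygosity and is
phase-free).  With the simple mismatch distance between copies the locus-wise
analysis is an ANOVA on 0/1 allele indicators; sums of squares are summed
over loci and the standard mean-square equations solved for the variance
components:

    sigma2_c = MS(within individuals)
    sigma2_b = (MS(among individuals within pops) - MS(within)) / 2
    sigma2_a = (MS(among pops) - MS(among individuals)) / n_c

with n_c the usual unequal-size coefficient on allele-copy counts.  Negative
intermediate components are reported as computed.  Significance is assessed
by permutation: whole individuals across populations for the among-population
level, allele copies re-paired within populations for the within-individual
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeDataset


@dataclass(frozen=True)
class AmovaResult:
    sigma2: tuple[float, float, float]  # among pops, among ind within pops, within ind
    percents: tuple[float, float, float]
    df: tuple[int, int, int]
    p_values: tuple[float | None, float | None, float | None]
    n_perm: int
    seed: int


def _components(g: np.ndarray, codes: np.ndarray):
    """Variance components from a dosage matrix and integer pop codes.

    Complete-case per locus; returns (sigma_a, sigma_b, sigma_c, df).
    Sums of squares accumulate over loci, as do the df-weighted coefficients,
    handling per-locus missingness the way locus-summed AMOVA does.
    Fully vectorized: per-locus sums of squares follow from the identities
    SS_b = 2(sum_i y_i^2 - sum_k n_k p_k^2) and SS_a = sum_k 2 n_k (p_k - p)^2
    with y_i the individual allele-indicator mean and p_k the population
    allele frequency.
    """
    K = int(codes.max()) + 1
    obs = g != MISSING
    gf = np.where(obs, g, 0).astype(float)
    n_k = np.stack([(obs & (codes == k)[:, None]).sum(axis=0) for k in range(K)]).astype(float)
    sum_k = np.stack([gf[codes == k].sum(axis=0) for k in range(K)])
    N = n_k.sum(axis=0)
    P = (n_k > 0).sum(axis=0).astype(float)
    used = (P >= 2) & (N >= 2)
    if not used.any():
        raise ValueError("no informative locus with >= 2 populations")
    with np.errstate(invalid="ignore", divide="ignore"):
        p_k = sum_k / (2 * n_k)
        p_tot = sum_k.sum(axis=0) / (2 * N)
        ss_a_j = np.nansum(2 * n_k * (p_k - p_tot) ** 2, axis=0)
        sum_y2 = (gf**2 / 4).sum(axis=0)
        ss_b_j = 2 * (sum_y2 - np.nansum(n_k * p_k**2, axis=0))
        ss_c_j = 0.5 * (obs & (g == 1)).sum(axis=0)  # each het: 2 copies at .25
        m_k = 2 * n_k
        nc_j = 2 * N - np.where(n_k > 0, m_k**2, 0).sum(axis=0) / (2 * N)
    ss_a = float(ss_a_j[used].sum())
    ss_b = float(ss_b_j[used].sum())
    ss_c = float(ss_c_j[used].sum())
    df_a = float((P[used] - 1).sum())
    df_b = float((N[used] - P[used]).sum())
    df_c = float(N[used].sum())
    nc_weight = float(nc_j[used].sum())
    ms_a = ss_a / df_a
    ms_b = ss_b / df_b if df_b > 0 else 0.0
    ms_c = ss_c / df_c if df_c > 0 else 0.0
    n_c = nc_weight / df_a
    sigma_c = ms_c
    sigma_b = (ms_b - ms_c) / 2
    sigma_a = (ms_a - ms_b) / n_c
    return sigma_a, sigma_b, sigma_c, (int(df_a), int(df_b), int(df_c))


def amova_three_level(
    ds: GenotypeDataset, n_perm: int = 0, seed: int = 0
) -> AmovaResult:
    """Hierarchical variance decomposition with permutation p-values.

    Percent components are constructed from the common total so they sum to
    exactly 100.
    """
    pops = ds.populations
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    for p in pops:
        if ds.population_mask(p).sum() < 2:
            raise ValueError(f"population {p!r} has < 2 individuals")
    codes = np.array([pops.index(s.population) for s in ds.samples])
    g = ds.genotypes
    sa, sb, sc, df = _components(g, codes)
    total = sa + sb + sc
    percents = (100 * sa / total, 100 * sb / total, 100 * sc / total)

    p_a = p_c = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits_a = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            pa, _, _, _ = _components(g, perm)
            if pa >= sa:
                hits_a += 1
        p_a = (hits_a + 1) / (n_perm + 1)
        # within-individual level: re-pair allele copies within populations
        hits_c = 0
        for _ in range(n_perm):
            newg = _repair_copies(g, codes, rng)
            _, _, pc, _ = _components(newg, codes)
            if pc >= sc:
                hits_c += 1
        p_c = (hits_c + 1) / (n_perm + 1)

    return AmovaResult(
        sigma2=(float(sa), float(sb), float(sc)),
        percents=tuple(float(x) for x in percents),
        df=df,
        p_values=(p_a, None, p_c),
        n_perm=n_perm,
        seed=seed,
    )


def _repair_copies(g: np.ndarray, codes: np.ndarray, rng) -> np.ndarray:
    """Shuffle allele copies among individuals within each population."""
    from .fstats import shuffle_alleles_within

    out = g.copy()
    for pop in np.unique(codes):
        rows = np.flatnonzero(codes == pop)
        out[rows] = shuffle_alleles_within(g[rows], rng)
    return out
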