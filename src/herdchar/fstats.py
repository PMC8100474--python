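"""Weir–Cockerham F-statistics for biallelic SNP panels.

Per-locus variance components a (among populations), b (among individuals
within populations) and c (within individuals) follow the 1984 ANOVA
estimators; multi-locus statistics are ratios of component sums
(ratio-of-sums, not mean-of-ratios):

    theta (F_ST) = sum(a) / sum(a + b + c)
    f     (F_IS) = 1 - sum(c) / sum(b + c)
    F     (F_IT) = 1 - sum(c) / sum(a + b + c)

so (1 - F_IT) = (1 - F_IS)(1 - F_ST) holds exactly by construction.
Confidence intervals bootstrap loci with replacement; p-values permute
population labels of individuals (F_ST) or re-pair allele copies within
populations (F_IS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeDataset


@dataclass(frozen=True)
class LocusComponents:
    """Weir–Cockerham variance components at one locus."""

    a: float
    b: float
    c: float
    informative: bool = True

    @property
    def total(self) -> float:
        return self.a + self.b + self.c


@dataclass(frozen=True)
class FStatResult:
    fst: float
    fis: float
    fit: float
    ci_fst: tuple[float, float] | None = None
    ci_fis: tuple[float, float] | None = None
    ci_fit: tuple[float, float] | None = None
    p_fst: float | None = None
    p_fis: float | None = None
    n_boot: int = 0
    n_perm: int = 0
    seed: int = 0


def wright_identity(fis: float, fst: float) -> float:
    """Total inbreeding from Wright's identity (1−F_IT) = (1−F_IS)(1−F_ST)."""
    return 1.0 - (1.0 - fis) * (1.0 - fst)


def _pop_stats(ds: GenotypeDataset):
    """Per-population per-locus (n, p, h): sample size, allele freq, het freq."""
    pops = ds.populations
    g = ds.genotypes
    n = np.zeros((len(pops), ds.n_snps))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, pop in enumerate(pops):
        sub = g[ds.population_mask(pop)]
        obs = sub != MISSING
        cnt = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(cnt > 0, np.where(obs, sub, 0).sum(axis=0) / (2 * cnt), np.nan)
            h[k] = np.where(cnt > 0, (obs & (sub == 1)).sum(axis=0) / cnt, np.nan)
        n[k] = cnt
    return pops, n, p, h


def _wc_components_arrays(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Vectorized 1984 a/b/c over loci.

    ``n, p, h`` have shape (r populations, m loci); populations with zero
    calls at a locus are excluded from that locus.  Returns (a, b, c,
    informative) arrays of length m.
    """
    have = n > 0
    r = have.sum(axis=0).astype(float)
    n_sum = np.where(have, n, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - np.where(have, n * n, 0).sum(axis=0) / n_sum) / (r - 1)
        pbar = np.where(have, n * np.nan_to_num(p), 0).sum(axis=0) / n_sum
        s2 = np.where(have, n * (np.nan_to_num(p) - pbar) ** 2, 0).sum(axis=0) / (
            (r - 1) * nbar
        )
        hbar = np.where(have, n * np.nan_to_num(h), 0).sum(axis=0) / n_sum
        a = (nbar / nc) * (
            s2
            - (1 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2
    mono = (pbar <= 0) | (pbar >= 1)
    bad = (r < 2) | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    informative = ~(mono | bad)
    a = np.where(informative, a, 0.0)
    b = np.where(informative, b, 0.0)
    c = np.where(informative, c, 0.0)
    return a, b, c, informative


def wc_locus_components(counts_by_population: dict[str, tuple[int, int, int]]) -> LocusComponents:
    """Components at one locus from per-population genotype counts.

    ``counts_by_population`` maps a label to (n_hom_ref, n_het, n_hom_alt)
    counts of the three genotype classes among non-missing calls.
    """
    labels = [k for k, v in counts_by_population.items() if sum(v) > 0]
    if len(labels) < 2:
        raise ValueError("need >= 2 populations with data at the locus")
    n = np.zeros((len(labels), 1))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for i, lab in enumerate(labels):
        n0, n1, n2 = counts_by_population[lab]
        tot = n0 + n1 + n2
        n[i, 0] = tot
        p[i, 0] = (n1 + 2 * n2) / (2 * tot)
        h[i, 0] = n1 / tot
    a, b, c, info = _wc_components_arrays(n, p, h)
    return LocusComponents(float(a[0]), float(b[0]), float(c[0]), bool(info[0]))


def _ratios(a, b, c):
    """Ratio-of-sums (theta, f, F) over the given component arrays."""
    A, B, C = a.sum(), b.sum(), c.sum()
    tot = A + B + C
    theta = A / tot if tot != 0 else 0.0
    f = 1 - C / (B + C) if (B + C) != 0 else 0.0
    F = 1 - C / tot if tot != 0 else 0.0
    return float(theta), float(f), float(F)


def _within_pop_f(ds: GenotypeDataset, population: str) -> float:
    """Single-population Weir–Cockerham f = 1 − Σc/Σ(b+c).

    With one population the among-population level vanishes; b and c reduce
    to the standard within-population forms with r = 1.
    """
    g = ds.genotypes[ds.population_mask(population)]
    obs = g != MISSING
    n = obs.sum(axis=0).astype(float)
    ok = n > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g, 0).sum(axis=0) / (2 * n)
        h = (obs & (g == 1)).sum(axis=0) / n
        b = (n / (n - 1)) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
    c = h / 2
    b = np.where(ok, b, 0.0)
    c = np.where(ok, c, 0.0)
    denom = (b + c).sum()
    if denom == 0:
        return 0.0
    return float(1 - c.sum() / denom)


def global_fstats(
    ds: GenotypeDataset,
    n_boot: int = 0,
    n_perm: int = 0,
    seed: int = 0,
) -> FStatResult:
    """Multi-locus F_ST/F_IS/F_IT with optional bootstrap CIs and permutation
    p-values.

    Bootstrap resamples loci with replacement (95% percentile CIs).
    Permutations: individuals' population labels are shuffled for the F_ST
    p-value; allele copies are re-paired within populations for F_IS.
    """
    if len(ds.populations) < 2:
        raise ValueError("need >= 2 populations")
    _, n, p, h = _pop_stats(ds)
    a, b, c, info = _wc_components_arrays(n, p, h)
    theta, f, F = _ratios(a, b, c)

    rng = np.random.default_rng(seed)
    ci_fst = ci_fis = ci_fit = None
    if n_boot > 0:
        idx = rng.integers(0, a.size, size=(n_boot, a.size))
        A = a[idx].sum(axis=1)
        B = b[idx].sum(axis=1)
        C = c[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            th = A / (A + B + C)
            fi = 1 - C / (B + C)
            ft = 1 - C / (A + B + C)
        ci_fst = tuple(np.nanpercentile(th, [2.5, 97.5]))
        ci_fis = tuple(np.nanpercentile(fi, [2.5, 97.5]))
        ci_fit = tuple(np.nanpercentile(ft, [2.5, 97.5]))

    p_fst = p_fis = None
    if n_perm > 0:
        p_fst = _permute_fst(ds, theta, n_perm, rng)
        p_fis = _permute_fis(ds, f, n_perm, rng)

    return FStatResult(
        fst=theta, fis=f, fit=F,
        ci_fst=ci_fst, ci_fis=ci_fis, ci_fit=ci_fit,
        p_fst=p_fst, p_fis=p_fis,
        n_boot=n_boot, n_perm=n_perm, seed=seed,
    )


def _theta_from_matrix(g: np.ndarray, pop_codes: np.ndarray) -> float:
    """theta for a genotype matrix given integer population codes."""
    K = pop_codes.max() + 1
    m = g.shape[1]
    n = np.zeros((K, m))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k in range(K):
        sub = g[pop_codes == k]
        obs = sub != MISSING
        cnt = obs.sum(axis=0).astype(float)
        n[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(cnt > 0, np.where(obs, sub, 0).sum(axis=0) / (2 * cnt), np.nan)
            h[k] = np.where(cnt > 0, (obs & (sub == 1)).sum(axis=0) / cnt, np.nan)
    a, b, c, _ = _wc_components_arrays(n, p, h)
    return _ratios(a, b, c)[0]


def _permute_fst(ds, observed, n_perm, rng):
    pops = ds.populations
    codes = np.array([pops.index(s.population) for s in ds.samples])
    g = ds.genotypes
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _theta_from_matrix(g, perm) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def shuffle_alleles_within(sub: np.ndarray, rng) -> np.ndarray:
    """Re-pair allele copies among individuals at every locus of one
    population's dosage block (vectorized over loci).

    Each column's observed allele copies are randomly re-paired into
    genotypes, preserving allele counts but breaking within-individual
    correlation; missing calls stay missing.
    """
    n, m = sub.shape
    obs = sub != MISSING
    ones = np.where(obs, sub, 0).sum(axis=0)  # minor copies per locus
    # one random key per allele slot; missing slots sort last
    keys = rng.random((2 * n, m))
    keys[np.repeat(~obs, 2, axis=0)] = 2.0
    ranks = np.argsort(np.argsort(keys, axis=0, kind="stable"), axis=0)
    vals = (ranks < ones[None, :]).astype(np.int8)
    out = (vals[0::2] + vals[1::2]).astype(np.int8)
    out[~obs] = MISSING
    return out


def _permute_fis(ds, observed, n_perm, rng):
    """Re-pair allele copies within each population, recompute f."""
    pops = ds.populations
    g = ds.genotypes
    masks = [ds.population_mask(p) for p in pops]
    hits = 0
    for _ in range(n_perm):
        newg = g.copy()
        for mask in masks:
            newg[mask] = shuffle_alleles_within(g[mask], rng)
        _, n, p, h = _pop_stats(GenotypeDataset(newg, list(ds.snps), list(ds.samples)))
        a, b, c, _ = _wc_components_arrays(n, p, h)
        f = _ratios(a, b, c)[1]
        if f >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def pairwise_fst(ds: GenotypeDataset, min_samples: int = 2) -> tuple[list[str], np.ndarray]:
    """Weir–Cockerham theta for every population pair.

    Returns (labels, matrix) with a zero diagonal and symmetric entries; each
    pair's theta uses only that pair's samples.  Populations with fewer than
    ``min_samples`` individuals are excluded.
    """
    pops = [
        p for p in ds.populations
        if int(ds.population_mask(p).sum()) >= min_samples
    ]
    K = len(pops)
    if K < 2:
        raise ValueError("need >= 2 populations with enough samples")
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            mask = ds.population_mask(pops[i]) | ds.population_mask(pops[j])
            sub = ds.subset(np.flatnonzero(mask))
            res = global_fstats(sub)
            out[i, j] = out[j, i] = res.fst
    return pops, out
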