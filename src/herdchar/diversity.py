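"""Within-population diversity: MAF, observed/expected heterozygosity, F_IS.

Per population and per SNP (complete-case over non-missing calls):

* H_O — fraction of heterozygous genotypes,
* H_E — unbiased (Nei 1978) expectation (2n/(2n−1)) · 2·p̂(1−p̂),
* MAF — min(p̂, 1−p̂) of the globally oriented minor allele.

Means and SDs are across SNPs; loci monomorphic within the population
contribute H_O = H_E = 0 (genome-wide-mean semantics) while loci with no
calls are excluded.  F_IS is the Weir–Cockerham within-population f (which
can be negative under heterozygote excess); the plain 1 − H̄_O/H̄_E form is
exposed for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeDataset
from .fstats import _within_pop_f


@dataclass(frozen=True)
class DiversitySummary:
    population: str
    n: int
    maf_mean: float
    maf_sd: float
    ho_mean: float
    ho_sd: float
    he_mean: float
    he_sd: float
    fis: float
    fis_simple: float
    monomorphic: bool = False


def pop_allele_freq(ds: GenotypeDataset, population: str) -> np.ndarray:
    """Per-SNP frequency of the globally oriented minor allele within one
    population; NaN where the population has no calls at the locus."""
    g = ds.genotypes[ds.population_mask(population)]
    obs = g != MISSING
    cnt = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs, g, 0).sum(axis=0) / (2 * cnt)
    return np.where(cnt > 0, freq, np.nan)


def _per_pop_stats(g: np.ndarray, unbiased: bool = True):
    obs = g != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g, 0).sum(axis=0) / (2 * n)
        ho = (obs & (g == 1)).sum(axis=0) / n
        he = 2 * p * (1 - p)
        if unbiased:
            he = he * (2 * n) / (2 * n - 1)
    maf = np.minimum(p, 1 - p)
    defined = n > (1 if unbiased else 0)
    return p, ho, he, maf, defined


def diversity_summary(
    ds: GenotypeDataset, unbiased_he: bool = True
) -> list[DiversitySummary]:
    """Per-population diversity table; populations of size 1 are excluded."""
    out = []
    for pop in ds.populations:
        mask = ds.population_mask(pop)
        n_ind = int(mask.sum())
        if n_ind < 2:
            continue
        g = ds.genotypes[mask]
        _, ho, he, maf, defined = _per_pop_stats(g, unbiased=unbiased_he)
        ho, he, maf = ho[defined], he[defined], maf[defined]
        if ho.size == 0:
            continue
        he_bar = float(he.mean())
        ho_bar = float(ho.mean())
        mono = he_bar == 0
        fis_simple = 0.0 if mono else float(1 - ho_bar / he_bar)
        fis = 0.0 if mono else _within_pop_f(ds, pop)
        out.append(
            DiversitySummary(
                population=pop,
                n=n_ind,
                maf_mean=float(maf.mean()),
                maf_sd=float(maf.std(ddof=1)) if maf.size > 1 else 0.0,
                ho_mean=ho_bar,
                ho_sd=float(ho.std(ddof=1)) if ho.size > 1 else 0.0,
                he_mean=he_bar,
                he_sd=float(he.std(ddof=1)) if he.size > 1 else 0.0,
                fis=fis,
                fis_simple=fis_simple,
                monomorphic=mono,
            )
        )
    if not out:
        raise ValueError("no population with >= 2 samples and defined loci")
    return out
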