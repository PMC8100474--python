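"""Synthetic genotype generators with known truth for estimator validation.

Three complementary models:

* **Balding–Nichols** — K island populations whose per-population allele
  frequencies are Beta-distributed around an ancestral frequency with
  dispersion set by a target F_ST.  Gives a closed-form differentiation
  target for the F-statistic and distance estimators.
* **Forward Wright–Fisher** — discrete non-overlapping generations of 2N
  haplotypes with random mating and Poisson recombination along a chromosome,
  under an arbitrary step trajectory of N_e.  Validates LD decay and the
  LD-based historical N_e estimator.
* **Admixture mixing** — genotypes drawn from known ancestry fractions Q and
  source frequencies F, the generative model the admixture EM inverts.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genio import MISSING, GenotypeDataset, SampleRecord, SnpRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaldingNicholsSpec:
    """Island-model spec: ``fst`` may be a scalar or one value per population."""

    n_pops: int
    n_per_pop: int
    n_loci: int
    fst: float | tuple[float, ...] = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def fst_vector(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_pops,))
        if not ((f > 0) & (f < 1)).all():
            raise ValueError("fst values must lie in (0, 1)")
        return f

    def __post_init__(self):
        if self.n_per_pop < 2:
            raise ValueError("n_per_pop must be >= 2")
        self.fst_vector()


@dataclass(frozen=True)
class WrightFisherSpec:
    """Forward-simulation spec.

    ``ne_trajectory`` is a list of (generation_span, N_e) steps applied from
    past to present; their spans must sum to ``n_generations``.  Loci start in
    linkage equilibrium at uniform intermediate frequencies, so early
    generations serve as burn-in toward drift–recombination equilibrium.
    """

    ne_trajectory: tuple[tuple[int, int], ...]
    chrom_length_bp: int
    recomb_rate: float  # per bp per generation
    n_loci: int
    n_sample: int  # diploid individuals sampled at the end
    n_generations: int
    mutation_rate: float = 0.0  # symmetric flip per site per generation
    init_maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self):
        if any(ne < 2 for _, ne in self.ne_trajectory):
            raise ValueError("all N_e must be >= 2")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if sum(span for span, _ in self.ne_trajectory) != self.n_generations:
            raise ValueError("trajectory spans must sum to n_generations")


@dataclass(frozen=True)
class AdmixtureSpec:
    """Known ancestry fractions Q (individuals × K) and source frequencies F
    (K × loci)."""

    Q: np.ndarray
    F: np.ndarray
    seed: int = 0

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        F = np.asarray(self.F, dtype=float)
        if not np.allclose(Q.sum(axis=1), 1.0):
            raise ValueError("each row of Q must sum to 1")
        if ((F < 0) | (F > 1)).any():
            raise ValueError("F entries must lie in [0, 1]")
        if Q.shape[1] != F.shape[0]:
            raise ValueError("Q columns must match F rows (K)")


def _orient_minor(geno: np.ndarray) -> np.ndarray:
    """Flip columns so the stored dosage counts the pooled minor allele
    (strict majority; exact ties keep the original orientation)."""
    obs = np.ma.masked_equal(geno, MISSING)
    freq = obs.mean(axis=0).filled(0) / 2
    out = geno.copy()
    flip = freq > 0.5
    cols = out[:, flip]
    out[:, flip] = np.where(cols == MISSING, MISSING, 2 - cols)
    return out.astype(np.int8)


def _snp_map(n_loci: int, chrom: str = "1", spacing: int = 1000) -> list[SnpRecord]:
    return [
        SnpRecord(f"snp{j + 1}", chrom, (j + 1) * spacing) for j in range(n_loci)
    ]


def simulate_balding_nichols(spec: BaldingNicholsSpec) -> GenotypeDataset:
    """Draw genotypes under the Balding–Nichols island model.

    Per locus an ancestral frequency p is uniform on ``ancestral_maf_range``;
    population k draws p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) and
    individuals draw dosages Binomial(2, p_k).
    """
    rng = np.random.default_rng(spec.seed)
    f = spec.fst_vector()
    lo, hi = spec.ancestral_maf_range
    p = rng.uniform(lo, hi, size=spec.n_loci)
    # Redraw any degenerate ancestral frequency (possible only at range ends).
    while ((p <= 0) | (p >= 1)).any():
        bad = (p <= 0) | (p >= 1)
        p[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
    blocks = []
    samples = []
    for k in range(spec.n_pops):
        ratio = (1 - f[k]) / f[k]
        pk = rng.beta(p * ratio, (1 - p) * ratio)
        pk = np.clip(pk, 1e-12, 1 - 1e-12)
        g = rng.binomial(2, pk, size=(spec.n_per_pop, spec.n_loci))
        blocks.append(g.astype(np.int8))
        samples += [
            SampleRecord(f"pop{k + 1}_ind{i + 1}", f"pop{k + 1}")
            for i in range(spec.n_per_pop)
        ]
    return GenotypeDataset(_orient_minor(np.vstack(blocks)), _snp_map(spec.n_loci), samples)


def simulate_wright_fisher(spec: WrightFisherSpec) -> GenotypeDataset:
    """Forward Wright–Fisher simulation of one chromosome.

    Haplotypes are 0/1 arrays over ``n_loci`` positions placed evenly on the
    chromosome.  Each generation every offspring haplotype is a recombinant of
    one diploid parent's two haplotypes: crossover indicators between adjacent
    loci are Bernoulli with the Haldane inter-locus recombination fraction,
    and a cumulative-XOR selects the transmitted parent strand.  Loci
    monomorphic in the final sample are dropped with a logged count.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_loci
    positions = np.linspace(1, spec.chrom_length_bp, L).round().astype(np.int64)
    positions = np.maximum.accumulate(positions)  # keep sorted under rounding
    d_bp = np.diff(positions).astype(float)
    # Haldane map: recombination fraction between adjacent loci.
    c_adj = 0.5 * (1 - np.exp(-2 * spec.recomb_rate * d_bp))

    ne0 = spec.ne_trajectory[0][1]
    p0 = rng.uniform(*spec.init_maf_range, size=L)
    hap = (rng.random((2 * ne0, L)) < p0).astype(np.int8)

    for span, ne in spec.ne_trajectory:
        for _ in range(span):
            n_hap = 2 * ne
            parents = rng.integers(0, hap.shape[0] // 2, size=n_hap)
            h1 = hap[2 * parents]
            h2 = hap[2 * parents + 1]
            cross = rng.random((n_hap, L - 1)) < c_adj
            start = rng.integers(0, 2, size=n_hap)
            strand = np.empty((n_hap, L), dtype=np.int8)
            strand[:, 0] = start
            strand[:, 1:] = (start[:, None] + np.cumsum(cross, axis=1)) % 2
            hap = np.where(strand == 0, h1, h2).astype(np.int8)
            if spec.mutation_rate > 0:
                flips = rng.random(hap.shape) < spec.mutation_rate
                hap = np.where(flips, 1 - hap, hap).astype(np.int8)

    n_hap_final = hap.shape[0]
    if 2 * spec.n_sample > n_hap_final:
        raise ValueError("n_sample exceeds final population size")
    pick = rng.choice(n_hap_final // 2, size=spec.n_sample, replace=False)
    geno = (hap[2 * pick] + hap[2 * pick + 1]).astype(np.int8)

    poly = (geno.min(axis=0) < geno.max(axis=0))
    dropped = int(L - poly.sum())
    if dropped:
        logger.info("dropped %d monomorphic loci from WF sample", dropped)
    keep = np.flatnonzero(poly)
    # Orient to the sample minor allele.
    geno = geno[:, keep]
    freq = geno.mean(axis=0) / 2
    flip = freq > 0.5
    geno[:, flip] = 2 - geno[:, flip]
    snps = [SnpRecord(f"wf{j + 1}", "1", int(positions[j])) for j in keep]
    samples = [SampleRecord(f"wf_ind{i + 1}", "wf") for i in range(spec.n_sample)]
    return GenotypeDataset(geno, snps, samples)


def simulate_admixed(spec: AdmixtureSpec) -> GenotypeDataset:
    """Draw genotypes from known ancestry fractions.

    Each of the two allele copies of individual i at locus j picks its source
    population from Q_i and its allele from that source's frequency at j.
    """
    rng = np.random.default_rng(spec.seed)
    Q = np.asarray(spec.Q, dtype=float)
    F = np.asarray(spec.F, dtype=float)
    n, K = Q.shape
    m = F.shape[1]
    geno = np.zeros((n, m), dtype=np.int8)
    for copy in range(2):
        u = rng.random((n, m, 1))
        cum = np.cumsum(Q, axis=1)[:, None, :]  # (n, 1, K)
        origin = (u < cum).argmax(axis=2)  # (n, m)
        p = F[origin, np.arange(m)[None, :]]
        geno += (rng.random((n, m)) < p).astype(np.int8)
    snps = _snp_map(m)
    samples = [SampleRecord(f"adm_ind{i + 1}", "admixed") for i in range(n)]
    return GenotypeDataset(_orient_minor(geno), snps, samples)


def inject_inbreeding(ds: GenotypeDataset, f_target: float, seed: int = 0) -> GenotypeDataset:
    """Introduce within-population inbreeding at level ``f_target``.

    Per locus and individual, with probability ``f_target`` the genotype is
    replaced by a homozygote whose allele is drawn at the population's allele
    frequency (identical-by-descent allele pair), so the expected deficit of
    heterozygotes — hence F_IS — is approximately ``f_target``.
    """
    if not (0 <= f_target < 1):
        raise ValueError("f_target must be in [0, 1)")
    if f_target == 0:
        return ds
    rng = np.random.default_rng(seed)
    geno = ds.genotypes.copy()
    for pop in ds.populations:
        mask = ds.population_mask(pop)
        sub = geno[mask]
        obs = np.ma.masked_equal(sub, MISSING)
        p = obs.mean(axis=0).filled(0) / 2  # per-locus frequency in this pop
        ibd = rng.random(sub.shape) < f_target
        allele = (rng.random(sub.shape) < p[None, :]).astype(np.int8)
        homo = 2 * allele
        replaced = np.where(ibd & (sub != MISSING), homo, sub)
        geno[mask] = replaced
    return GenotypeDataset(geno, list(ds.snps), list(ds.samples))
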