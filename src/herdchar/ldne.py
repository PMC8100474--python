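"""Pairwise r² linkage disequilibrium, decay binning, and LD-based N_e.

r² between two biallelic loci with haplotype frequency P_ab and allele
frequencies P_a, P_b:

    r² = (P_ab − P_a·P_b)² / (P_a(1−P_a)·P_b(1−P_b))

Unphased genotypes leave only the double-heterozygote phase ambiguous;
haplotype frequencies come from the standard EM over that ambiguity,
initialized at linkage equilibrium.

Historical effective population size follows the Sved/Corbin machinery: a
pair at recombination fraction c reflects the population roughly
t = 1/(2c) generations ago, and

    N_T(t) = (4·f(c_t))⁻¹ · (E[r²_adj | c_t]⁻¹ − α),   f(c) = c(1−c/2)/(1−c)²

with r²_adj = r² − 1/(2n) the sample-size adjustment (n diploid samples,
phased-style correction) and α ∈ {1, 2, 2.2} the mutation correction
(default 2.2).  Physical distance maps to c linearly at a configurable
cM/Mb (default 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HaplotypeFreqs:
    p_a: float
    p_b: float
    p_ab: float
    converged: bool = True

    def __post_init__(self):
        lo = max(0.0, self.p_a + self.p_b - 1.0)
        hi = min(self.p_a, self.p_b)
        if not (lo - 1e-9 <= self.p_ab <= hi + 1e-9):
            raise ValueError(
                f"P_ab={self.p_ab} violates Frechet bounds [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class LdPair:
    distance_bp: int
    r2: float
    chromosome: str


@dataclass(frozen=True)
class LdBin:
    lo_bp: int
    hi_bp: int
    mean_r2: float  # NaN when empty
    n_pairs: int
    representative_distance: float  # mean pair distance; midpoint if empty


@dataclass(frozen=True)
class NeTrajectory:
    """Rows of (generations ago, N_e, recombination fraction, adjusted r²)."""

    t: np.ndarray
    ne: np.ndarray
    c_t: np.ndarray
    mean_r2_adj: np.ndarray


def r2_from_haplotypes(h: HaplotypeFreqs) -> float:
    """Squared allelic correlation from haplotype and allele frequencies."""
    pa, pb = h.p_a, h.p_b
    if not (0 < pa < 1 and 0 < pb < 1):
        raise ValueError("r2 undefined at a monomorphic locus")
    d = h.p_ab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _em_pab(counts: np.ndarray, max_iter: int = 1000, tol: float = 1e-12):
    """Vectorized EM for P_ab over many locus pairs.

    ``counts``: (9, P) table of genotype-pair counts, index g1*3+g2 with g
    the minor-allele dosage.  Returns (p_a, p_b, p_ab, converged) arrays.
    """
    c = counts.astype(float)
    n = c.sum(axis=0)
    # allele frequencies straight from margins
    g1 = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], dtype=float)
    g2 = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = (c * g1[:, None]).sum(axis=0) / (2 * n)
        p_b = (c * g2[:, None]).sum(axis=0) / (2 * n)
    # phase-known haplotype counts (indices: g1*3+g2)
    n_ab = 2 * c[8] + c[7] + c[5]  # minor-minor haplotypes: (2,2)*2 + (2,1) + (1,2)
    dh = c[4]  # double heterozygotes (ambiguous phase)
    tot = 2 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        p11 = p_a * p_b  # init at linkage equilibrium
        converged = np.zeros(p11.shape, dtype=bool)
        for _ in range(max_iter):
            p10 = np.clip(p_a - p11, 1e-15, None)
            p01 = np.clip(p_b - p11, 1e-15, None)
            p00 = np.clip(1 - p_a - p_b + p11, 1e-15, None)
            cis = p11 * p00
            trans = p10 * p01
            pi = np.where(cis + trans > 0, cis / (cis + trans), 0.5)
            new = (n_ab + pi * dh) / tot
            new = np.clip(new, np.maximum(0, p_a + p_b - 1), np.minimum(p_a, p_b))
            done = np.abs(new - p11) < tol
            converged |= done
            p11 = new
            if done.all():
                break
    return p_a, p_b, p11, converged


def estimate_haplotype_freqs(
    g1: np.ndarray, g2: np.ndarray, max_iter: int = 1000
) -> HaplotypeFreqs:
    """MLE haplotype frequencies from two unphased dosage vectors.

    Complete-case over samples; EM resolves the double-heterozygote phase,
    deterministically initialized at linkage equilibrium.  When no double
    heterozygotes are present the result is the closed-form count.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    code = g1[ok].astype(int) * 3 + g2[ok].astype(int)
    counts = np.bincount(code, minlength=9).astype(float)[:, None]
    p_a, p_b, p_ab, conv = _em_pab(counts, max_iter=max_iter)
    if not conv[0]:
        logger.warning("haplotype EM did not converge; returning last iterate")
    return HaplotypeFreqs(float(p_a[0]), float(p_b[0]), float(p_ab[0]), bool(conv[0]))


def _pairwise_r2(
    g: np.ndarray, j1: np.ndarray, j2: np.ndarray, method: str = "em"
) -> np.ndarray:
    """r² for many column pairs of a dosage matrix (NaN where undefined)."""
    if method == "composite":
        out = np.full(j1.size, np.nan)
        for idx, (a, b) in enumerate(zip(j1, j2)):
            x = g[:, a].astype(float)
            y = g[:, b].astype(float)
            ok = (x != MISSING) & (y != MISSING)
            x, y = x[ok], y[ok]
            if x.size < 2 or x.var() == 0 or y.var() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            out[idx] = r * r
        return out
    x = g[:, j1]
    y = g[:, j2]
    ok = (x != MISSING) & (y != MISSING)
    code = np.where(ok, x.astype(np.int64) * 3 + y.astype(np.int64), 9)
    counts = np.stack([(code == k).sum(axis=0) for k in range(9)]).astype(float)
    p_a, p_b, p_ab, _ = _em_pab(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = p_ab - p_a * p_b
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    return r2


#: The 20 half-open decay bins (kb): [0,1), [1,10), [10,20) ... [90,100),
#: [100,200) ... [900,1000].
DECAY_BIN_EDGES_BP: tuple[int, ...] = tuple(
    [0, 1_000]
    + [k * 10_000 for k in range(1, 10)]
    + [k * 100_000 for k in range(1, 11)]
)


def _collect_pairs(ds, population, max_distance_bp):
    g = ds.genotypes[ds.population_mask(population)]
    pos = ds.positions()
    chroms = ds.chromosomes()
    j1_all, j2_all = [], []
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        for a in range(idx.size):
            upper = np.searchsorted(p, p[a] + max_distance_bp, side="right")
            for b in range(a + 1, upper):
                if p[b] > p[a]:
                    j1_all.append(idx[a])
                    j2_all.append(idx[b])
    return g, np.array(j1_all, dtype=int), np.array(j2_all, dtype=int)


def ld_decay(
    ds: GenotypeDataset,
    population: str,
    max_distance_bp: int = 1_000_000,
    method: str = "em",
    bin_edges_bp: tuple[int, ...] | None = None,
) -> list[LdBin]:
    """Mean r² in distance bins for all intra-chromosomal pairs.

    Default bins are the fixed 20-bin decay scheme up to 1 Mb; pass
    ``bin_edges_bp`` for alternatives (e.g. log-spaced bins for N_e).
    Empty bins are reported with ``n_pairs=0`` and a NaN mean.
    """
    edges = list(bin_edges_bp) if bin_edges_bp is not None else list(DECAY_BIN_EDGES_BP)
    g, j1, j2 = _collect_pairs(ds, population, max_distance_bp)
    if j1.size == 0:
        dist = np.empty(0)
        r2 = np.empty(0)
    else:
        pos = ds.positions()
        dist = (pos[j2] - pos[j1]).astype(float)
        r2 = _pairwise_r2(g, j1, j2, method=method)
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist >= lo) & (dist < hi) & np.isfinite(r2)
        npairs = int(sel.sum())
        bins.append(
            LdBin(
                lo_bp=int(lo),
                hi_bp=int(hi),
                mean_r2=float(r2[sel].mean()) if npairs else float("nan"),
                n_pairs=npairs,
                representative_distance=float(dist[sel].mean())
                if npairs
                else (lo + hi) / 2,
            )
        )
    return bins


def ne_bin_edges(lo_bp: int = 10_000, hi_bp: int = 4_000_000, n_bins: int = 20):
    """Default N_e binning: log-spaced edges covering recent and ancient t."""
    return tuple(np.unique(np.geomspace(lo_bp, hi_bp, n_bins + 1).round().astype(int)))


def sved_f(c: float | np.ndarray) -> float | np.ndarray:
    """Sved's mapping f(c) = c·(1−c/2)/(1−c)² between recombination fraction
    and expected LD."""
    c = np.asarray(c, dtype=float)
    if (c <= 0).any() or (c >= 1).any():
        raise ValueError("recombination fraction must lie in (0, 1)")
    out = c * (1 - c / 2) / (1 - c) ** 2
    return float(out) if out.ndim == 0 else out


def ne_trajectory(
    bins: list[LdBin],
    n_sample: int,
    alpha: float = 2.2,
    cm_per_mb: float = 1.0,
) -> NeTrajectory:
    """Historical N_e from binned LD.

    Per bin: c_t from the representative distance at ``cm_per_mb``,
    r²_adj = mean_r2 − 1/(2·n_sample), t = round(1/(2c_t)) and
    N_T(t) = (4f(c_t))⁻¹(1/r²_adj − α).  Bins with undefined means or
    non-positive adjusted LD signal (which would imply negative N_e) are
    dropped with a warning.  Rows come back sorted by t ascending.
    """
    rows = []
    for b in bins:
        if b.n_pairs == 0 or not np.isfinite(b.mean_r2):
            continue
        c = b.representative_distance * (cm_per_mb / 100.0) / 1e6
        if not (0 < c < 1):
            logger.warning("bin %s-%s: recombination fraction %g out of range", b.lo_bp, b.hi_bp, c)
            continue
        r2_adj = b.mean_r2 - 1.0 / (2 * n_sample)
        if r2_adj <= 0 or 1.0 / r2_adj <= alpha:
            logger.warning(
                "bin %s-%s dropped: adjusted r2 %.4g gives non-positive N_e",
                b.lo_bp, b.hi_bp, r2_adj,
            )
            continue
        t = max(1, int(round(1.0 / (2 * c))))
        ne = (1.0 / (4 * sved_f(c))) * (1.0 / r2_adj - alpha)
        rows.append((t, ne, c, r2_adj))
    rows.sort(key=lambda r: r[0])
    arr = np.array(rows, dtype=float).reshape(-1, 4)
    return NeTrajectory(
        t=arr[:, 0].astype(int),
        ne=arr[:, 1],
        c_t=arr[:, 2],
        mean_r2_adj=arr[:, 3],
    )
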