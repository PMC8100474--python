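"""Allele-frequency PCA and model-based admixture with cross-validation.

PCA uses Patterson scaling: each SNP column is mean-centered and divided by
sqrt(p(1-p)) with p the column mean frequency; missing calls are imputed to
the column mean.  Scores come from the eigendecomposition of the sample
covariance; explained fractions are eigenvalue / trace.

Admixture fits the binomial mixture likelihood

    L(Q, F) = sum_ij [ g_ij log(sum_k q_ik f_kj)
                       + (2 - g_ij) log(sum_k q_ik (1 - f_kj)) ]

by plain EM (FRAPPE-style multiplicative updates) from a seeded random
start; missing entries are skipped.  The log-likelihood is non-decreasing at
every iteration — asserted in the test suite.  K is chosen by masking random
genotype entries, refitting on the rest and scoring squared deviation of the
masked dosages from their fitted expectation 2*sum_k q_ik f_kj.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

_F_EPS = 1e-6


@dataclass(frozen=True)
class PcaResult:
    coordinates: np.ndarray  # samples x k
    explained: np.ndarray  # fraction of total variance per PC


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # samples x K
    F: np.ndarray  # K x SNPs
    loglik: float
    loglik_path: np.ndarray
    cv_error: float | None = None
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 2000
    converged: bool = False


def pca_genotypes(ds: GenotypeDataset, k: int = 10, breed_level: bool = False) -> PcaResult:
    """Principal components of the genotype matrix (Patterson scaling).

    ``breed_level=True`` runs the PCA on the populations × SNPs allele
    frequency matrix instead of individuals (useful when the interesting
    structure is between groups).  Monomorphic SNPs are skipped.
    """
    if breed_level:
        from .diversity import pop_allele_freq

        rows = [pop_allele_freq(ds, p) for p in ds.populations]
        X = 2 * np.vstack(rows)  # dosage scale
    else:
        X = ds.genotypes.astype(float)
        X[X == MISSING] = np.nan
    n = X.shape[0]
    if not (0 < k < min(n, X.shape[1]) + 1):
        raise ValueError("k must be in [1, min(samples, snps)]")
    mean = np.nanmean(X, axis=0)
    p = mean / 2
    keep = (p > 0) & (p < 1) & np.isfinite(p)
    X = X[:, keep]
    mean = mean[keep]
    p = p[keep]
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    Z = (X - mean) / np.sqrt(p * (1 - p))
    cov = Z @ Z.T / Z.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0, None)
    total = vals.sum()
    k = min(k, vals.size)
    coords = vecs[:, :k] * np.sqrt(vals[:k])[None, :]
    explained = vals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(coordinates=coords, explained=explained)


def _init_qf(n: int, m: int, K: int, rng) -> tuple[np.ndarray, np.ndarray]:
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, m))
    return Q, F


def _loglik(G, W, Q, F):
    P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
    with np.errstate(invalid="ignore"):
        ll = W * (G * np.log(P) + (2 - G) * np.log(1 - P))
    return float(np.nansum(ll))


def admixture_em(
    ds: GenotypeDataset,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    weights: np.ndarray | None = None,
) -> AdmixtureFit:
    """Fit the K-cluster admixture model by EM.

    ``weights`` (samples × SNPs in {0,1}) optionally masks entries out of the
    likelihood — used by :func:`cv_error`.  Missing genotypes are always
    masked.  Q rows are renormalized each step; F is clipped to
    [1e-6, 1−1e-6] for numerical stability.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ds.n_samples:
        raise ValueError("K exceeds the number of samples")
    G = ds.genotypes.astype(float)
    W = (ds.genotypes != MISSING).astype(float)
    if weights is not None:
        W = W * weights
    G = np.where(W > 0, G, 0.0)
    n, m = G.shape
    rng = np.random.default_rng(seed)
    Q, F = _init_qf(n, m, K, rng)
    if K == 1:
        # closed-form MLE: pooled frequency per SNP
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (W * G).sum(axis=0) / (2 * W.sum(axis=0))
        F = np.clip(np.nan_to_num(f), _F_EPS, 1 - _F_EPS)[None, :]
        Q = np.ones((n, 1))
        ll = _loglik(G, W, Q, F)
        return AdmixtureFit(K=1, Q=Q, F=F, loglik=ll,
                            loglik_path=np.array([ll]), seed=seed,
                            tol=tol, max_iter=max_iter, converged=True)

    path = []
    ll_old = -np.inf
    converged = False
    Gc = 2 - G
    for it in range(max_iter):
        P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)  # n x m
        # responsibilities aggregated analytically:
        #   A = sum_j w g q f / P   (minor-allele copies to cluster k)
        #   B = sum_j w (2-g) q (1-f) / (1-P)
        WG = W * G / P
        WC = W * Gc / (1 - P)
        A = Q * (WG @ F.T)  # n x K
        B = Q * (WC @ (1 - F).T)
        denom = (2 * W).sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Qn = (A + B) / denom
        Qn = np.where(denom > 0, Qn, 1.0 / K)
        Qn /= Qn.sum(axis=1, keepdims=True)
        # F update: per (k, j) expected minor copies / expected total copies
        num = F * (Q.T @ WG)  # K x m
        den = num + (1 - F) * (Q.T @ WC)
        with np.errstate(invalid="ignore", divide="ignore"):
            Fn = num / den
        Fn = np.where(den > 0, Fn, F)
        Q = Qn
        F = np.clip(Fn, _F_EPS, 1 - _F_EPS)
        ll = _loglik(G, W, Q, F)
        path.append(ll)
        if ll - ll_old < tol and it > 0:
            converged = True
            break
        ll_old = ll
    return AdmixtureFit(
        K=K, Q=Q, F=F, loglik=path[-1], loglik_path=np.array(path),
        seed=seed, tol=tol, max_iter=max_iter, converged=converged,
    )


def cv_error(
    ds: GenotypeDataset,
    K: int,
    folds: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> float:
    """Entry-masking cross-validation error for one K.

    Non-missing genotype entries are partitioned into ``folds`` random folds;
    each fold is masked in turn, the model refit on the rest, and masked
    dosages scored by squared deviation from 2 * sum_k q_ik f_kj.  Returns the
    root mean squared deviation over all masked entries.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    present = ds.genotypes != MISSING
    entries = np.argwhere(present)
    if entries.size == 0:
        warnings.warn("no genotype entries to mask; CV error 0 by convention")
        return 0.0
    assign = rng.integers(0, folds, size=entries.shape[0])
    G = ds.genotypes.astype(float)
    sq = 0.0
    cnt = 0
    for fold in range(folds):
        mask = np.ones_like(G)
        rows = entries[assign == fold]
        mask[rows[:, 0], rows[:, 1]] = 0.0
        fit = admixture_em(
            ds, K, seed=int(rng.integers(2**31)), tol=tol,
            max_iter=max_iter, weights=mask,
        )
        pred = 2 * np.clip(fit.Q @ fit.F, 0, 1)
        diffs = G[rows[:, 0], rows[:, 1]] - pred[rows[:, 0], rows[:, 1]]
        sq += float((diffs**2).sum())
        cnt += rows.shape[0]
    return float(np.sqrt(sq / cnt))
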