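"""Admixture estimation by maximum-likelihood EM, Evanno's delta-K, PCA, and
discriminant analysis of principal components (DAPC).

The admixture model is the standard one: accession i's genotype at locus l is
Binomial(2, f_il) with f_il = sum_k q_ik p_kl, where q_ik are membership
coefficients and p_kl cluster allele frequencies.  Q and P are estimated by
alternating EM updates of the complete-data log-likelihood; a multi-restart
wrapper guards against local optima.  This is the frequentist counterpart of
Bayesian MCMC clustering: same estimands, orders of magnitude faster, and
deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotype_io import GenotypeMatrix

__all__ = [
    "AncestryResult",
    "DeltaKTable",
    "em_admixture",
    "per_chromosome_ancestry",
    "evanno_delta_k",
    "pca",
    "dapc",
]

_P_EPS = 1e-6  # cluster allele frequencies clamped to [eps, 1-eps]


@dataclass
class AncestryResult:
    """Membership coefficients Q (accessions x K) and cluster frequencies P (K x SNPs)."""

    accessions: list[str]
    Q: np.ndarray
    P: np.ndarray
    loglik: float
    K: int
    seed: int
    scope: str = "genome-wide"
    converged: bool = True
    n_iter: int = 0
    cluster_names: Optional[list[str]] = None

    def __post_init__(self):
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if (self.Q < -1e-12).any() or (self.Q > 1 + 1e-12).any():
            raise ValueError("Q entries must lie in [0, 1]")

    def q_of(self, accession: str, cluster: int) -> float:
        return float(self.Q[self.accessions.index(accession), cluster])

    def to_tsv(self, path) -> None:
        cols = self.cluster_names or [f"Q{k + 1}" for k in range(self.K)]
        pd.DataFrame(self.Q, index=self.accessions, columns=cols).to_csv(
            path, sep="\t", index_label="accession")


@dataclass
class DeltaKTable:
    """Evanno summary per K: mean L(K), sd, |L''(K)|, delta K (NaN where undefined)."""

    table: pd.DataFrame

    def best_k(self) -> int:
        t = self.table.dropna(subset=["delta_k"])
        if t.empty:
            raise ValueError("delta K undefined for every interior K")
        return int(t["delta_k"].idxmax())


def _binom_loglik(D: np.ndarray, F: np.ndarray) -> float:
    # binomial coefficient terms: log C(2, g) = log 2 for g == 1, else 0
    const = float(np.log(2.0) * (D == 1.0).sum())
    return const + float((D * np.log(F) + (2.0 - D) * np.log(1.0 - F)).sum())


def _em_once(D: np.ndarray, K: int, rng: np.random.Generator, max_iter: int,
             tol: float, fixed_rows: Optional[np.ndarray] = None,
             fixed_Q: Optional[np.ndarray] = None):
    n, L = D.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(rng.random((K, L)) * 0.5 + D.mean(axis=0) / 4.0, _P_EPS, 1 - _P_EPS)
    if fixed_rows is not None:
        Q[fixed_rows] = fixed_Q
    prev = -np.inf
    converged = False
    it = 0
    ll = -np.inf
    D2 = 2.0 - D
    for it in range(1, max_iter + 1):
        F = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)  # (n, L)
        ll = _binom_loglik(D, F)
        if ll < prev - 1e-8 * (1.0 + abs(prev)):
            raise AssertionError(
                f"EM log-likelihood decreased ({prev:.6f} -> {ll:.6f})")
        if ll - prev < tol:
            converged = True
            break
        prev = ll
        # responsibilities: expected allele copies attributed to cluster k
        alt_over_f = D / F
        ref_over_f = D2 / (1.0 - F)
        new_P = np.empty_like(P)
        new_Q = np.empty_like(Q)
        for k in range(K):
            alt_k = Q[:, k, None] * P[k][None, :] * alt_over_f          # (n, L)
            ref_k = Q[:, k, None] * (1.0 - P[k])[None, :] * ref_over_f
            tot_k = alt_k + ref_k
            new_P[k] = alt_k.sum(axis=0) / np.clip(tot_k.sum(axis=0), 1e-300, None)
            new_Q[:, k] = tot_k.sum(axis=1)
        P = np.clip(new_P, _P_EPS, 1 - _P_EPS)
        new_Q /= new_Q.sum(axis=1, keepdims=True)
        if fixed_rows is not None:
            new_Q[fixed_rows] = fixed_Q
        Q = new_Q
    return Q, P, ll, converged, it


def em_admixture(G: GenotypeMatrix, K: int, seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-3, supervised_labels: Optional[dict[str, int]] = None,
                 n_restarts: int = 5) -> AncestryResult:
    """Estimate admixture proportions by EM with multi-seed restarts.

    Maximises sum_il log Binomial(g_il | 2, sum_k q_ik p_kl).  In supervised
    mode, accessions named in ``supervised_labels`` (accession -> cluster
    index) have their Q rows fixed at the unit vector of their label.  The
    best of ``n_restarts`` runs (by log-likelihood) is returned; non-converged
    best runs are returned with ``converged=False`` and a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_accessions:
        raise ValueError(f"K={K} exceeds the number of accessions ({G.n_accessions})")
    D = G.dosage
    if np.isnan(D).any():
        raise ValueError("missing dosages present; impute before admixture analysis")

    if K == 1:
        P = np.clip(D.mean(axis=0, keepdims=True) / 2.0, _P_EPS, 1 - _P_EPS)
        Q = np.ones((G.n_accessions, 1))
        return AncestryResult(list(G.accessions), Q, P,
                              _binom_loglik(D, np.clip(Q @ P, _P_EPS, 1 - _P_EPS)),
                              K=1, seed=seed, n_iter=0)

    fixed_rows = fixed_Q = None
    if supervised_labels:
        fixed_rows = G.accession_index(list(supervised_labels))
        fixed_Q = np.zeros((len(fixed_rows), K))
        for r, (acc, k) in enumerate(supervised_labels.items()):
            if not 0 <= k < K:
                raise ValueError(f"label {k} for {acc!r} outside 0..{K - 1}")
            fixed_Q[r, k] = 1.0

    best = None
    root = np.random.default_rng(seed)
    for _ in range(max(n_restarts, 1)):
        rng = np.random.default_rng(root.integers(2 ** 31))
        Q, P, ll, conv, it = _em_once(D, K, rng, max_iter, tol, fixed_rows, fixed_Q)
        if best is None or ll > best[2]:
            best = (Q, P, ll, conv, it)
    Q, P, ll, conv, it = best
    if not conv:
        warnings.warn(f"EM did not converge within {max_iter} iterations (K={K})")
    return AncestryResult(list(G.accessions), Q, P, ll, K=K, seed=seed,
                          converged=conv, n_iter=it)


def per_chromosome_ancestry(G: GenotypeMatrix, K: int = 2, seed: int = 0,
                            min_snps: int = 20, max_iter: int = 500,
                            tol: float = 1e-3, n_restarts: int = 5,
                            supervised_labels: Optional[dict[str, int]] = None,
                            ) -> list[AncestryResult]:
    """Run the admixture EM separately on each chromosome, with aligned labels.

    Cluster labels are aligned across chromosomes by correlating each
    chromosome's P rows against the genome-wide cluster frequencies at that
    chromosome's SNPs, which removes label switching.  Chromosomes with fewer
    than ``min_snps`` mapped SNPs are skipped with a warning.
    """
    genome = em_admixture(G, K, seed=seed, max_iter=max_iter, tol=tol,
                          supervised_labels=supervised_labels,
                          n_restarts=n_restarts)
    results = []
    for chrom in G.chromosomes():
        mask = G.chrom_mask(chrom)
        if mask.sum() < min_snps:
            warnings.warn(f"{chrom}: only {int(mask.sum())} SNPs (< {min_snps}); skipped")
            continue
        sub = G.subset(snp_mask=mask)
        res = em_admixture(sub, K, seed=seed, max_iter=max_iter, tol=tol,
                           supervised_labels=supervised_labels,
                           n_restarts=n_restarts)
        perm = _align_clusters(res.P, genome.P[:, mask])
        res.Q = res.Q[:, perm]
        res.P = res.P[perm]
        res.scope = chrom
        results.append(res)
    return results


def _align_clusters(P: np.ndarray, P_ref: np.ndarray) -> np.ndarray:
    """Permutation of rows of P best matching P_ref (greedy max correlation)."""
    K = P.shape[0]
    sim = np.empty((K, K))
    for a in range(K):
        for b in range(K):
            x, y = P[a], P_ref[b]
            sx, sy = x.std(), y.std()
            sim[a, b] = (np.corrcoef(x, y)[0, 1] if sx > 0 and sy > 0
                         else -np.mean(np.abs(x - y)))
    perm = np.full(K, -1)
    used = set()
    for b in np.argsort(-sim.max(axis=0)):  # most confident reference first
        a = max((a for a in range(K) if a not in used), key=lambda a: sim[a, b])
        perm[b] = a
        used.add(a)
    return perm


def evanno_delta_k(runs: pd.DataFrame) -> DeltaKTable:
    """Evanno et al. delta-K from a table of (K, run, loglik) rows.

    delta K(K) = mean over runs |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)); defined
    only for interior K with >= 2 runs and sd > 0 (flagged NaN otherwise).
    """
    req = {"K", "run", "loglik"}
    if not req.issubset(runs.columns):
        raise ValueError(f"runs table must have columns {sorted(req)}")
    grp = runs.groupby("K")["loglik"]
    means, sds, counts = grp.mean(), grp.std(ddof=1), grp.count()
    if (counts < 2).any():
        raise ValueError("need >= 2 runs per K")
    ks = sorted(means.index)
    if ks != list(range(min(ks), max(ks) + 1)):
        raise ValueError("K values must be consecutive")
    rows = {}
    for k in ks:
        lpp = (abs(means[k + 1] - 2 * means[k] + means[k - 1])
               if (k - 1 in means and k + 1 in means) else np.nan)
        sd = sds[k]
        dk = lpp / sd if (not np.isnan(lpp) and sd > 0) else np.nan
        rows[k] = {"mean_loglik": means[k], "sd_loglik": sd,
                   "abs_l2": lpp, "delta_k": dk}
    return DeltaKTable(pd.DataFrame.from_dict(rows, orient="index"))


def pca(G: GenotypeMatrix, n_components: int = 10, scale: bool = False,
        ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centred (optionally unit-scaled) dosage matrix.

    Returns (scores, variance fractions); ``n_components`` beyond the matrix
    rank is truncated with a warning.
    """
    if G.n_accessions < 2:
        raise ValueError("PCA needs at least 2 accessions")
    X = G.dosage
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute before PCA")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    rank = min(G.n_accessions - 1, G.n_snps)
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncated")
        n_components = rank
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.explained_variance_ratio_


def dapc(G: GenotypeMatrix, classes: dict[str, str], n_pcs: int = 10,
         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Discriminant analysis of principal components.

    PCA reduces the dosage matrix to ``n_pcs`` scores, then linear
    discriminant analysis maximises among-class over within-class variance.
    Returns (per-accession posterior class memberships, per-SNP loadings).
    Loadings are squared discriminant contributions mapped back through the
    PCA rotation and normalised to sum to 1.
    """
    labels = np.array([classes[a] for a in G.accessions])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 classes")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"class {small!r} has fewer than 2 accessions")
    if n_pcs >= G.n_accessions - len(uniq):
        raise ValueError("n_pcs must be < accessions - classes")
    X = G.dosage - G.dosage.mean(axis=0)
    model = _SkPCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(X)
    lda = LinearDiscriminantAnalysis(solver="svd")
    try:
        lda.fit(scores, labels)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise ValueError("singular within-class scatter; use fewer PCs") from e
    post = pd.DataFrame(lda.predict_proba(scores), index=G.accessions,
                        columns=lda.classes_)
    # discriminant axes in SNP space: PCA components (n_pcs x SNPs)' @ scalings
    snp_axes = model.components_.T @ lda.scalings_  # (n_snps, n_axes)
    loadings = (snp_axes ** 2).sum(axis=1)
    total = loadings.sum()
    if total <= 0:
        raise ValueError("degenerate discriminant axes")
    return post, loadings / total
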