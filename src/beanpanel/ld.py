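"""Pairwise linkage disequilibrium, covariate-corrected r2, kinship, the
Hill-Weir decay model, and derived design quantities.

r2 is the squared Pearson correlation of dosage vectors, computed per
intrachromosomal SNP pair.  In a panel that is almost completely homozygous
this coincides with the haplotype-based composite r2.  Corrections follow the
structure/kinship logic of LD estimation with covariates: the structure mode
projects each dosage vector off the covariate column space before
correlating; the kinship mode whitens dosage vectors by the inverse square
root of the kinship matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .genotype_io import GenotypeMatrix

__all__ = [
    "LdPairs",
    "HillWeirFit",
    "pairwise_r2",
    "corrected_r2",
    "kinship_matrix",
    "fit_hill_weir",
    "decay_distance",
    "min_snp_count",
    "hill_weir_expectation",
]


@dataclass
class LdPairs:
    """Intrachromosomal SNP-pair table: chrom, both SNP ids, distance bp, r2."""

    table: pd.DataFrame  # columns: chrom, snp_a, snp_b, dist_bp, r2
    correction: str = "none"  # none | structure | kinship
    n_skipped_monomorphic: int = 0

    def __post_init__(self):
        t = self.table
        if len(t) and ((t["r2"] < -1e-9).any() or (t["r2"] > 1 + 1e-9).any()):
            raise ValueError("r2 outside [0, 1]")
        if len(t) and (t["dist_bp"] <= 0).any():
            raise ValueError("pair distances must be > 0")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def mean_r2(self, max_dist_bp: Optional[float] = None) -> float:
        t = self.table
        if max_dist_bp is not None:
            t = t[t["dist_bp"] <= max_dist_bp]
        return float(t["r2"].mean())


def _pairs_from_columns(G: GenotypeMatrix, X: np.ndarray,
                        max_dist_bp: Optional[float], correction: str) -> LdPairs:
    """Correlate columns of X (same layout as G.dosage) per chromosome."""
    frames = []
    skipped = 0
    for chrom in G.chromosomes():
        mask = G.chrom_mask(chrom)
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            continue
        sub = X[:, idx]
        sd = sub.std(axis=0)
        poly = sd > 1e-12
        m, k = idx.size, int(poly.sum())
        skipped += m * (m - 1) // 2 - k * (k - 1) // 2
        use = idx[poly]
        if use.size < 2:
            continue
        Z = (X[:, use] - X[:, use].mean(axis=0)) / X[:, use].std(axis=0)
        C = (Z.T @ Z) / Z.shape[0]
        r2 = np.clip(C ** 2, 0.0, 1.0)
        pos = G.snps["pos"].to_numpy()[use]
        ids = G.snps["id"].to_numpy()[use]
        iu, ju = np.triu_indices(use.size, k=1)
        dist = np.abs(pos[ju] - pos[iu]).astype(float)
        keep = np.ones(dist.size, dtype=bool)
        if max_dist_bp is not None:
            keep &= dist <= max_dist_bp
        keep &= dist > 0
        frames.append(pd.DataFrame({
            "chrom": chrom, "snp_a": ids[iu][keep], "snp_b": ids[ju][keep],
            "dist_bp": dist[keep], "r2": r2[iu, ju][keep]}))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["chrom", "snp_a", "snp_b", "dist_bp", "r2"]))
    return LdPairs(table, correction=correction, n_skipped_monomorphic=skipped)


def pairwise_r2(G: GenotypeMatrix, max_dist_bp: Optional[float] = None) -> LdPairs:
    """Raw r2 (squared dosage correlation) for every intrachromosomal pair.

    Monomorphic SNPs cannot be correlated; their pairs are skipped and counted
    in ``n_skipped_monomorphic``.
    """
    if np.isnan(G.dosage).any():
        raise ValueError("missing dosages present; impute before LD analysis")
    return _pairs_from_columns(G, G.dosage, max_dist_bp, "none")


def corrected_r2(G: GenotypeMatrix, covariates: Optional[np.ndarray] = None,
                 kinship: Optional[np.ndarray] = None,
                 max_dist_bp: Optional[float] = None,
                 ridge: float = 1e-8) -> LdPairs:
    """Structure- or kinship-corrected r2.

    Exactly one of ``covariates`` (accessions x m matrix, e.g. admixture Q
    columns) or ``kinship`` must be given.  Structure mode correlates the
    residuals of each dosage vector after projection onto [1, covariates];
    kinship mode whitens dosages by the inverse square root of the kinship
    matrix (with a ``ridge`` term against singularity) before correlating.
    """
    if (covariates is None) == (kinship is None):
        raise ValueError("give exactly one of covariates or kinship")
    X = G.dosage
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute before LD analysis")
    n = G.n_accessions
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates not conformable with accessions")
        M = np.column_stack([np.ones(n), C])
        beta, *_ = np.linalg.lstsq(M, X, rcond=None)
        resid = X - M @ beta
        return _pairs_from_columns(G, resid, max_dist_bp, "structure")
    K = np.asarray(kinship, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship matrix not conformable with accessions")
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    if w.min() < -1e-6 * max(abs(w.max()), 1.0):
        raise ValueError("kinship matrix is not positive semidefinite")
    w = np.clip(w, 0.0, None) + ridge
    if w.min() <= 0:
        raise ValueError("singular whitening matrix; increase the ridge term")
    W = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    return _pairs_from_columns(G, W @ (X - X.mean(axis=0)), max_dist_bp, "kinship")


def kinship_matrix(G: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix: Z Z' / sum 2 p (1 - p).

    Z is the dosage matrix centred by twice the allele frequency; the result
    is symmetric positive semidefinite.
    """
    X = G.dosage
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute before kinship")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("panel is entirely monomorphic; kinship undefined")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = float((2.0 * p[poly] * (1.0 - p[poly])).sum())
    K = Z @ Z.T / denom
    return (K + K.T) / 2.0


def hill_weir_expectation(dist_bp: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Expected r2 under the Hill-Weir drift-recombination model.

    E(r2) = [(10+C)/((2+C)(11+C))] * [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))]
    with C = rho * distance and n the sample size.
    """
    C = rho * np.asarray(dist_bp, dtype=float)
    t1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    t2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C ** 2)) / (n * (2.0 + C) * (11.0 + C))
    return t1 * t2


@dataclass
class HillWeirFit:
    """Least-squares fit of the Hill-Weir decay curve: rho is per-bp."""

    rho: float
    n: int
    residual_ss: float
    n_pairs: int

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be >= 0")

    def expectation(self, dist_bp) -> np.ndarray:
        return hill_weir_expectation(np.asarray(dist_bp, dtype=float), self.rho, self.n)

    def to_json(self) -> str:
        return json.dumps({"rho_per_bp": self.rho, "n": self.n,
                           "residual_ss": self.residual_ss,
                           "n_pairs": self.n_pairs}, indent=2)


def fit_hill_weir(pairs: LdPairs, n: int) -> HillWeirFit:
    """Fit rho by nonlinear least squares over the (distance, r2) pairs."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    t = pairs.table
    if len(t) < 10:
        raise ValueError("need at least 10 SNP pairs to fit the decay curve")
    d = t["dist_bp"].to_numpy(dtype=float)
    r2 = t["r2"].to_numpy(dtype=float)

    def resid(log_rho):
        return hill_weir_expectation(d, np.exp(log_rho[0]), n) - r2

    best = None
    for start in (-np.log(np.median(d)), -np.log(d.max()), -np.log(d.min() + 1.0)):
        sol = least_squares(resid, x0=[start], method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):  # pragma: no cover
        raise RuntimeError("Hill-Weir optimiser failed")
    rho = float(np.exp(best.x[0]))
    rss = float(2.0 * best.cost)
    return HillWeirFit(rho=rho, n=n, residual_ss=rss, n_pairs=len(t))


def decay_distance(fit: HillWeirFit, threshold: float = 0.2,
                   max_dist_bp: float = 1e10) -> Optional[float]:
    """Distance (bp) where the fitted curve crosses ``threshold``.

    Returns None ("never") if the curve starts below the threshold or the
    threshold is not positive (the curve is strictly positive).
    """
    if threshold <= 0:
        return None
    start = fit.expectation(0.0)
    if start <= threshold:
        return None
    if fit.expectation(max_dist_bp) >= threshold:
        return None  # does not decay to the threshold within any sensible range
    f = lambda x: float(fit.expectation(x) - threshold)
    return float(brentq(f, 1e-9, max_dist_bp, xtol=1e-6, rtol=1e-12))


def min_snp_count(genome_size_mb: float, decay_distance_mb: float) -> int:
    """Markers needed for genome-wide coverage: round(genome / decay distance).

    Rounds half to even (Python's round), e.g. 587 / 0.59 -> 995.
    """
    if genome_size_mb <= 0 or decay_distance_mb <= 0:
        raise ValueError("genome size and decay distance must be > 0")
    return int(round(genome_size_mb / decay_distance_mb))
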