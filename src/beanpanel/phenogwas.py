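"""RCBD phenotype analysis and association-scan threshold machinery.

The phenotype side covers the classic randomised-complete-block workflow:
two-way ANOVA (cultivar + block), broad-sense heritability on a line-mean
basis, coefficient of variation, residual normality, least-squares means and
trait correlations.  The association side is a PC-adjusted single-marker
linear scan plus the two threshold rules used with it: an empirical
permutation threshold built from the distribution of minimum p-values, and
the Bonferroni bound.  BIC-based selection decides how many leading PCs
enter the scan as structure covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .structure import pca

__all__ = [
    "PhenotypeTable",
    "AnovaSummary",
    "GwasResult",
    "rcbd_anova",
    "ls_means",
    "trait_correlations",
    "bic_select_pcs",
    "gwas_scan",
    "permutation_threshold",
    "bonferroni_threshold",
]


@dataclass
class PhenotypeTable:
    """Long-format plot observations: accession, block, trait, value."""

    table: pd.DataFrame

    def __post_init__(self):
        req = {"accession", "block", "trait", "value"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"phenotype table must have columns {sorted(req)}")
        t = self.table
        bad = t[(t["trait"].isin(["DTF", "DTM"])) & (t["value"] <= 0)]
        if len(bad):
            raise ValueError("DTF/DTM values must be > 0")
        hab = t[t["trait"] == "HAB"]
        if len(hab) and not hab["value"].isin([1, 2, 3, 4]).all():
            raise ValueError("HAB values must be ordinal classes 1-4")

    def trait(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == name]
        if sub.empty:
            raise KeyError(f"trait {name!r} not in table")
        return sub

    def is_balanced(self, name: str) -> bool:
        sub = self.trait(name)
        counts = sub.groupby(["accession", "block"]).size()
        n_acc = sub["accession"].nunique()
        n_blk = sub["block"].nunique()
        return len(counts) == n_acc * n_blk and (counts == 1).all()


@dataclass
class AnovaSummary:
    trait: str
    ms_cultivar: float
    ms_block: float
    ms_residual: float
    df_cultivar: int
    df_block: int
    df_residual: int
    cv_percent: float
    h2: float
    h2_flagged: bool  # True when MS_cultivar < MS_residual (h2 clamped at 0)
    shapiro_p: float
    balanced: bool


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp, chrom, pos, effect, t, p, flagged
    n_pcs: int
    thresholds: dict[str, float] = field(default_factory=dict)

    def significant(self, threshold: float) -> list[str]:
        t = self.table
        return t.loc[t["p"] < threshold, "snp"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RCBD analysis
# ---------------------------------------------------------------------------

def _rcbd_fit(sub: pd.DataFrame):
    """Least-squares fit of value ~ mean + cultivar + block; returns the
    sequential (balanced-equivalent) SS pieces and the residuals."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("value ~ C(accession) + C(block)", data=sub).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ss_c = float(anova.loc["C(accession)", "sum_sq"])
    ss_b = float(anova.loc["C(block)", "sum_sq"])
    ss_r = float(anova.loc["Residual", "sum_sq"])
    df_c = int(anova.loc["C(accession)", "df"])
    df_b = int(anova.loc["C(block)", "df"])
    df_r = int(anova.loc["Residual", "df"])
    return (ss_c, ss_b, ss_r), (df_c, df_b, df_r), model


def rcbd_anova(P: PhenotypeTable, trait: str) -> AnovaSummary:
    """Two-way RCBD ANOVA with heritability, CV and residual normality.

    h2 (broad sense, line-mean basis) = (MS_cultivar - MS_residual) /
    MS_cultivar, clamped at 0 and flagged when MS_cultivar < MS_residual;
    CV = 100 sqrt(MS_residual) / grand mean; normality is Shapiro-Wilk on
    the model residuals.  Unbalanced designs fall back to the least-squares
    (type II) decomposition and are flagged.
    """
    sub = P.trait(trait)
    if sub["accession"].nunique() < 2 or sub["block"].nunique() < 2:
        raise ValueError("need >= 2 accessions and >= 2 blocks")
    balanced = P.is_balanced(trait)
    if not balanced:
        warnings.warn(f"{trait}: unbalanced design; least-squares decomposition used")
    (ss_c, ss_b, ss_r), (df_c, df_b, df_r), model = _rcbd_fit(sub)
    ms_c, ms_b, ms_r = ss_c / df_c, ss_b / df_b, ss_r / df_r
    grand = float(sub["value"].mean())
    cv = 100.0 * np.sqrt(ms_r) / grand
    flagged = ms_c < ms_r
    h2 = 0.0 if flagged else (ms_c - ms_r) / ms_c
    resid = np.asarray(model.resid)
    shapiro_p = float(stats.shapiro(resid).pvalue) if resid.size >= 3 else np.nan
    return AnovaSummary(trait, ms_c, ms_b, ms_r, df_c, df_b, df_r,
                        cv, h2, flagged, shapiro_p, balanced)


def ls_means(P: PhenotypeTable, trait: str) -> pd.Series:
    """Per-accession adjusted means from the two-way model.

    Predicted accession value averaged over all block levels; equals the
    arithmetic accession mean under a balanced design.  Accessions absent
    from every block are excluded with a warning upstream of the fit.
    """
    sub = P.trait(trait)
    _, _, model = _rcbd_fit(sub)
    accs = sorted(sub["accession"].unique())
    blocks = sorted(sub["block"].unique())
    grid = pd.DataFrame([(a, b) for a in accs for b in blocks],
                        columns=["accession", "block"])
    pred = model.predict(grid)
    return pred.groupby(grid["accession"]).mean().rename(trait)


def trait_correlations(means: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations (with p-values) of least-squares means.

    ``means``: accessions x traits.  Returns a long table (trait_a, trait_b,
    r, p); zero-variance traits yield NaN and a warning.
    """
    if len(means) < 3:
        raise ValueError("need >= 3 accessions for correlations")
    traits = list(means.columns)
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            x, y = means[a].to_numpy(float), means[b].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"zero variance in {a if x.std() == 0 else b}; r undefined")
                rows.append((a, b, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((a, b, float(r), float(p)))
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p"])


# ---------------------------------------------------------------------------
# association scan and thresholds
# ---------------------------------------------------------------------------

def _pc_covariates(G: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    if n_pcs == 0:
        return np.empty((G.n_accessions, 0))
    scores, _ = pca(G, n_components=n_pcs)
    return scores


def bic_select_pcs(G: GenotypeMatrix, y: np.ndarray, max_pcs: int = 5) -> int:
    """Number of leading PCs to include as structure covariates, by BIC.

    Fits the covariate-only Gaussian model with 0..max_pcs leading PC scores
    and returns the count maximising BIC in the higher-is-better convention
    loglik - (k/2) ln n, with k the number of mean-model coefficients.
    """
    y = np.asarray(y, dtype=float)
    n = G.n_accessions
    if len(y) != n:
        raise ValueError("y length must match the number of accessions")
    if max_pcs >= n:
        raise ValueError("max_pcs must be < number of accessions")
    if max_pcs < 0:
        raise ValueError("max_pcs must be >= 0")
    scores = _pc_covariates(G, max_pcs) if max_pcs else np.empty((n, 0))
    best_m, best_bic = 0, -np.inf
    for m in range(max_pcs + 1):
        M = np.column_stack([np.ones(n), scores[:, :m]])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        rss = float(((y - M @ beta) ** 2).sum())
        sigma2 = max(rss / n, 1e-300)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        bic = loglik - ((m + 1) / 2.0) * np.log(n)
        if bic > best_bic + 1e-12:
            best_m, best_bic = m, bic
    return best_m


def _scan_matrix(G: GenotypeMatrix, Y: np.ndarray, n_pcs: int):
    """Vectorised per-SNP slope t-test for one or many phenotype columns.

    Y: (n, r) matrix of phenotypes.  Returns (effects, t, p) each (L, r),
    with monomorphic SNPs flagged by p = 1 and effect NaN.
    """
    X = G.dosage
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute before the scan")
    n = G.n_accessions
    C = np.column_stack([np.ones(n), _pc_covariates(G, n_pcs)])
    p_cov = C.shape[1]
    # project covariates out of both genotypes and phenotypes
    Q, _ = np.linalg.qr(C)
    Xr = X - Q @ (Q.T @ X)
    Yr = Y - Q @ (Q.T @ Y)
    sx2 = (Xr ** 2).sum(axis=0)  # (L,)
    mono = sx2 <= 1e-12
    sx2_safe = np.where(mono, 1.0, sx2)
    beta = (Xr.T @ Yr) / sx2_safe[:, None]            # (L, r)
    sy2 = (Yr ** 2).sum(axis=0)[None, :]              # (1, r)
    rss = np.clip(sy2 - beta ** 2 * sx2_safe[:, None], 0.0, None)
    df = n - p_cov - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom for the scan")
    se = np.sqrt(rss / df / sx2_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    beta[mono] = np.nan
    t[mono] = 0.0
    pvals[mono] = 1.0
    return beta, t, pvals, mono


def gwas_scan(G: GenotypeMatrix, y: np.ndarray, n_pcs: int = 0) -> GwasResult:
    """Single-marker linear association scan: y ~ intercept + PCs + dosage.

    Two-sided p-values from the dosage coefficient's t statistic; monomorphic
    SNPs are recorded with p = 1 and flagged.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != G.n_accessions:
        raise ValueError("y length must match the number of accessions")
    if y.std() == 0:
        warnings.warn("constant phenotype; all p-values set to 1")
        table = G.snps.rename(columns={"id": "snp"}).copy()
        table["effect"], table["t"], table["p"], table["flagged"] = np.nan, 0.0, 1.0, True
        return GwasResult(table, n_pcs=n_pcs)
    beta, t, p, mono = _scan_matrix(G, y[:, None], n_pcs)
    table = G.snps.rename(columns={"id": "snp"}).copy()
    table["effect"] = beta[:, 0]
    table["t"] = t[:, 0]
    table["p"] = p[:, 0]
    table["flagged"] = mono
    return GwasResult(table, n_pcs=n_pcs)


def permutation_threshold(G: GenotypeMatrix, y: np.ndarray, n_perm: int = 300,
                          quantile_level: float = 0.05, seed: int = 0,
                          n_pcs: int = 0) -> float:
    """Empirical scan-wide p-value threshold from permuted phenotypes.

    The phenotype is permuted ``n_perm`` times to break genotype-phenotype
    associations, the minimum scan p-value is recorded for each permutation,
    and the threshold is the ``quantile_level`` quantile of those minima —
    0.05 (the default) controls the family-wise error rate near 5%; the
    permissive literal-95%-quantile reading is available via
    ``quantile_level=0.95``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} gives an unstable quantile estimate")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    _, _, pvals, _ = _scan_matrix(G, perms, n_pcs)
    min_p = pvals.min(axis=0)
    return float(np.quantile(min_p, quantile_level))


def bonferroni_threshold(n_snps: int, alpha: float = 0.01) -> float:
    """Bonferroni scan-wide threshold alpha / n_snps."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return alpha / n_snps
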