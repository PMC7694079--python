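"""Two-level hierarchical analysis of molecular variance (AMOVA).

The hierarchy is: commercial classes / cultivars (accessions) within classes
/ allele copies within cultivars.  Each accession contributes two allele
copies per locus, so the within-cultivar stratum is the between-allele-copy
(heterozygosity) level and the degrees of freedom total 2N - 1.  Sums of
squares follow the Excoffier decomposition (squared allele differences,
equivalently squared Euclidean deviations of 0/1 allele-copy vectors from
group centroids); variance components come from the nested expected mean
squares with unequal-size coefficients, and Phi statistics are their
variance ratios.  Significance is assessed by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = ["AmovaResult", "amova_two_level", "amova_permutation_test"]


@dataclass
class AmovaResult:
    """AMOVA table plus Phi statistics.

    ``table`` rows: among classes, among cultivars within classes, within
    cultivars, total; columns df, SS, variance component, percentage of the
    total.  Negative variance components are reported as estimated and
    flagged in ``negative_components`` (optionally truncated to zero before
    the percentage step via ``truncate_negative``).
    """

    table: pd.DataFrame
    phi_ct: float
    phi_sc: float
    phi_st: float
    negative_components: list[str] = field(default_factory=list)
    undefined: bool = False
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="Variance source")


def _allele_copy_matrix(G: GenotypeMatrix) -> np.ndarray:
    """(2N, L) 0/1 allele-copy matrix; heterozygotes split into one 0 and one 1."""
    D = G.dosage
    if np.isnan(D).any():
        raise ValueError("missing dosages present; impute before AMOVA")
    n, L = D.shape
    X = np.zeros((2 * n, L), dtype=np.float64)
    X[0::2] = (D >= 1.0).astype(float)   # first copy carries the alt allele if d >= 1
    X[1::2] = (D == 2.0).astype(float)   # second copy only for alt homozygotes
    return X


def _ss_terms(X: np.ndarray, acc_of_copy: np.ndarray, class_of_copy: np.ndarray,
              n_acc: int, n_classes: int):
    """Total, within-class and within-cultivar sums of squares for 0/1 copies."""
    N = X.shape[0]
    total_norm = float(X.sum())  # sum of squares of 0/1 entries
    col_sum = X.sum(axis=0)
    ss_total = total_norm - float(col_sum @ col_sum) / N

    acc_sums = np.zeros((n_acc, X.shape[1]))
    np.add.at(acc_sums, acc_of_copy, X)
    acc_counts = np.bincount(acc_of_copy, minlength=n_acc).astype(float)
    ss_within_cult = total_norm - float(
        ((acc_sums ** 2).sum(axis=1) / acc_counts).sum())

    cls_sums = np.zeros((n_classes, X.shape[1]))
    np.add.at(cls_sums, class_of_copy, X)
    cls_counts = np.bincount(class_of_copy, minlength=n_classes).astype(float)
    ss_within_class = total_norm - float(
        ((cls_sums ** 2).sum(axis=1) / cls_counts).sum())
    return ss_total, ss_within_class, ss_within_cult


def _components(ss_total, ss_within_class, ss_within_cult,
                copies_per_cult: np.ndarray, class_of_cult: np.ndarray,
                n_classes: int):
    """Variance components from nested expected mean squares."""
    J = len(copies_per_cult)
    I = n_classes
    N = float(copies_per_cult.sum())
    N_i = np.bincount(class_of_cult, weights=copies_per_cult, minlength=I)

    ss_a = ss_total - ss_within_class
    ss_b = ss_within_class - ss_within_cult
    df_a, df_b, df_c = I - 1, J - I, int(N) - J

    ms_c = ss_within_cult / df_c
    ms_b = ss_b / df_b
    ms_a = ss_a / df_a

    sum_nij2_over_Ni = float(np.bincount(
        class_of_cult, weights=copies_per_cult ** 2, minlength=I)
        @ (1.0 / N_i))
    n_c = (N - sum_nij2_over_Ni) / df_b
    n_bp = (sum_nij2_over_Ni - float((copies_per_cult ** 2).sum()) / N) / df_a
    n_a = (N - float((N_i ** 2).sum()) / N) / df_a

    sig_c = ms_c
    sig_b = (ms_b - sig_c) / n_c
    sig_a = (ms_a - sig_c - n_bp * sig_b) / n_a
    return (ss_a, ss_b, ss_within_cult), (df_a, df_b, df_c), (sig_a, sig_b, sig_c)


def _phis(sig_a, sig_b, sig_c):
    total = sig_a + sig_b + sig_c
    if total <= 0:
        return np.nan, np.nan, np.nan
    phi_ct = sig_a / total
    phi_sc = sig_b / (sig_b + sig_c) if (sig_b + sig_c) != 0 else np.nan
    phi_st = (sig_a + sig_b) / total
    return phi_ct, phi_sc, phi_st


def _prepare(G: GenotypeMatrix, classes: dict[str, str]):
    cls_labels = [classes[a] for a in G.accessions]
    uniq = sorted(set(cls_labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 classes")
    counts = pd.Series(cls_labels).value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"class {bad!r} has only one accession")
    cls_idx = {c: i for i, c in enumerate(uniq)}
    class_of_cult = np.array([cls_idx[c] for c in cls_labels])
    n = G.n_accessions
    acc_of_copy = np.repeat(np.arange(n), 2)
    class_of_copy = class_of_cult[acc_of_copy]
    return uniq, class_of_cult, acc_of_copy, class_of_copy


def amova_two_level(G: GenotypeMatrix, classes: dict[str, str],
                    truncate_negative: bool = False) -> AmovaResult:
    """AMOVA of classes / cultivars within classes / allele copies within cultivars."""
    uniq, class_of_cult, acc_of_copy, class_of_copy = _prepare(G, classes)
    X = _allele_copy_matrix(G)
    n = G.n_accessions
    ss = _ss_terms(X, acc_of_copy, class_of_copy, n, len(uniq))
    copies = np.full(n, 2.0)
    (ss_a, ss_b, ss_c), (df_a, df_b, df_c), sigs = _components(
        *ss, copies, class_of_cult, len(uniq))
    sig_a, sig_b, sig_c = sigs
    negative = [name for name, s in
                zip(["among classes", "among cultivars within classes",
                     "within cultivars"], sigs) if s < 0]
    rep = [0.0 if (truncate_negative and s < 0) else s for s in sigs]
    total_var = sum(rep)
    undefined = total_var <= 0
    pct = ([np.nan] * 3 if undefined else [100.0 * s / total_var for s in rep])
    phi_ct, phi_sc, phi_st = (np.nan, np.nan, np.nan) if undefined else _phis(*rep)
    table = pd.DataFrame(
        {
            "df": [df_a, df_b, df_c, df_a + df_b + df_c],
            "SS": [ss_a, ss_b, ss_c, ss_a + ss_b + ss_c],
            "variance_component": rep + [total_var],
            "percent": pct + [100.0 if not undefined else np.nan],
        },
        index=["Between commercial classes", "Between cultivars",
               "Within cultivars", "Total"],
    )
    return AmovaResult(table, phi_ct, phi_sc, phi_st,
                       negative_components=negative, undefined=undefined)


def amova_permutation_test(G: GenotypeMatrix, classes: dict[str, str],
                           n_perm: int = 9999, seed: int = 0,
                           truncate_negative: bool = False) -> AmovaResult:
    """AMOVA with permutation p-values for each Phi statistic.

    Null schemes: Phi_CT — whole accessions permuted among classes; Phi_SC —
    allele copies permuted among cultivars within their class; Phi_ST —
    allele copies permuted among all accessions.  p = (#null >= observed + 1)
    / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    result = amova_two_level(G, classes, truncate_negative=truncate_negative)
    if result.undefined:
        result.p_values = {"phi_ct": np.nan, "phi_sc": np.nan, "phi_st": np.nan}
        return result

    uniq, class_of_cult, acc_of_copy, class_of_copy = _prepare(G, classes)
    X = _allele_copy_matrix(G)
    n = G.n_accessions
    I = len(uniq)
    copies = np.full(n, 2.0)

    def phis_for(acc_map, cls_cult):
        ss = _ss_terms(X, acc_map, cls_cult[acc_map], n, I)
        _, _, sigs = _components(*ss, copies, cls_cult, I)
        if truncate_negative:
            sigs = tuple(max(s, 0.0) for s in sigs)
        return _phis(*sigs)

    ge_ct = ge_sc = ge_st = 0
    for _ in range(n_perm):
        # Phi_CT: shuffle class labels over accessions
        cls_perm = class_of_cult[rng.permutation(n)]
        ct, _, _ = phis_for(acc_of_copy, cls_perm)
        if not np.isnan(ct) and ct >= result.phi_ct - 1e-12:
            ge_ct += 1
        # Phi_SC: shuffle copies among accessions within each class
        acc_map_sc = acc_of_copy.copy()
        for c in range(I):
            rows = np.flatnonzero(class_of_copy == c)
            acc_map_sc[rows] = acc_map_sc[rows[rng.permutation(rows.size)]]
        _, sc, _ = phis_for(acc_map_sc, class_of_cult)
        if not np.isnan(sc) and sc >= result.phi_sc - 1e-12:
            ge_sc += 1
        # Phi_ST: shuffle copies among all accessions
        acc_map_st = acc_of_copy[rng.permutation(2 * n)]
        _, _, st = phis_for(acc_map_st, class_of_cult)
        if not np.isnan(st) and st >= result.phi_st - 1e-12:
            ge_st += 1

    result.p_values = {
        "phi_ct": (ge_ct + 1) / (n_perm + 1),
        "phi_sc": (ge_sc + 1) / (n_perm + 1),
        "phi_st": (ge_st + 1) / (n_perm + 1),
    }
    result.n_permutations = n_perm
    return result
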