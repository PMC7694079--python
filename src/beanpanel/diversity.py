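"""Per-group diversity statistics, rarefied allelic richness, diversity gain,
Nei distances, and UPGMA clustering.

All statistics treat each biallelic SNP as a two-allele locus; heterozygotes
contribute one copy of each allele to allele frequencies.  Group values are
means over loci of the per-locus statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from skbio import TreeNode

from .genotype_io import GenotypeMatrix

__all__ = [
    "DiversityTable",
    "DistanceMatrix",
    "group_diversity",
    "rarefied_allelic_richness",
    "diversity_delta",
    "nei_distance_matrix",
    "upgma",
]


@dataclass
class DiversityTable:
    """Per-group diversity summary mirroring the classic GenAlEx-style table.

    Columns: N (accessions), Npa (private alleles), I (Shannon information
    index, natural log), Rs (rarefied allelic richness), Ho, He, uHe, PIC.
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="Group")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmax(np.abs(np.diag(self.values))) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")


def _allele_counts(G: GenotypeMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ref copies, alt copies) per SNP for the given accession rows."""
    d = G.dosage[rows]
    if np.isnan(d).any():
        raise ValueError("missing dosages present; impute before diversity analysis")
    alt = d.sum(axis=0)
    ref = 2.0 * len(rows) - alt
    return ref, alt


def _groups_to_rows(G: GenotypeMatrix, groups: dict[str, str]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for i, a in enumerate(G.accessions):
        if a in groups:
            out.setdefault(groups[a], []).append(i)
    return {g: np.array(rows) for g, rows in out.items()}


def group_diversity(G: GenotypeMatrix, groups: dict[str, str],
                    rarefaction_g: int | None = None) -> DiversityTable:
    """Compute N, Npa, I, Rs, Ho, He, uHe and PIC per group.

    Per locus with alternative-allele frequency p (q = 1-p):
    Ho = heterozygote fraction, He = 2pq, uHe = He * 2N/(2N-1),
    I = -p ln p - q ln q (0 for fixed loci), PIC = 1 - (p^2+q^2) - 2 p^2 q^2.
    Group values are means over loci; Npa counts allele/locus combinations
    present in the group and absent from every other group.  Rs uses
    rarefaction to ``rarefaction_g`` gene copies (default: 2 x smallest group).
    """
    rows_by_group = _groups_to_rows(G, groups)
    if not rows_by_group:
        raise ValueError("no accession in G appears in the groups mapping")
    for g, rows in rows_by_group.items():
        if len(rows) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 accessions")
    rs = rarefied_allelic_richness(G, groups, g=rarefaction_g)

    # presence masks for private-allele counting
    presence = {}
    for g, rows in rows_by_group.items():
        ref, alt = _allele_counts(G, rows)
        presence[g] = (ref > 0, alt > 0)

    records = {}
    for g, rows in rows_by_group.items():
        N = len(rows)
        ref, alt = _allele_counts(G, rows)
        p = alt / (ref + alt)
        q = 1.0 - p
        he = 2.0 * p * q
        uhe = he * (2.0 * N) / (2.0 * N - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            shannon = -(np.where(p > 0, p * np.log(p), 0.0)
                        + np.where(q > 0, q * np.log(q), 0.0))
        pic = 1.0 - (p ** 2 + q ** 2) - 2.0 * p ** 2 * q ** 2
        ho = (G.dosage[rows] == 1.0).mean()
        others = [presence[h] for h in rows_by_group if h != g]
        if others:
            ref_elsewhere = np.any([o[0] for o in others], axis=0)
            alt_elsewhere = np.any([o[1] for o in others], axis=0)
        else:
            ref_elsewhere = np.zeros(G.n_snps, dtype=bool)
            alt_elsewhere = np.zeros(G.n_snps, dtype=bool)
        npa = int((presence[g][0] & ~ref_elsewhere).sum()
                  + (presence[g][1] & ~alt_elsewhere).sum())
        records[g] = {"N": N, "Npa": npa, "I": shannon.mean(), "Rs": rs[g],
                      "Ho": ho, "He": he.mean(), "uHe": uhe.mean(),
                      "PIC": pic.mean()}
    table = pd.DataFrame.from_dict(records, orient="index")
    return DiversityTable(table[["N", "Npa", "I", "Rs", "Ho", "He", "uHe", "PIC"]])


def rarefied_allelic_richness(G: GenotypeMatrix, groups: dict[str, str],
                              g: int | None = None) -> dict[str, float]:
    """Expected allele count per locus in a rarefied draw of ``g`` gene copies.

    Per locus: Rs = sum over alleles of [1 - C(2N - n_a, g) / C(2N, g)], with
    n_a the copies of allele a in the group; the group value is the mean over
    loci.  ``g`` defaults to twice the smallest group size and must not exceed
    2N for any group.
    """
    rows_by_group = _groups_to_rows(G, groups)
    if not rows_by_group:
        raise ValueError("no accession in G appears in the groups mapping")
    if g is None:
        g = 2 * min(len(r) for r in rows_by_group.values())
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = {}
    for name, rows in rows_by_group.items():
        two_n = 2 * len(rows)
        if g > two_n:
            raise ValueError(
                f"rarefaction size g={g} exceeds 2N={two_n} for group {name!r}")
        ref, alt = _allele_counts(G, rows)
        rs = np.zeros(G.n_snps)
        for counts in (ref, alt):
            miss = np.zeros(G.n_snps)
            ok = (two_n - counts) >= g  # otherwise the allele is always drawn
            miss[ok] = np.exp(log_comb(two_n - counts[ok], g) - log_comb(two_n, g))
            rs += np.where(counts > 0, 1.0 - miss, 0.0)
        out[name] = float(rs.mean())
    return out


def diversity_delta(v_old: float, v_modern: float) -> float:
    """Relative diversity change 1 - v_modern/v_old (negative = gain)."""
    if v_old <= 0:
        raise ValueError("v_old must be > 0")
    return 1.0 - v_modern / v_old


def nei_distance_matrix(G: GenotypeMatrix, units: str = "accessions",
                        groups: dict[str, str] | None = None) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between accessions or groups.

    D = -ln( J_xy / sqrt(J_x J_y) ) with J terms summed over all loci and
    alleles.  A unit pair sharing no allele anywhere has identity 0 and
    distance +inf; such pairs are flagged with a warning rather than silently
    propagated.
    """
    if units == "accessions":
        labels = list(G.accessions)
        d = G.dosage
        if np.isnan(d).any():
            raise ValueError("missing dosages present; impute first")
        freqs = d / 2.0  # per-accession alt-allele frequency per locus
    elif units == "groups":
        if groups is None:
            raise ValueError("groups mapping required for units='groups'")
        rows_by_group = _groups_to_rows(G, groups)
        labels = list(rows_by_group)
        freqs = np.vstack([
            _allele_counts(G, rows)[1] / (2.0 * len(rows))
            for rows in rows_by_group.values()])
    else:
        raise ValueError("units must be 'accessions' or 'groups'")

    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    # J_xy = sum over loci/alleles of x*y; vectorised via dot products
    jxx = (p * p + q * q).sum(axis=1)
    jxy = p @ p.T + q @ q.T
    denom = np.sqrt(np.outer(jxx, jxx))
    with np.errstate(divide="ignore"):
        ident = jxy / denom
        D = -np.log(np.clip(ident, 0.0, None))
    D = np.where(ident <= 0.0, np.inf, D)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    D = (D + D.T) / 2.0
    if np.isinf(D).any():
        n_inf = int(np.isinf(D).sum() // 2)
        warnings.warn(f"{n_inf} unit pair(s) share no alleles: distance set to +inf")
    return DistanceMatrix(labels, D)


def upgma(D: DistanceMatrix) -> TreeNode:
    """UPGMA (average-linkage) clustering of a distance matrix.

    Returns a rooted ultrametric :class:`skbio.TreeNode`; serialise with
    ``str(tree)`` or ``tree.write(...)`` for newick output.
    """
    if np.isnan(D.values).any() or np.isinf(D.values).any():
        raise ValueError("UPGMA requires finite distances")
    condensed = squareform(D.values, checks=False)
    linkage = average(condensed)
    return TreeNode.from_linkage_matrix(linkage, D.labels)
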