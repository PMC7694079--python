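"""Genotype matrix containers, HapMap/VCF readers and writers, and SNP quality control.

Genotypes are held as alternative-allele dosages: 0 (homozygous reference),
1 (heterozygous), 2 (homozygous alternative), NaN (missing call).  The HapMap
dialect used by bean SNP-array pipelines codes the same four states with the
single letters A (reference homozygote), G (alternative homozygote),
R (heterozygote) and N (missing); both readers normalise to dosages.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "SnpRecord",
    "EmptyPanelError",
    "GenotypeParseError",
    "read_hapmap",
    "write_hapmap",
    "read_vcf",
    "write_vcf",
    "apply_qc_filters",
    "impute_missing",
    "normalize_chrom",
]

# HapMap dialect genotype symbols -> dosage
_HAPMAP_CODE = {"A": 0.0, "R": 1.0, "G": 2.0, "N": np.nan}
_DOSAGE_CODE = {0: "A", 1: "R", 2: "G"}

# standard 11 leading HapMap columns
HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_CHROM_RE = re.compile(r"^(?:Pv|pv|Chr|chr)?0*(\d{1,2})$")


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be interpreted."""


class EmptyPanelError(ValueError):
    """Raised when an operation would produce a panel with no SNPs or accessions."""


def normalize_chrom(label) -> str:
    """Normalise a chromosome label to the ``Pv01``..``Pv11`` convention.

    Integers and strings such as ``"1"``, ``"Pv1"``, ``"chr01"`` all map to
    ``"Pv01"``.  Labels that do not look like a numbered chromosome (scaffolds,
    empty strings) are returned unchanged and treated as unplaced downstream.
    """
    s = str(label).strip()
    m = _CHROM_RE.match(s)
    if m:
        return f"Pv{int(m.group(1)):02d}"
    return s


def _is_placed(chrom: str, pos) -> bool:
    if not re.match(r"^Pv\d{2}$", str(chrom)):
        return False
    try:
        return int(pos) >= 1
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class SnpRecord:
    """A single mapped SNP: marker id, chromosome label, 1-based bp position."""

    id: str
    chrom: str
    pos: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with its SNP map.

    Parameters
    ----------
    accessions
        Ordered accession identifiers (rows of ``dosage``).
    snps
        DataFrame with columns ``id``, ``chrom``, ``pos`` (columns of
        ``dosage``), sorted by chromosome then position on construction.
    dosage
        ``(n_accessions, n_snps)`` float array with values in {0, 1, 2, NaN}.
    """

    accessions: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.accessions = list(self.accessions)
        self.snps = self.snps.reset_index(drop=True).copy()
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(self.accessions) == 0:
            raise EmptyPanelError("genotype matrix has no accessions")
        if len(self.snps) == 0:
            raise EmptyPanelError("genotype matrix has no SNPs")
        if self.dosage.shape != (len(self.accessions), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"dosage values outside {{0,1,2,NaN}}: {bad}")
        self.snps["chrom"] = [normalize_chrom(c) for c in self.snps["chrom"]]
        if self.snps["id"].duplicated().any():
            dup = self.snps.loc[self.snps["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")
        placed = self.snps.apply(lambda r: _is_placed(r["chrom"], r["pos"]), axis=1)
        if placed.any():
            pp = self.snps.loc[placed, ["chrom", "pos"]]
            if pp.duplicated().any():
                raise ValueError("duplicate (chrom, pos) in SNP map")
        # keep map sorted by chrom then pos (unplaced SNPs kept, sorted last)
        order = self.snps.assign(_placed=~placed).sort_values(
            ["_placed", "chrom", "pos"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]

    # -- basic introspection -------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["id"].tolist()

    def accession_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} not in panel") from None

    def snp_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snps["id"])}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"SNP {e.args[0]!r} not in panel") from None

    def subset(self, accessions: Sequence[str] | None = None,
               snp_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given accessions and/or SNP mask."""
        rows = (self.accession_index(accessions) if accessions is not None
                else np.arange(self.n_accessions))
        if snp_mask is None:
            snp_mask = np.ones(self.n_snps, dtype=bool)
        snp_mask = np.asarray(snp_mask)
        if snp_mask.dtype != bool:
            m = np.zeros(self.n_snps, dtype=bool)
            m[snp_mask] = True
            snp_mask = m
        acc = [self.accessions[i] for i in rows]
        return GenotypeMatrix(acc, self.snps.loc[snp_mask], self.dosage[np.ix_(rows, snp_mask)])

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.snps["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.snps["chrom"] == normalize_chrom(chrom)).to_numpy()

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.accessions), self.snps.copy(), self.dosage.copy())

    # -- per-SNP summaries ---------------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Alternative-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def het_fraction(self) -> np.ndarray:
        """Fraction of heterozygous calls per SNP among non-missing calls."""
        het = (self.dosage == 1.0).sum(axis=0)
        n = (~np.isnan(self.dosage)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)


@dataclass
class QcReport:
    """Bookkeeping for SNP quality filtering.

    Each removed SNP is attributed to the first failed filter in the order
    unplaced -> missing -> heterozygosity -> MAF, so counts are reproducible.
    """

    n_input: int
    n_removed_unplaced: int
    n_removed_missing: int
    n_removed_het: int
    n_removed_maf: int
    n_retained: int
    thresholds: dict = field(default_factory=dict)
    removed_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        total = (self.n_removed_unplaced + self.n_removed_missing
                 + self.n_removed_het + self.n_removed_maf + self.n_retained)
        if total != self.n_input:
            raise ValueError("QcReport counts do not sum to n_input")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("n_input", "n_removed_unplaced", "n_removed_missing",
              "n_removed_het", "n_removed_maf", "n_retained", "thresholds")}
        return json.dumps(d, indent=2)

    def log_lines(self) -> list[str]:
        return [
            f"QC input SNPs: {self.n_input}",
            f"  removed unplaced:        {self.n_removed_unplaced}",
            f"  removed missing > {self.thresholds.get('miss_max')}: {self.n_removed_missing}",
            f"  removed het > {self.thresholds.get('het_max')}:     {self.n_removed_het}",
            f"  removed MAF < {self.thresholds.get('maf_min')}:     {self.n_removed_maf}",
            f"QC retained SNPs: {self.n_retained}",
        ]


# ---------------------------------------------------------------------------
# HapMap dialect
# ---------------------------------------------------------------------------

def read_hapmap(path) -> GenotypeMatrix:
    """Read a tab-separated HapMap file in the A/G/R/N single-letter dialect.

    The file must have the 11 standard HapMap header columns followed by one
    column per accession; genotype cells must be one of A (reference
    homozygote, dosage 0), R (heterozygote, 1), G (alternative homozygote, 2)
    or N (missing).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise GenotypeParseError(f"{path}: empty file")
        cols = header.split("\t")
        if len(cols) < 11 or cols[0] not in ("rs#", "rs"):
            raise GenotypeParseError(
                f"{path} line 1: expected 11 standard HapMap columns starting "
                f"with 'rs#', got {cols[:3]}..."
            )
        accessions = cols[11:]
        if not accessions:
            raise GenotypeParseError(f"{path}: no accession columns after the 11 header columns")
        ids, chroms, poss, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 11 + len(accessions):
                raise GenotypeParseError(
                    f"{path} line {lineno}: expected {11 + len(accessions)} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            chroms.append(parts[2])
            poss.append(int(parts[3]) if parts[3] not in ("", "NA") else 0)
            row = np.empty(len(accessions))
            for j, cell in enumerate(parts[11:]):
                try:
                    row[j] = _HAPMAP_CODE[cell]
                except KeyError:
                    raise GenotypeParseError(
                        f"{path} line {lineno}, accession {accessions[j]!r}: "
                        f"unknown genotype symbol {cell!r}"
                    ) from None
            rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no SNP rows")
    snps = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(accessions, snps, np.vstack(rows).T)


def write_hapmap(G: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix in the A/G/R/N HapMap dialect (inverse of read_hapmap)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + list(G.accessions)) + "\n")
        for j in range(G.n_snps):
            rec = G.snps.iloc[j]
            cells = []
            for i in range(G.n_accessions):
                d = G.dosage[i, j]
                cells.append("N" if np.isnan(d) else _DOSAGE_CODE[int(d)])
            fh.write("\t".join(
                [str(rec["id"]), "A/G", str(rec["chrom"]), str(int(rec["pos"])),
                 "+", "NA", "NA", "NA", "NA", "NA", "NA"] + cells) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, multiallelic: str = "reject") -> GenotypeMatrix:
    """Read a VCF (v4.x) into a GenotypeMatrix using cyvcf2.

    GT ``0/0`` -> 0, ``0/1`` -> 1, ``1/1`` -> 2, ``./.`` -> missing; phasing is
    ignored.  Sites with more than one ALT allele are an error under
    ``multiallelic="reject"`` (the default) or dropped under ``"skip"``.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("reject", "skip"):
        raise ValueError("multiallelic must be 'reject' or 'skip'")
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    if not accessions:
        raise GenotypeParseError(f"{path}: VCF has no samples")
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if multiallelic == "reject":
                raise GenotypeParseError(
                    f"{path}: multiallelic site {var.CHROM}:{var.POS} "
                    f"(ALT={var.ALT}) under 'reject' policy"
                )
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gts = np.asarray(var.genotypes, dtype=object)
        row = np.empty(len(accessions))
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            row[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(row)
    vcf.close()
    if not rows:
        raise GenotypeParseError(f"{path}: no usable variant records")
    snps = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(accessions, snps, np.vstack(rows).T)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal biallelic VCF v4.2 with REF=A, ALT=G placeholder alleles."""
    path = Path(path)
    chroms = G.chromosomes()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=beanpanel\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.accessions) + "\n")
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(G.n_snps):
            rec = G.snps.iloc[j]
            cells = ["./." if np.isnan(G.dosage[i, j]) else gt_code[int(G.dosage[i, j])]
                     for i in range(G.n_accessions)]
            fh.write(f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['id']}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Quality control and imputation
# ---------------------------------------------------------------------------

def apply_qc_filters(G: GenotypeMatrix, maf_min: float = 0.03,
                     het_max: float = 0.05, miss_max: float = 0.10,
                     ) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the standard marker filters and return the retained panel plus report.

    A SNP is retained iff it has a placed (chrom, pos), missing fraction
    <= ``miss_max``, heterozygous-call fraction <= ``het_max`` among non-missing
    calls, and minor allele frequency >= ``maf_min`` on non-missing dosages.
    Removed SNPs are attributed to the first failed filter in the order
    unplaced -> missing -> het -> MAF.
    """
    placed = np.array([_is_placed(c, p) for c, p in
                       zip(G.snps["chrom"], G.snps["pos"])])
    miss = G.missing_fraction()
    het = G.het_fraction()
    maf = G.maf()

    fail_unplaced = ~placed
    fail_missing = placed & (miss > miss_max)
    fail_het = placed & ~fail_missing & (het > het_max)
    with np.errstate(invalid="ignore"):
        fail_maf = placed & ~fail_missing & ~fail_het & ~(maf >= maf_min)
    keep = ~(fail_unplaced | fail_missing | fail_het | fail_maf)

    if not keep.any():
        raise EmptyPanelError("all SNPs removed by QC filters — empty panel")

    report = QcReport(
        n_input=G.n_snps,
        n_removed_unplaced=int(fail_unplaced.sum()),
        n_removed_missing=int(fail_missing.sum()),
        n_removed_het=int(fail_het.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        thresholds={"maf_min": maf_min, "het_max": het_max, "miss_max": miss_max},
        removed_ids={
            "unplaced": G.snps.loc[fail_unplaced, "id"].tolist(),
            "missing": G.snps.loc[fail_missing, "id"].tolist(),
            "het": G.snps.loc[fail_het, "id"].tolist(),
            "maf": G.snps.loc[fail_maf, "id"].tolist(),
        },
    )
    return G.subset(snp_mask=keep), report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-SNP modal dosage (ties -> lower dosage).

    Suited to highly inbred panels with low missingness; SNPs that are entirely
    missing are an error (they should have been removed by QC).
    """
    if not np.isnan(G.dosage).any():
        return G
    out = G.dosage.copy()
    for j in np.flatnonzero(np.isnan(G.dosage).any(axis=0)):
        col = out[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(
                f"SNP {G.snps['id'].iloc[j]!r} is entirely missing; run QC first"
            )
        counts = np.array([(obs == d).sum() for d in (0.0, 1.0, 2.0)])
        mode = float(np.argmax(counts))  # argmax takes the lowest dosage on ties
        col[np.isnan(col)] = mode
    return GenotypeMatrix(list(G.accessions), G.snps, out)
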