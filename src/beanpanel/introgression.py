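"""Diagnostic-SNP discovery and donor-introgression scanning.

The procedure identifies accessions that are pure members of the recipient
gene pool (per-chromosome ancestry >= a purity tolerance on every
chromosome), contrasts their genotypes against a donor-pool reference panel
to find *diagnostic SNPs* (loci fixed for opposite homozygotes between the
panels), scans the whole recipient pool for donor-allele frequencies at
those SNPs, and groups high-frequency SNPs into LD-backed introgression
segments.  A GFF3 window lookup annotates segments with nearby gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SnpRecord, normalize_chrom
from .ld import LdPairs
from .structure import AncestryResult

__all__ = [
    "DiagnosticSnpSet",
    "IntrogressionScan",
    "IntrogressionSegment",
    "identify_pure_accessions",
    "find_diagnostic_snps",
    "introgression_scan",
    "detect_segments",
    "genes_in_window",
]

FREQ_BINS = ("<=10%", "11-15%", "16-19%", ">20%")


def assign_bin(freq: float) -> str:
    """Donor-frequency bin: [0,0.10], (0.10,0.15], (0.15,0.20), [0.20,1].

    The published bin labels (11-15%, 16-19%, >20%) leave gaps between their
    round-number edges; the half-open intervals above partition [0,1] with the
    >=20% boundary assigned to the top bin.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency {freq} outside [0, 1]")
    if freq >= 0.20:
        return ">20%"
    if freq > 0.15:
        return "16-19%"
    if freq > 0.10:
        return "11-15%"
    return "<=10%"


@dataclass
class DiagnosticSnpSet:
    """Fixed-contrast loci between a recipient and a donor reference panel.

    ``alt_in_donor`` holds SNPs where the recipient panel is homozygous
    reference and the donor panel homozygous alternative; ``alt_in_recipient``
    is the mirrored set.  The two sets are disjoint by construction.
    """

    alt_in_donor: list[str]
    alt_in_recipient: list[str]
    recipient_panel: list[str] = field(default_factory=list)
    donor_panel: list[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.alt_in_donor) & set(self.alt_in_recipient)
        if overlap:
            raise ValueError(f"diagnostic orientation sets overlap: {sorted(overlap)[:5]}")

    @property
    def all_ids(self) -> list[str]:
        return list(self.alt_in_donor) + list(self.alt_in_recipient)

    def __len__(self) -> int:
        return len(self.alt_in_donor) + len(self.alt_in_recipient)


@dataclass
class IntrogressionScan:
    """Per-diagnostic-SNP donor-allele frequency in the recipient pool."""

    table: pd.DataFrame  # columns: snp, chrom, pos, freq, bin

    def __post_init__(self):
        t = self.table
        if len(t) and ((t["freq"] < 0).any() or (t["freq"] > 1).any()):
            raise ValueError("scan frequencies outside [0, 1]")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def max_freq(self) -> float:
        return float(self.table["freq"].max())


@dataclass
class IntrogressionSegment:
    """A run of high-donor-frequency diagnostic SNPs in mutual strong LD."""

    chrom: str
    snp_ids: list[str]
    start_bp: int
    end_bp: int
    min_pair_r2: float
    max_donor_freq: float

    def to_bed_line(self) -> str:
        # BED is 0-based half-open; the 1-based inclusive map converts as start-1
        return f"{self.chrom}\t{self.start_bp - 1}\t{self.end_bp}\t{len(self.snp_ids)}snp"


def identify_pure_accessions(chrom_ancestry: Sequence[AncestryResult],
                             pool: int, pure_tol: float = 0.999) -> list[str]:
    """Accessions with membership >= ``pure_tol`` for ``pool`` on every chromosome.

    ``chrom_ancestry`` must be label-aligned per-chromosome results (as
    produced by :func:`beanpanel.structure.per_chromosome_ancestry`); ``pool``
    is the cluster column index of the recipient pool.
    """
    if not chrom_ancestry:
        raise ValueError("no per-chromosome ancestry results given")
    accs = chrom_ancestry[0].accessions
    ok = np.ones(len(accs), dtype=bool)
    for res in chrom_ancestry:
        if res.accessions != accs:
            raise ValueError("per-chromosome results disagree on accession order")
        ok &= res.Q[:, pool] >= pure_tol
    pure = [a for a, keep in zip(accs, ok) if keep]
    if not pure:
        raise ValueError(
            f"no accession is pure at tolerance {pure_tol}; consider lowering pure_tol")
    return pure


def find_diagnostic_snps(G: GenotypeMatrix, pure_recipient_ids: Sequence[str],
                         donor_ids: Sequence[str],
                         max_missing: float = 0.0) -> DiagnosticSnpSet:
    """Genotype-contrast analysis between a pure recipient and a donor panel.

    A SNP is diagnostic iff every recipient-panel call is one homozygote and
    every donor-panel call the opposite homozygote.  Any heterozygous call in
    either panel disqualifies the SNP; missing calls are tolerated up to a
    fraction ``max_missing`` per panel.
    """
    rec = list(pure_recipient_ids)
    don = list(donor_ids)
    if not rec or not don:
        raise ValueError("both contrast panels must be non-empty")
    overlap = set(rec) & set(don)
    if overlap:
        raise ValueError(f"recipient and donor panels overlap: {sorted(overlap)[:5]}")
    R = G.dosage[G.accession_index(rec)]
    A = G.dosage[G.accession_index(don)]

    def panel_state(M):
        """Per SNP: 0/2 if the panel is uniformly that homozygote, else NaN."""
        miss_frac = np.isnan(M).mean(axis=0)
        any_het = np.nansum(M == 1.0, axis=0) > 0
        with np.errstate(invalid="ignore"):
            all0 = np.all(np.isnan(M) | (M == 0.0), axis=0) & ~np.all(np.isnan(M), axis=0)
            all2 = np.all(np.isnan(M) | (M == 2.0), axis=0) & ~np.all(np.isnan(M), axis=0)
        state = np.full(M.shape[1], np.nan)
        ok = (miss_frac <= max_missing) & ~any_het
        state[ok & all0] = 0.0
        state[ok & all2] = 2.0
        return state

    rs, ds = panel_state(R), panel_state(A)
    ids = G.snps["id"].to_numpy()
    alt_in_donor = ids[(rs == 0.0) & (ds == 2.0)].tolist()
    alt_in_recipient = ids[(rs == 2.0) & (ds == 0.0)].tolist()
    return DiagnosticSnpSet(alt_in_donor, alt_in_recipient,
                            recipient_panel=rec, donor_panel=don)


def introgression_scan(G: GenotypeMatrix, recipient_ids: Sequence[str],
                       diag: DiagnosticSnpSet) -> IntrogressionScan:
    """Donor-allele frequency at every diagnostic SNP across the recipient pool.

    The scan runs over *all* recipient-pool accessions (not only the pure ones
    used for discovery).  Heterozygotes count as one donor-allele copy:
    freq = (2 x donor homozygotes + heterozygotes) / (2 x non-missing).
    """
    if len(diag) == 0:
        raise ValueError("diagnostic SNP set is empty")
    rows = G.accession_index(list(recipient_ids))
    cols = G.snp_index(diag.all_ids)
    D = G.dosage[np.ix_(rows, cols)]
    # donor dosage: alternative-allele dosage where the donor pool is fixed for
    # the alternative allele, reference dosage (2 - d) for the mirrored set
    donor_dosage = D.copy()
    n_alt_donor = len(diag.alt_in_donor)
    donor_dosage[:, n_alt_donor:] = 2.0 - donor_dosage[:, n_alt_donor:]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(donor_dosage, axis=0) / 2.0
    sub = G.snps.iloc[cols]
    table = pd.DataFrame({
        "snp": sub["id"].to_numpy(), "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(), "freq": freq,
        "bin": [assign_bin(f) for f in freq],
    }).sort_values(["chrom", "pos"], ignore_index=True)
    return IntrogressionScan(table)


def detect_segments(scan: IntrogressionScan, ld_pairs: LdPairs,
                    freq_min: float = 0.20, r2_min: float = 0.8,
                    max_span_bp: float = 5_000_000) -> list[IntrogressionSegment]:
    """Group high-frequency diagnostic SNPs into LD-backed segments.

    Per chromosome, SNPs with donor frequency >= ``freq_min`` are walked in
    map order; a SNP joins the open segment if its r2 with every current
    member is >= ``r2_min`` and the segment span stays <= ``max_span_bp``,
    otherwise it opens a new segment.  Singleton segments are allowed.
    """
    r2_lookup: dict[tuple[str, str], float] = {}
    for a, b, r2 in zip(ld_pairs.table["snp_a"], ld_pairs.table["snp_b"],
                        ld_pairs.table["r2"]):
        r2_lookup[(a, b)] = r2
        r2_lookup[(b, a)] = r2

    def pair_r2(a: str, b: str) -> float:
        return r2_lookup.get((a, b), 0.0)

    segments: list[IntrogressionSegment] = []
    qual = scan.table[scan.table["freq"] >= freq_min]
    for chrom, sub in qual.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        current: list[tuple[str, int, float]] = []  # (id, pos, freq)
        for snp, pos, freq in zip(sub["snp"], sub["pos"], sub["freq"]):
            fits = bool(current) and (pos - current[0][1] <= max_span_bp) and all(
                pair_r2(snp, m) >= r2_min for m, _, _ in current)
            if fits:
                current.append((snp, int(pos), float(freq)))
            else:
                if current:
                    segments.append(_close_segment(chrom, current, pair_r2))
                current = [(snp, int(pos), float(freq))]
        if current:
            segments.append(_close_segment(chrom, current, pair_r2))
    return segments


def _close_segment(chrom, members, pair_r2) -> IntrogressionSegment:
    ids = [m for m, _, _ in members]
    pos = [p for _, p, _ in members]
    if len(ids) > 1:
        min_r2 = min(pair_r2(a, b) for i, a in enumerate(ids) for b in ids[i + 1:])
    else:
        min_r2 = 1.0
    return IntrogressionSegment(
        chrom=chrom, snp_ids=ids, start_bp=min(pos), end_bp=max(pos),
        min_pair_r2=float(min_r2), max_donor_freq=max(f for _, _, f in members))


def genes_in_window(gff_path, snp: SnpRecord, window_bp: int = 2_000_000,
                    ) -> list[dict]:
    """Genes whose span intersects a window centred on the SNP.

    The window extends ``window_bp / 2`` each side, clipped at position 1.
    Each gene is returned with a signed distance: 0 if the SNP lies inside the
    gene, positive if the gene starts downstream of the SNP, negative if it
    ends upstream.  A chromosome name absent from the GFF3 is an error.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    seqids = {f.seqid for f in db.all_features()}
    chrom = normalize_chrom(snp.chrom)
    if chrom not in seqids and snp.chrom not in seqids:
        raise ValueError(
            f"chromosome {snp.chrom!r} not present in GFF3 (has {sorted(seqids)})")
    use_chrom = chrom if chrom in seqids else snp.chrom
    half = window_bp // 2
    lo, hi = max(1, snp.pos - half), snp.pos + half
    out = []
    for gene in db.region(seqid=use_chrom, start=lo, end=hi, featuretype="gene"):
        if gene.start <= snp.pos <= gene.end:
            dist = 0
        elif gene.start > snp.pos:
            dist = gene.start - snp.pos
        else:
            dist = gene.end - snp.pos  # negative: gene upstream of the SNP
        out.append({"gene_id": gene.id, "start": gene.start, "end": gene.end,
                    "strand": gene.strand, "distance_bp": dist})
    out.sort(key=lambda g: abs(g["distance_bp"]))
    return out
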