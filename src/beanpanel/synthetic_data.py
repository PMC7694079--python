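"""Synthetic two-gene-pool bean panels with planted ground truth.

The generator emulates the statistical structure of a diversity panel of
highly inbred common-bean cultivars drawn from the two domesticated gene
pools (Mesoamerican and Andean):

* a configurable fraction of loci are *diagnostic* — fixed for opposite
  homozygous genotypes between the pools;
* non-diagnostic loci get an ancestral frequency from a symmetric Beta and
  pool frequencies drifted around it Balding-Nichols style, with the pools
  sharing ancestry but strongly drifted (array-style ascertainment then
  keeps only panel-informative loci without near-private rare variants);
* accessions are built by block-wise copying from a small set of founder
  haplotypes, which induces linkage disequilibrium on the scale of the block
  length and, because founders are partitioned among commercial classes,
  genetic differentiation among classes;
* residual heterozygosity is injected at a low rate, matching the near-total
  selfing of elite bean germplasm;
* Andean introgression segments are planted into chosen Mesoamerican
  recipients by overwriting their dosages with donor-pool alleles;
* quantitative RCBD phenotypes are driven by planted QTLs plus a polygenic
  term, block effects and residual noise.

Everything planted is recorded in a :class:`TruthRecord` so that recovery by
the analysis modules can be tested exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .phenogwas import PhenotypeTable

__all__ = [
    "SimParams",
    "IntrogressionSpec",
    "PanelMetadata",
    "TruthRecord",
    "PhenoDesign",
    "simulate_panel",
    "simulate_phenotypes",
]

MESO = "Mesoamerican"
ANDEAN = "Andean"


@dataclass
class IntrogressionSpec:
    """One planted donor segment: how many recipients, where, from which pool."""

    n_recipients: int
    chrom: int  # 1-based chromosome number
    start_bp: int
    end_bp: int
    donor: str = ANDEAN
    recipients: Optional[list[str]] = None  # explicit ids override n_recipients


@dataclass
class SimParams:
    """Conditions for the synthetic panel.

    Defaults reproduce the headline study conditions: 175 Mesoamerican plus
    10 Andean accessions typed at 2827 SNPs over 11 chromosomes, ~37.5% of
    loci diagnostic between the pools (1060), ~2% residual heterozygosity,
    three commercial classes with the Carioca class split into old/modern/line
    era groups, 22 introgression-free Mesoamerican cultivars, and a large
    planted Andean segment on chromosome Pv05 carried by ~29% of the
    Mesoamerican accessions.
    """

    n_meso: int = 175
    n_andean: int = 10
    n_chrom: int = 11
    snps_per_chrom: int = 257
    chrom_length_bp: int = 50_000_000
    frac_diagnostic: float = 0.375
    frac_diag_alt_in_andean: float = 0.5208
    ancestral_beta_shape: float = 0.5
    fst_meso: float = 0.9
    fst_andean: float = 0.7
    residual_het_rate: float = 0.02
    missing_rate: float = 0.0
    n_low_maf: int = 0
    maf_floor: float = 0.04
    pool_maf_floor: float = 0.05
    n_founders_per_class: int = 8
    n_founders_andean: int = 6
    ld_block_len_bp: int = 1_000_000
    class_sizes: Optional[dict[str, int]] = None  # Mesoamerican class counts
    era_sizes: Optional[dict[str, int]] = None    # Carioca era-group counts
    introgression: object = "auto"  # "auto" | None | list[IntrogressionSpec]
    n_pure: int = 22
    main_segment_freq: float = 0.29
    main_segment_chrom: int = 5
    main_segment_len_bp: int = 2_600_000
    scatter_diag_snps: int = 3
    scatter_max_span_bp: int = 4_000_000
    qtls: object = "auto"  # "auto" | None | list[(trait, snp_id, effect)]
    seed: int = 0

    def __post_init__(self):
        if self.n_meso < 1 or self.n_andean < 0 or self.n_chrom < 1:
            raise ValueError("accession and chromosome counts must be >= 1")
        if not 0.0 <= self.frac_diagnostic <= 1.0:
            raise ValueError("frac_diagnostic must be in [0, 1]")
        if not 0.0 <= self.residual_het_rate <= 0.05:
            raise ValueError("residual_het_rate must be in [0, 0.05]")


@dataclass
class PanelMetadata:
    """Per-accession labels: gene pool, commercial class, era group."""

    table: pd.DataFrame  # columns: accession, pool, commercial_class, era_group

    def pools(self) -> dict[str, str]:
        return dict(zip(self.table["accession"], self.table["pool"]))

    def classes(self) -> dict[str, str]:
        return dict(zip(self.table["accession"], self.table["commercial_class"]))

    def accessions_in_pool(self, pool: str) -> list[str]:
        t = self.table
        return t.loc[t["pool"] == pool, "accession"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class TruthRecord:
    """Ground truth of everything the generator planted."""

    pools: dict[str, str]
    classes: dict[str, str]
    era_groups: dict[str, str]
    diagnostic_snp_ids: list[str]
    diag_alt_in_andean: list[str]   # Andean pool fixed for the alternative allele
    diag_alt_in_meso: list[str]
    low_maf_snp_ids: list[str]
    pure_accessions: list[str]      # Mesoamerican accessions with no planted segment
    segments: list[dict]            # accession, chrom, start_bp, end_bp, donor
    qtls: list[dict]                # trait, snp_id, effect
    simulated_h2: dict[str, float] = field(default_factory=dict)
    target_freq_meso: Optional[np.ndarray] = None
    target_freq_andean: Optional[np.ndarray] = None
    ancestral_freq: Optional[np.ndarray] = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("target_freq_meso", "target_freq_andean", "ancestral_freq"):
            if d[k] is not None:
                d[k] = [None if np.isnan(x) else round(float(x), 6) for x in d[k]]
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# metadata / allocation helpers
# ---------------------------------------------------------------------------

def _drift_freqs(rng: np.random.Generator, p0: np.ndarray, fst: float) -> np.ndarray:
    """Balding-Nichols pool frequencies: Beta(p0 (1-F)/F, (1-p0) (1-F)/F)."""
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    c = (1.0 - fst) / fst
    return rng.beta(np.maximum(p0 * c, 1e-8), np.maximum((1.0 - p0) * c, 1e-8))


_CLASS_PROPS = {"Carioca": 131, "Black": 29, "Special": 15}  # of 175 Mesoamerican
_ERA_PROPS = {"old Carioca": 36, "modern Carioca": 53, "Carioca lines": 42}  # of 131


def _largest_remainder(total: int, props: dict[str, int]) -> dict[str, int]:
    keys = list(props)
    weights = np.array([props[k] for k in keys], dtype=float)
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - base))[: total - base.sum()]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def _assign_metadata(params: SimParams) -> PanelMetadata:
    meso = [f"Meso-{i + 1:03d}" for i in range(params.n_meso)]
    andean = [f"And-{i + 1:03d}" for i in range(params.n_andean)]
    class_sizes = params.class_sizes or _largest_remainder(params.n_meso, _CLASS_PROPS)
    if sum(class_sizes.values()) != params.n_meso:
        raise ValueError("class_sizes must sum to n_meso")
    classes: list[str] = []
    for cname, k in class_sizes.items():
        classes += [cname] * k
    era_sizes = params.era_sizes or _largest_remainder(
        classes.count("Carioca"), _ERA_PROPS)
    eras = []
    era_pool = [e for e, k in era_sizes.items() for _ in range(k)]
    ei = 0
    for c in classes:
        if c == "Carioca" and ei < len(era_pool):
            eras.append(era_pool[ei])
            ei += 1
        else:
            eras.append("")
    table = pd.DataFrame({
        "accession": meso + andean,
        "pool": [MESO] * params.n_meso + [ANDEAN] * params.n_andean,
        "commercial_class": classes + ["Special"] * params.n_andean,
        "era_group": eras + [""] * params.n_andean,
    })
    return PanelMetadata(table)


def _diag_counts_per_chrom(params: SimParams) -> list[int]:
    L = params.n_chrom * params.snps_per_chrom
    total = int(round(params.frac_diagnostic * L))
    cum = np.round(np.linspace(0, total, params.n_chrom + 1)).astype(int)
    return np.diff(cum).tolist()


def _resolve_introgression(params: SimParams, meta: PanelMetadata,
                           snps: pd.DataFrame, diag_mask: np.ndarray,
                           rng: np.random.Generator):
    """Turn the introgression parameter into explicit per-accession segments.

    Returns (segment dicts, pure Mesoamerican accession list).
    """
    meso = meta.accessions_in_pool(MESO)
    if params.introgression is None:
        return [], list(meso)

    if isinstance(params.introgression, (list, tuple)):
        segments = []
        carriers: set[str] = set()
        for spec in params.introgression:
            if not (1 <= spec.start_bp < spec.end_bp <= params.chrom_length_bp):
                raise ValueError(
                    f"segment {spec.start_bp}-{spec.end_bp} outside chromosome "
                    f"bounds [1, {params.chrom_length_bp}]")
            if not (1 <= spec.chrom <= params.n_chrom):
                raise ValueError(f"segment chromosome {spec.chrom} out of range")
            if spec.recipients is not None:
                recs = list(spec.recipients)
            else:
                recs = list(rng.choice(meso, size=spec.n_recipients, replace=False))
            carriers.update(recs)
            for r in recs:
                segments.append({"accession": r, "chrom": int(spec.chrom),
                                 "start_bp": int(spec.start_bp),
                                 "end_bp": int(spec.end_bp), "donor": spec.donor})
        pure = [a for a in meso if a not in carriers]
        return segments, pure

    if params.introgression != "auto":
        raise ValueError("introgression must be 'auto', None, or a list of IntrogressionSpec")

    # auto: reserve a pure set, plant one large high-frequency segment plus a
    # whole-chromosome carrier on the main chromosome, and scatter one small
    # segment into every remaining (non-pure) Mesoamerican accession.
    n_pure = min(params.n_pure, max(params.n_meso - 3, 0))
    n_main = max(1, int(round(params.main_segment_freq * params.n_meso)) - 1)
    shuffled = list(rng.permutation(meso))
    pure = sorted(shuffled[:n_pure])
    rest = shuffled[n_pure:]
    if len(rest) < n_main + 1:
        raise ValueError("n_meso too small for the auto introgression layout")
    whole_chrom_acc = rest[0]
    main_recipients = rest[1:1 + n_main]

    main_chrom = min(params.main_segment_chrom, params.n_chrom)
    chrom_label = f"Pv{main_chrom:02d}"
    on_main = snps.index[(snps["chrom"] == chrom_label) & diag_mask].to_numpy()
    if on_main.size == 0:
        raise ValueError("no diagnostic SNP on the main introgression chromosome")
    # centre the segment on the densest diagnostic run so it carries several
    # SNPs in mutual LD (the signature a segment caller keys on)
    pos_main = snps.loc[on_main, "pos"].to_numpy()
    half = params.main_segment_len_bp // 2
    covered = [(np.sum((pos_main >= p - half) & (pos_main <= p + half)), -i)
               for i, p in enumerate(pos_main)]
    center_pos = int(pos_main[-max(covered)[1]])
    main_start = max(1, center_pos - half)
    main_end = min(params.chrom_length_bp, center_pos + half)

    segments = [{"accession": whole_chrom_acc, "chrom": main_chrom,
                 "start_bp": int(params.chrom_length_bp * 0.01) + 1,
                 "end_bp": params.chrom_length_bp, "donor": ANDEAN}]
    for r in main_recipients:
        segments.append({"accession": r, "chrom": main_chrom,
                         "start_bp": main_start, "end_bp": main_end,
                         "donor": ANDEAN})
    # every non-pure accession additionally carries one small private segment —
    # cultivars bred from donor parents typically retain several tracts, and a
    # rare tract is what the per-chromosome membership screen keys on; each
    # tract spans `scatter_diag_snps` consecutive diagnostic SNPs so the
    # carrier's donor signal is unambiguous
    k_span = max(params.scatter_diag_snps, 1)
    starts: list[tuple[int, int, int]] = []  # (chrom_num, start_bp, end_bp)
    for c in range(1, params.n_chrom + 1):
        if c == main_chrom and params.n_chrom > 1:
            continue  # keep private tracts off the shared-segment chromosome
        pos_c = snps.loc[(snps["chrom"] == f"Pv{c:02d}") & diag_mask, "pos"].to_numpy()
        # disjoint runs so each scattered tract's donor alleles are private to
        # its carrier (shared donor alleles would be read as ordinary
        # within-pool polymorphism, not ancestry)
        for i in range(0, len(pos_c) - k_span + 1, k_span):
            span = int(pos_c[i + k_span - 1] - pos_c[i])
            if span <= params.scatter_max_span_bp:
                starts.append((c, max(1, int(pos_c[i]) - 25_000),
                               min(params.chrom_length_bp,
                                   int(pos_c[i + k_span - 1]) + 25_000)))
    if len(starts) < len(rest):
        raise ValueError("not enough diagnostic-SNP runs for scattered segments")
    for r, si in zip(rest, rng.choice(len(starts), size=len(rest), replace=False)):
        c, s, e = starts[int(si)]
        segments.append({"accession": r, "chrom": c, "start_bp": s,
                         "end_bp": e, "donor": ANDEAN})
    return segments, pure


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def simulate_panel(params: SimParams) -> tuple[GenotypeMatrix, PanelMetadata, TruthRecord]:
    """Simulate a two-gene-pool panel; deterministic given ``params.seed``.

    Diagnostic loci are fixed homozygous-opposite between the pools before
    introgression; planted donor segments overwrite recipient dosages with
    donor alleles; residual heterozygotes are injected only at non-diagnostic
    loci (at rate ``residual_het_rate`` genome-wide).  Non-diagnostic loci are
    ascertained the way array markers are: loci whose realised panel MAF falls
    below ``maf_floor``, or that are accidentally fixed-contrast between the
    pure-Mesoamerican and Andean panels, are redrawn.
    """
    rng = np.random.default_rng(params.seed)
    meta = _assign_metadata(params)
    n_acc = params.n_meso + params.n_andean
    L_c = params.snps_per_chrom

    # -- SNP map ------------------------------------------------------------
    frames = []
    for c in range(1, params.n_chrom + 1):
        pos = np.sort(rng.choice(
            np.arange(1, params.chrom_length_bp + 1), size=L_c, replace=False))
        frames.append(pd.DataFrame({
            "id": [f"sim{c:02d}_{k + 1:04d}" for k in range(L_c)],
            "chrom": f"Pv{c:02d}", "pos": pos}))
    snps = pd.concat(frames, ignore_index=True)
    L = len(snps)

    # -- designate diagnostic and low-MAF loci -------------------------------
    diag_mask = np.zeros(L, dtype=bool)
    per_chrom = _diag_counts_per_chrom(params)
    for c, k in enumerate(per_chrom):
        base = c * L_c
        if k > 0:
            diag_mask[base + rng.choice(L_c, size=k, replace=False)] = True
    diag_idx = np.flatnonzero(diag_mask)
    n_diag = diag_idx.size
    orient = rng.permutation(n_diag)
    n_alt_and = int(round(params.frac_diag_alt_in_andean * n_diag))
    alt_in_andean_idx = np.sort(diag_idx[orient[:n_alt_and]])
    alt_in_meso_idx = np.sort(diag_idx[orient[n_alt_and:]])

    nondiag_idx = np.flatnonzero(~diag_mask)
    if params.n_low_maf > nondiag_idx.size:
        raise ValueError("n_low_maf exceeds the number of non-diagnostic loci")
    low_maf_idx = np.sort(rng.choice(nondiag_idx, size=params.n_low_maf, replace=False))
    low_maf_mask = np.zeros(L, dtype=bool)
    low_maf_mask[low_maf_idx] = True

    segments, pure = _resolve_introgression(params, meta, snps, diag_mask, rng)

    # -- founders ------------------------------------------------------------
    class_sizes = params.class_sizes or _largest_remainder(params.n_meso, _CLASS_PROPS)
    class_names = list(class_sizes)
    nf = params.n_founders_per_class
    n_meso_founders = nf * len(class_names)
    founder_slice = {c: slice(i * nf, (i + 1) * nf) for i, c in enumerate(class_names)}

    # per-locus target allele frequencies (alternative allele): an ancestral
    # frequency drawn from a symmetric Beta, then pool frequencies drifted
    # around it Balding-Nichols style (pool-specific Fst); the two pools share
    # ancestry, so within-pool-rare alleles are rarely common in the other pool
    a0 = params.ancestral_beta_shape
    p0 = np.clip(rng.beta(a0, a0, size=L), 1e-4, 1 - 1e-4)
    tf_meso = _drift_freqs(rng, p0, params.fst_meso)
    tf_andean = _drift_freqs(rng, p0, params.fst_andean)
    # diagnostic loci: fixed opposite
    tf_meso[alt_in_andean_idx], tf_andean[alt_in_andean_idx] = 0.0, 1.0
    tf_meso[alt_in_meso_idx], tf_andean[alt_in_meso_idx] = 1.0, 0.0

    F_meso = (rng.random((n_meso_founders, L)) < tf_meso).astype(np.int8)
    F_andean = (rng.random((max(params.n_founders_andean, 1), L))
                < tf_andean).astype(np.int8)

    # -- block-wise founder copying ------------------------------------------
    n_blocks = int(np.ceil(params.chrom_length_bp / params.ld_block_len_bp))
    block_of = np.minimum(((snps["pos"].to_numpy() - 1)
                           // params.ld_block_len_bp), n_blocks - 1)
    acc_class = meta.table["commercial_class"].to_numpy()
    acc_pool = meta.table["pool"].to_numpy()
    # founder choice per accession x (chrom, block)
    fc = np.empty((n_acc, params.n_chrom * n_blocks), dtype=np.int32)
    for i in range(n_acc):
        if acc_pool[i] == MESO:
            sl = founder_slice[acc_class[i]]
            fc[i] = rng.integers(sl.start, sl.stop, size=fc.shape[1])
        else:
            fc[i] = rng.integers(0, F_andean.shape[0], size=fc.shape[1])
    chrom_of = np.repeat(np.arange(params.n_chrom), L_c)
    col_block = (chrom_of * n_blocks + block_of).astype(np.int32)

    # allele per accession/locus from the pool-specific founder matrix
    meso_rows = acc_pool == MESO
    D = np.empty((n_acc, L))
    f_idx = fc[:, col_block]  # (n_acc, L)
    D[meso_rows] = 2.0 * F_meso[f_idx[meso_rows], np.arange(L)]
    if (~meso_rows).any():
        D[~meso_rows] = 2.0 * F_andean[f_idx[~meso_rows], np.arange(L)]

    # -- ascertainment repair -------------------------------------------------
    pure_rows = np.array([a in set(pure) for a in meta.table["accession"]]) & meso_rows
    and_rows = ~meso_rows

    def _bad(j: int) -> bool:
        col = D[:, j]
        p = col.mean() / 2.0
        if min(p, 1 - p) < params.maf_floor:
            return True
        # array-style ascertainment: no near-private rare variants — each
        # pool's realised MAF is either 0 (fixed) or >= pool_maf_floor
        for pool_rows in (meso_rows, and_rows):
            if pool_rows.any():
                f = col[pool_rows].mean() / 2.0
                if 0.0 < min(f, 1.0 - f) < params.pool_maf_floor:
                    return True
        if and_rows.any() and pure_rows.any():
            pm, am = col[pure_rows], col[and_rows]
            if ((np.all(pm == 0) and np.all(am == 2))
                    or (np.all(pm == 2) and np.all(am == 0))):
                return True
        return False

    repair = [j for j in nondiag_idx if not low_maf_mask[j] and _bad(j)]
    for j in repair:
        for _ in range(500):
            p0[j] = float(np.clip(rng.beta(a0, a0), 1e-4, 1 - 1e-4))
            tf_meso[j] = _drift_freqs(rng, p0[j:j + 1], params.fst_meso)[0]
            tf_andean[j] = _drift_freqs(rng, p0[j:j + 1], params.fst_andean)[0]
            F_meso[:, j] = rng.random(n_meso_founders) < tf_meso[j]
            F_andean[:, j] = rng.random(F_andean.shape[0]) < tf_andean[j]
            D[meso_rows, j] = 2.0 * F_meso[f_idx[meso_rows, j], j]
            if (~meso_rows).any():
                D[~meso_rows, j] = 2.0 * F_andean[f_idx[~meso_rows, j], j]
            if not _bad(j):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not ascertain locus {j}")

    # -- planted low-MAF loci: a single heterozygous copy in one accession,
    # giving MAF 1/(2N) — sub-threshold for any panel of a few dozen or more
    for j in low_maf_idx:
        D[:, j] = 0.0
        D[int(rng.integers(0, n_acc)), j] = 1.0

    # -- residual heterozygosity (non-diagnostic, non-planted loci only) -----
    if params.residual_het_rate > 0 and params.frac_diagnostic < 1.0:
        eligible = ~diag_mask & ~low_maf_mask
        rate = min(params.residual_het_rate / max(eligible.mean(), 1e-9), 1.0)
        het_hits = rng.random((n_acc, L)) < rate
        het_hits[:, ~eligible] = False
        D[het_hits] = 1.0

    # -- planted introgression ------------------------------------------------
    acc_index = {a: i for i, a in enumerate(meta.table["accession"])}
    pos_arr = snps["pos"].to_numpy()
    for seg in segments:
        chrom_label = f"Pv{seg['chrom']:02d}"
        in_seg = ((snps["chrom"] == chrom_label).to_numpy()
                  & (pos_arr >= seg["start_bp"]) & (pos_arr <= seg["end_bp"]))
        if not in_seg.any():
            continue
        donor_F = F_andean if seg["donor"] == ANDEAN else F_meso
        donor_hap = donor_F[int(rng.integers(0, donor_F.shape[0]))]
        D[acc_index[seg["accession"]], in_seg] = 2.0 * donor_hap[in_seg]

    # -- missing calls ---------------------------------------------------------
    if params.missing_rate > 0:
        miss = rng.random((n_acc, L)) < params.missing_rate
        D[miss] = np.nan

    tfm, tfa, tf0 = tf_meso.copy(), tf_andean.copy(), p0.copy()
    tfm[diag_mask | low_maf_mask] = np.nan
    tfa[diag_mask | low_maf_mask] = np.nan
    tf0[diag_mask | low_maf_mask] = np.nan

    G = GenotypeMatrix(meta.table["accession"].tolist(), snps, D)
    truth = TruthRecord(
        pools=meta.pools(),
        classes=meta.classes(),
        era_groups={a: e for a, e in zip(meta.table["accession"],
                                         meta.table["era_group"]) if e},
        diagnostic_snp_ids=snps["id"].iloc[diag_idx].tolist(),
        diag_alt_in_andean=snps["id"].iloc[alt_in_andean_idx].tolist(),
        diag_alt_in_meso=snps["id"].iloc[alt_in_meso_idx].tolist(),
        low_maf_snp_ids=snps["id"].iloc[low_maf_idx].tolist(),
        pure_accessions=sorted(pure),
        segments=segments,
        qtls=_resolve_qtls(params, meta, snps, D, diag_mask, rng),
        target_freq_meso=tfm,
        target_freq_andean=tfa,
        ancestral_freq=tf0,
    )
    return G, meta, truth


_DEFAULT_EFFECTS = {"DTF": 1.85, "DTM": 2.11, "HAB": 0.77}  # one residual sd (DTF/DTM)


def _resolve_qtls(params: SimParams, meta: PanelMetadata, snps: pd.DataFrame,
                  D: np.ndarray, diag_mask: np.ndarray,
                  rng: np.random.Generator) -> list[dict]:
    if params.qtls is None:
        return []
    if isinstance(params.qtls, (list, tuple)):
        return [{"trait": t, "snp_id": s, "effect": float(e)}
                for t, s, e in params.qtls]
    if params.qtls != "auto":
        raise ValueError("qtls must be 'auto', None, or a list of (trait, snp_id, effect)")
    # auto: one QTL shared by DTF and DTM (inducing their positive correlation)
    # and one for HAB, both chosen among loci polymorphic within the Carioca class
    carioca = (meta.table["commercial_class"] == "Carioca").to_numpy()
    if carioca.sum() < 4:
        carioca = np.ones(len(meta.table), dtype=bool)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(D[carioca], axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    cand = np.flatnonzero(~diag_mask & (maf >= 0.15))
    if cand.size < 2:
        cand = np.flatnonzero(~diag_mask & (maf > 0))
    picks = rng.choice(cand, size=min(2, cand.size), replace=False)
    shared = snps["id"].iloc[int(picks[0])]
    hab = snps["id"].iloc[int(picks[-1])]
    return [
        {"trait": "DTF", "snp_id": shared, "effect": _DEFAULT_EFFECTS["DTF"]},
        {"trait": "DTM", "snp_id": shared, "effect": _DEFAULT_EFFECTS["DTM"]},
        {"trait": "HAB", "snp_id": hab, "effect": _DEFAULT_EFFECTS["HAB"]},
    ]


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class PhenoDesign:
    """RCBD layout and trait model parameters.

    Trait means and residual standard deviations default to values typical of
    irrigated-season bean trials (days to flowering ~39 d with ~4.8% CV, days
    to maturation ~76 d with ~2.8% CV); growth habit is modelled on a latent
    scale and discretised to ordinal classes 1-3 (elite panels carry no
    climbing type-4 accessions).  ``h2`` targets are broad-sense
    heritabilities on a line-mean basis.
    """

    n_blocks: int = 4
    traits: tuple[str, ...] = ("DTF", "DTM", "HAB")
    trait_means: dict = field(default_factory=lambda: {"DTF": 39.0, "DTM": 76.0, "HAB": 2.0})
    residual_sd: dict = field(default_factory=lambda: {"DTF": 1.85, "DTM": 2.11, "HAB": 0.96})
    h2: dict = field(default_factory=lambda: {"DTF": 0.78, "DTM": 0.83, "HAB": 0.83})
    block_sd: float = 0.4
    hab_cuts: tuple[float, float] = (-0.6, 0.6)  # latent thresholds in total-sd units


def simulate_phenotypes(G: GenotypeMatrix, truth: TruthRecord,
                        design: PhenoDesign | None = None,
                        seed: int = 0) -> PhenotypeTable:
    """Simulate plot-level RCBD phenotypes for every accession in ``G``.

    Plot value = trait mean + sum(QTL effect x centred dosage) + polygenic
    term + block effect + residual.  The polygenic variance is set so the
    line-mean broad-sense heritability matches ``design.h2``; the realised
    heritability is recorded in ``truth.simulated_h2``.  HAB is generated on a
    latent scale and discretised to classes 1-3.  Deterministic given ``seed``
    (a separate stream from the genotype seed, so phenotype replicates can be
    regenerated on a fixed panel).
    """
    design = design or PhenoDesign()
    if design.n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    n = G.n_accessions
    records = []
    for trait in design.traits:
        mu = design.trait_means[trait]
        sd_e = design.residual_sd[trait]
        h2 = design.h2[trait]
        qtls = [q for q in truth.qtls if q["trait"] == trait]
        for q in qtls:
            if q["snp_id"] not in set(G.snps["id"]):
                raise KeyError(f"QTL SNP {q['snp_id']!r} not present in genotype matrix")
        g = np.zeros(n)
        for q in qtls:
            j = int(G.snp_index([q["snp_id"]])[0])
            d = G.dosage[:, j]
            d = np.where(np.isnan(d), np.nanmean(d), d)
            g += q["effect"] * (d - d.mean())
        var_target = h2 / (1.0 - h2) * sd_e ** 2 / design.n_blocks
        var_qtl = g.var()
        sd_u = np.sqrt(max(var_target - var_qtl, 0.0))
        u = rng.normal(0.0, sd_u, size=n)
        genetic = g + u
        blocks = rng.normal(0.0, design.block_sd, size=design.n_blocks)
        resid = rng.normal(0.0, sd_e, size=(n, design.n_blocks))
        y = mu + genetic[:, None] + blocks[None, :] + resid
        gv = genetic.var(ddof=1)
        truth.simulated_h2[trait] = float(gv / (gv + sd_e ** 2 / design.n_blocks))
        if trait == "HAB":
            tot_sd = np.sqrt(genetic.var() + design.block_sd ** 2 + sd_e ** 2)
            c1 = mu + design.hab_cuts[0] * tot_sd
            c2 = mu + design.hab_cuts[1] * tot_sd
            y = np.digitize(y, [c1, c2]) + 1.0  # ordinal classes 1..3
        for b in range(design.n_blocks):
            for i, acc in enumerate(G.accessions):
                records.append((acc, b + 1, trait, y[i, b]))
    return PhenotypeTable(
        pd.DataFrame(records, columns=["accession", "block", "trait", "value"]))
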