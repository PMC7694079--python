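import numpy as np
import pandas as pd
import pytest

from beanpanel import (
    GenotypeMatrix, SimParams, apply_qc_filters, em_admixture,
    find_diagnostic_snps, identify_pure_accessions, impute_missing,
    introgression_scan, per_chromosome_ancestry, simulate_panel,
)

MESO, ANDEAN = "Mesoamerican", "Andean"


def make_matrix(dosage, chrom="Pv01", start=1000, step=1000, accessions=None,
                ids=None):
    """GenotypeMatrix from a raw (accessions x snps) dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, L = dosage.shape
    accessions = accessions or [f"acc{i}" for i in range(n)]
    ids = ids or [f"snp{j}" for j in range(L)]
    snps = pd.DataFrame({"id": ids, "chrom": [chrom] * L,
                         "pos": [start + j * step for j in range(L)]})
    return GenotypeMatrix(accessions, snps, dosage)


@pytest.fixture(scope="session")
def small_params():
    return SimParams(
        n_meso=60, n_andean=10, n_chrom=4, snps_per_chrom=130,
        chrom_length_bp=30_000_000, residual_het_rate=0.0,
        n_pure=14, seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_params):
    """A modest study-structured panel shared by pipeline-level tests."""
    return simulate_panel(small_params)


@pytest.fixture(scope="session")
def small_imputed(small_panel):
    G, meta, truth = small_panel
    Gq, report = apply_qc_filters(G)
    return impute_missing(Gq), report


@pytest.fixture(scope="session")
def small_pipeline(small_panel, small_imputed):
    """Full structure -> purity -> diagnostic -> scan chain on the small panel."""
    G, meta, truth = small_panel
    Gi, _ = small_imputed
    meso = [a for a in Gi.accessions if truth.pools[a] == MESO]
    andean = [a for a in Gi.accessions if truth.pools[a] == ANDEAN]
    genome = em_admixture(Gi, K=2, seed=11, n_restarts=3)
    meso_rows = [Gi.accessions.index(a) for a in meso]
    meso_k = int(np.argmax(genome.Q[meso_rows].mean(axis=0)))
    chrom_res = per_chromosome_ancestry(Gi, K=2, seed=11, n_restarts=3)
    pure = identify_pure_accessions(chrom_res, pool=meso_k, pure_tol=0.99)
    diag = find_diagnostic_snps(Gi, pure, andean)
    scan = introgression_scan(Gi, meso, diag)
    return {
        "G": Gi, "truth": truth, "meta": meta, "meso": meso, "andean": andean,
        "genome": genome, "meso_k": meso_k, "chrom_res": chrom_res,
        "pure": pure, "diag": diag, "scan": scan,
    }
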