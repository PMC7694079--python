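import numpy as np
import pandas as pd
import pytest

from beanpanel import (
    AncestryResult, DiagnosticSnpSet, SnpRecord, detect_segments,
    find_diagnostic_snps, genes_in_window, identify_pure_accessions,
    introgression_scan, pairwise_r2,
)
from beanpanel.introgression import assign_bin
from beanpanel.ld import LdPairs
from conftest import make_matrix

MESO, ANDEAN = "Mesoamerican", "Andean"


def ancestry(accs, q_pool, scope="Pv01"):
    Q = np.column_stack([q_pool, 1.0 - np.asarray(q_pool)])
    return AncestryResult(list(accs), Q, np.full((2, 5), 0.5), loglik=-1.0,
                          K=2, seed=0, scope=scope)


class TestIdentifyPure:
    def test_inclusion_and_exclusion(self):
        accs = ["a", "b", "c"]
        chrom1 = ancestry(accs, [1.0, 0.90, 1.0], "Pv01")
        chrom2 = ancestry(accs, [1.0, 1.0, 0.9995], "Pv02")
        pure = identify_pure_accessions([chrom1, chrom2], pool=0)
        assert pure == ["a", "c"]  # b fails on Pv01 at default 0.999

    def test_empty_result_suggests_lower_tol(self):
        accs = ["a", "b"]
        res = ancestry(accs, [0.95, 0.9])
        with pytest.raises(ValueError, match="pure_tol"):
            identify_pure_accessions([res], pool=0)

    def test_planted_pure_set_recovered_exactly(self, small_pipeline):
        """The accessions simulated without any donor segment are exactly the
        ones the per-chromosome membership screen returns."""
        assert sorted(small_pipeline["pure"]) == \
            sorted(small_pipeline["truth"].pure_accessions)


class TestFindDiagnosticSnps:
    def test_orientation_sets(self):
        # snp0: recipients 0 / donors 2; snp1: recipients 2 / donors 0;
        # snp2: monomorphic everywhere; snp3: donor het present
        d = np.array([
            [0, 2, 0, 0], [0, 2, 0, 0], [0, 2, 0, 0],   # recipients
            [2, 0, 0, 2], [2, 0, 0, 2], [2, 0, 0, 1],   # donors
        ], dtype=float)
        G = make_matrix(d)
        rec, don = G.accessions[:3], G.accessions[3:]
        diag = find_diagnostic_snps(G, rec, don)
        assert diag.alt_in_donor == ["snp0"]
        assert diag.alt_in_recipient == ["snp1"]
        assert "snp2" not in diag.all_ids and "snp3" not in diag.all_ids

    def test_overlapping_panels_error(self):
        G = make_matrix(np.zeros((4, 2)) + [[0, 2]])
        with pytest.raises(ValueError, match="overlap"):
            find_diagnostic_snps(G, G.accessions[:2], G.accessions[1:])

    def test_missing_tolerance(self):
        d = np.array([[0.0, 0.0], [np.nan, 0.0], [2.0, 2.0], [2.0, 2.0]])
        G = make_matrix(d)
        strict = find_diagnostic_snps(G, G.accessions[:2], G.accessions[2:],
                                      max_missing=0.0)
        assert strict.all_ids == ["snp1"]
        lax = find_diagnostic_snps(G, G.accessions[:2], G.accessions[2:],
                                   max_missing=0.5)
        assert sorted(lax.all_ids) == ["snp0", "snp1"]

    def test_matches_brute_force_enumeration(self, small_pipeline):
        """Vectorised contrast analysis equals a per-SNP loop."""
        G = small_pipeline["G"]
        truth = small_pipeline["truth"]
        rec = truth.pure_accessions
        don = small_pipeline["andean"]
        diag = find_diagnostic_snps(G, rec, don)
        R = G.dosage[G.accession_index(rec)]
        A = G.dosage[G.accession_index(don)]
        expected = []
        for j, sid in enumerate(G.snps["id"]):
            r, a = R[:, j], A[:, j]
            if ((r == 0).all() and (a == 2).all()) or \
               ((r == 2).all() and (a == 0).all()):
                expected.append(sid)
        assert sorted(diag.all_ids) == sorted(expected)
        # and the planted set is recovered exactly
        assert sorted(diag.all_ids) == sorted(truth.diagnostic_snp_ids)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            DiagnosticSnpSet(["s1", "s2"], ["s2", "s3"])


class TestIntrogressionScan:
    def test_frequency_counting(self):
        # 10 recipients; snp0: 2 donor homozygotes -> 0.20; snp1: 1 het -> 0.05
        d = np.zeros((12, 2))
        d[0, 0] = d[1, 0] = 2.0
        d[2, 1] = 1.0
        d[10:, :] = 2.0  # donors
        G = make_matrix(d)
        diag = DiagnosticSnpSet(["snp0", "snp1"], [])
        scan = introgression_scan(G, G.accessions[:10], diag)
        t = scan.table.set_index("snp")
        assert t.loc["snp0", "freq"] == pytest.approx(0.20)
        assert t.loc["snp0", "bin"] == ">20%"  # boundary assigned upward
        assert t.loc["snp1", "freq"] == pytest.approx(0.05)
        assert t.loc["snp1", "bin"] == "<=10%"

    def test_bins_partition_unit_interval(self):
        for f in np.linspace(0, 1, 201):
            assert assign_bin(float(f)) in ("<=10%", "11-15%", "16-19%", ">20%")
        assert assign_bin(0.10) == "<=10%"
        assert assign_bin(0.101) == "11-15%"
        assert assign_bin(0.15) == "11-15%"
        assert assign_bin(0.151) == "16-19%"
        assert assign_bin(0.199) == "16-19%"
        assert assign_bin(0.20) == ">20%"

    def test_planted_segment_frequency_recovered(self, small_pipeline,
                                                 small_params):
        """Scan frequency at the shared planted segment equals
        recipients / n_meso; outside all segments it is ~0."""
        scan = small_pipeline["scan"]
        truth = small_pipeline["truth"]
        n_main = round(small_params.main_segment_freq * small_params.n_meso)
        assert scan.max_freq() == pytest.approx(n_main / small_params.n_meso,
                                                abs=1e-9)
        covered = set()
        pos = small_pipeline["G"].snps.set_index("id")
        for seg in truth.segments:
            for sid in scan.table["snp"]:
                row = pos.loc[sid]
                if (row["chrom"] == f"Pv{seg['chrom']:02d}"
                        and seg["start_bp"] <= row["pos"] <= seg["end_bp"]):
                    covered.add(sid)
        outside = scan.table[~scan.table["snp"].isin(covered)]
        assert (outside["freq"] == 0).all()  # residual_het_rate = 0 here

    def test_empty_diag_set_error(self):
        G = make_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="empty"):
            introgression_scan(G, ["acc0"], DiagnosticSnpSet([], []))


def scan_from(rows):
    t = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "freq"])
    t["bin"] = [assign_bin(f) for f in t["freq"]]
    from beanpanel.introgression import IntrogressionScan
    return IntrogressionScan(t)


def pairs_from(r2map):
    rows = [(a.split("|")[0], a.split("|")[1], r) for a, r in r2map.items()]
    return LdPairs(pd.DataFrame(
        [("Pv01", a, b, 1000.0, r) for a, b, r in rows],
        columns=["chrom", "snp_a", "snp_b", "dist_bp", "r2"]))


class TestDetectSegments:
    def test_five_snps_in_strong_ld_form_one_segment(self):
        rows = [(f"s{i}", "Pv01", 1_000_000 + i * 400_000, 0.25)
                for i in range(5)]
        r2map = {f"s{i}|s{j}": 1.0 for i in range(5) for j in range(i + 1, 5)}
        segs = detect_segments(scan_from(rows), pairs_from(r2map),
                               max_span_bp=2_700_000)
        assert len(segs) == 1
        assert segs[0].snp_ids == [f"s{i}" for i in range(5)]
        assert segs[0].min_pair_r2 == 1.0

    def test_weak_ld_gives_singletons(self):
        rows = [("s0", "Pv01", 1_000_000, 0.3), ("s1", "Pv01", 1_500_000, 0.3)]
        segs = detect_segments(scan_from(rows), pairs_from({"s0|s1": 0.3}))
        assert [s.snp_ids for s in segs] == [["s0"], ["s1"]]

    def test_span_cap_breaks_segments(self):
        rows = [("s0", "Pv01", 1_000_000, 0.3), ("s1", "Pv01", 9_000_000, 0.3)]
        segs = detect_segments(scan_from(rows), pairs_from({"s0|s1": 1.0}),
                               max_span_bp=5_000_000)
        assert len(segs) == 2

    def test_sub_threshold_frequencies_ignored(self):
        rows = [("s0", "Pv01", 1_000_000, 0.1)]
        segs = detect_segments(scan_from(rows), pairs_from({}))
        assert segs == []

    def test_planted_segment_recovered_with_high_jaccard(self, small_pipeline):
        """The planted shared segment is recovered with member-SNP Jaccard
        >= 0.9 against the diagnostic SNPs it covers."""
        G = small_pipeline["G"]
        truth = small_pipeline["truth"]
        scan = small_pipeline["scan"]
        diag_ids = set(small_pipeline["diag"].all_ids)
        ld = pairwise_r2(G.subset(
            snp_mask=G.snps["id"].isin(diag_ids).to_numpy()))
        segs = detect_segments(scan, ld)
        main = max((s for s in truth.segments), key=lambda s: sum(
            1 for a in truth.segments if a["chrom"] == s["chrom"]
            and a["start_bp"] == s["start_bp"]))
        pos = G.snps.set_index("id")
        members = {sid for sid in diag_ids
                   if pos.loc[sid, "chrom"] == f"Pv{main['chrom']:02d}"
                   and main["start_bp"] <= pos.loc[sid, "pos"] <= main["end_bp"]}
        best = max(segs, key=lambda s: len(set(s.snp_ids) & members))
        jac = len(set(best.snp_ids) & members) / len(set(best.snp_ids) | members)
        assert jac >= 0.9

    def test_members_inside_bounds_and_disjoint(self, small_pipeline):
        G = small_pipeline["G"]
        scan = small_pipeline["scan"]
        ld = pairwise_r2(G)
        segs = detect_segments(scan, ld, freq_min=0.05)
        pos = G.snps.set_index("id")
        seen = set()
        for s in segs:
            for sid in s.snp_ids:
                assert s.start_bp <= pos.loc[sid, "pos"] <= s.end_bp
                assert sid not in seen
                seen.add(sid)


GFF = """##gff-version 3
Pv01\ttest\tgene\t900000\t1100000\t.\t+\t.\tID=geneA
Pv01\ttest\tgene\t1400000\t1600000\t.\t-\t.\tID=geneB
Pv01\ttest\tgene\t5000000\t5200000\t.\t+\t.\tID=geneC
Pv02\ttest\tgene\t1000000\t1200000\t.\t+\t.\tID=geneD
"""


class TestGenesInWindow:
    @pytest.fixture()
    def gff_path(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(GFF)
        return p

    def test_hand_enumerated_window(self, gff_path):
        snp = SnpRecord("s1", "Pv01", 1_000_000)
        genes = genes_in_window(gff_path, snp, window_bp=2_000_000)
        byid = {g["gene_id"]: g for g in genes}
        assert set(byid) == {"geneA", "geneB"}  # geneC is 4 Mb away
        assert byid["geneA"]["distance_bp"] == 0  # SNP inside geneA
        assert byid["geneB"]["distance_bp"] == 400_000

    def test_upstream_gene_negative_distance(self, gff_path):
        snp = SnpRecord("s2", "Pv01", 1_700_000)
        genes = genes_in_window(gff_path, snp, window_bp=1_000_000)
        byid = {g["gene_id"]: g for g in genes}
        assert byid["geneB"]["distance_bp"] == -100_000

    def test_empty_region(self, gff_path):
        snp = SnpRecord("s3", "Pv01", 20_000_000)
        assert genes_in_window(gff_path, snp, window_bp=1_000_000) == []

    def test_chromosome_mismatch_lists_names(self, gff_path):
        snp = SnpRecord("s4", "Pv09", 1_000_000)
        with pytest.raises(ValueError, match="Pv09"):
            genes_in_window(gff_path, snp)
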