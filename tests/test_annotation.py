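"""Unit and property tests for annotation geometry and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import admp_atlas as aa
from admp_atlas.annotation import (
    AnnotationError,
    GenomicInterval,
    assign_state,
    cgi_membership,
    classify_cgi,
    enrichment_from_counts,
    merge_intervals,
    nearest_gene,
)


def brute_force_cgi(chrom, pos, islands):
    """Linear-scan oracle for island/shore/non-CGI classification."""
    best = None
    for iv in islands:
        if iv.chrom != chrom:
            continue
        if iv.start <= pos < iv.end:
            return "island"
        gap = iv.start - pos if pos < iv.start else pos - iv.end
        best = gap if best is None else min(best, gap)
    if best is not None and best <= 2000:
        return "shore"
    return "non_CGI"


class TestClassifyCgi:
    ISLANDS = [GenomicInterval("chr1", 10_000, 12_000)]

    @pytest.mark.parametrize("pos,expected", [
        (11_000, "island"),        # midpoint
        (10_000, "island"),        # half-open start
        (12_000, "shore"),         # first base past the island (end + 1)
        (14_000, "shore"),         # exactly 2 kb out: inclusive shore edge
        (14_001, "non_CGI"),       # 2001 bp out
        (8_000, "shore"),
        (7_999, "non_CGI"),
    ])
    def test_boundary_geometry(self, pos, expected):
        probes = pd.DataFrame({"chrom": ["chr1"], "pos": [pos]}, index=["p"])
        assert classify_cgi(probes, self.ISLANDS).iloc[0] == expected

    def test_overlapping_islands_merged(self):
        islands = [GenomicInterval("chr1", 100, 300),
                   GenomicInterval("chr1", 200, 500)]
        merged = merge_intervals(islands)["chr1"]
        assert merged[0].tolist() == [100] and merged[1].tolist() == [500]

    def test_missing_chromosome_is_non_cgi(self):
        probes = pd.DataFrame({"chrom": ["chrX"], "pos": [50]}, index=["p"])
        assert classify_cgi(probes, self.ISLANDS).iloc[0] == "non_CGI"

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(17)
        islands = []
        for _ in range(60):
            s = int(rng.integers(0, 500_000))
            islands.append(GenomicInterval("chr1", s, s + int(rng.integers(200, 3000))))
        probes = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(0, 520_000, size=2000),
        }, index=[f"p{i}" for i in range(2000)])
        got = classify_cgi(probes, islands)
        for pid, row in probes.iterrows():
            assert got[pid] == brute_force_cgi("chr1", row["pos"], islands)


class TestAssignState:
    SEG = [GenomicInterval("chr1", 0, 1000, "Quies"),
           GenomicInterval("chr1", 1000, 2000, "Enh"),
           GenomicInterval("chr1", 2000, 3000, "ReprPC")]

    def test_interior_and_boundary(self):
        probes = pd.DataFrame({"chrom": "chr1", "pos": [1500, 1000, 2000]},
                              index=["mid", "left_edge", "next_edge"])
        states = assign_state(probes, self.SEG)
        # boundary probes belong to the interval beginning there (half-open)
        assert states.tolist() == ["Enh", "Enh", "ReprPC"]

    def test_uncovered_probe_flagged(self):
        probes = pd.DataFrame({"chrom": "chr1", "pos": [5000]}, index=["p"])
        assert assign_state(probes, self.SEG).iloc[0] == "unassigned"

    def test_overlapping_segments_rejected(self):
        seg = self.SEG + [GenomicInterval("chr1", 2500, 2600, "Tx")]
        probes = pd.DataFrame({"chrom": "chr1", "pos": [10]}, index=["p"])
        with pytest.raises(AnnotationError, match="overlapping"):
            assign_state(probes, seg)

    def test_unknown_state_rejected(self):
        probes = pd.DataFrame({"chrom": "chr1", "pos": [10]}, index=["p"])
        with pytest.raises(AnnotationError, match="invalid state"):
            assign_state(probes, [GenomicInterval("chr1", 0, 100, "Exotic")])


class TestNearestGene:
    GENES = pd.DataFrame({
        "gene_id": ["GA", "GB"],
        "chrom": ["chr1", "chr1"],
        "start": [10_000, 30_000],
        "end": [20_000, 40_000],
        "strand": ["+", "-"],
    })

    def test_upstream_probe(self):
        probes = pd.DataFrame({"chrom": "chr1", "pos": [9_900]}, index=["p"])
        out = nearest_gene(probes, self.GENES)
        assert out.loc["p", "nearest_gene"] == "GA"
        assert out.loc["p", "gene_distance"] == 100

    def test_equidistant_tie_breaks_lexicographically(self):
        # midpoint between GA end (20000) and GB start (30000)
        probes = pd.DataFrame({"chrom": "chr1", "pos": [25_000]}, index=["p"])
        assert nearest_gene(probes, self.GENES).loc["p", "nearest_gene"] == "GA"

    def test_probe_inside_gene_measured_to_nearer_end(self):
        probes = pd.DataFrame({"chrom": "chr1", "pos": [11_000]}, index=["p"])
        out = nearest_gene(probes, self.GENES)
        assert out.loc["p", "gene_distance"] == 1000

    def test_no_gene_on_chromosome_unmapped(self):
        probes = pd.DataFrame({"chrom": "chr9", "pos": [100]}, index=["p"])
        out = nearest_gene(probes, self.GENES)
        assert pd.isna(out.loc["p", "nearest_gene"])

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        genes = pd.DataFrame({
            "gene_id": [f"G{i:03d}" for i in range(50)],
            "chrom": rng.choice(["chr1", "chr2"], 50),
            "start": rng.integers(0, 900_000, 50),
            "strand": rng.choice(["+", "-"], 50),
        })
        genes["end"] = genes["start"] + rng.integers(1000, 50_000, 50)
        probes = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 500),
            "pos": rng.integers(0, 950_000, 500),
        }, index=[f"p{i}" for i in range(500)])
        got = nearest_gene(probes, genes)
        for pid, row in probes.iterrows():
            cand = genes[genes["chrom"] == row["chrom"]]
            d = np.minimum((cand["start"] - row["pos"]).abs(),
                           (cand["end"] - row["pos"]).abs())
            best = min(zip(d, cand["gene_id"]))
            assert got.loc[pid, "gene_distance"] == best[0]
            assert got.loc[pid, "nearest_gene"] == best[1]


class TestEnrichment:
    def test_worked_example_odds_ratio(self):
        res = enrichment_from_counts(30, 70, 10, 90)
        assert res.odds_ratio == pytest.approx(27 / 7)

    def test_worked_example_chi2(self):
        res = enrichment_from_counts(30, 70, 10, 90)
        assert res.chi2 == pytest.approx(12.5)
        assert res.p == pytest.approx(4.07e-4, rel=1e-2)

    def test_null_table_is_flat(self):
        res = enrichment_from_counts(30, 70, 30, 70)
        assert res.odds_ratio == 1.0 and res.chi2 == 0.0 and res.p == 1.0

    def test_haldane_correction_only_on_zero_cells(self):
        res = enrichment_from_counts(10, 0, 5, 85)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1
        clean = enrichment_from_counts(10, 1, 5, 85)
        assert clean.odds_ratio == (10 * 85) / (1 * 5)

    def test_degenerate_categories_flagged(self):
        assert enrichment_from_counts(0, 10, 0, 90).degenerate  # empty category
        assert enrichment_from_counts(10, 0, 90, 0).degenerate  # universal

    def test_subset_precondition(self):
        with pytest.raises(AnnotationError, match="subset"):
            aa.enrichment_test(["x"], ["a", "b", "c", "d"], ["a"])

    @given(st.tuples(*[st.integers(1, 400)] * 4))
    def test_matches_scipy_contingency(self, cells):
        """Pearson chi-squared equals scipy's (no continuity correction)."""
        from scipy.stats import chi2_contingency

        a, b, c, d = cells
        res = enrichment_from_counts(a, b, c, d)
        chi2, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        assert res.chi2 == pytest.approx(chi2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-8, abs=1e-300)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))

    @given(st.tuples(*[st.integers(1, 400)] * 4))
    def test_symmetry_properties(self, cells):
        a, b, c, d = cells
        base = enrichment_from_counts(a, b, c, d)
        swapped = enrichment_from_counts(d, c, b, a)  # rows+columns together
        cols = enrichment_from_counts(b, a, d, c)     # columns only
        assert swapped.odds_ratio == pytest.approx(base.odds_ratio)
        assert swapped.chi2 == pytest.approx(base.chi2)
        assert cols.odds_ratio == pytest.approx(1.0 / base.odds_ratio)


class TestStateProfileAndJoint:
    def test_profile_partitions_admps(self, genome3, admps3):
        states = genome3.states("brain")
        tab = admps3["brain"]
        profile = aa.state_enrichment_profile(tab.probes("gain"),
                                              tab.tested_probes, states)
        assert len(profile) == 15
        assert sum(r.a for r in profile) == len(tab.probes("gain"))

    def test_profile_flags_planted_state_bias(self):
        """An aDMP set packed into ReprPC probes is flagged significant."""
        rng = np.random.default_rng(5)
        probes = [f"p{i}" for i in range(2000)]
        states = pd.Series(rng.choice(["ReprPC", "Quies", "Enh"], 2000,
                                      p=[0.15, 0.7, 0.15]), index=probes)
        repr_probes = list(states.index[states == "ReprPC"][:150])
        other = list(states.index[states != "ReprPC"][:50])
        profile = aa.state_enrichment_profile(repr_probes + other, probes, states)
        by_cat = {r.category: r for r in profile}
        assert by_cat["ReprPC"].significant and by_cat["ReprPC"].odds_ratio > 1

    def test_joint_extreme_enrichment(self):
        probes = [f"p{i}" for i in range(400)]
        cgi = pd.Series(["island"] * 200 + ["non_CGI"] * 200, index=probes)
        ez = pd.Series([True, False] * 200, index=probes)
        both = [p for p in probes if cgi[p] == "island" and ez[p]][:50]
        res = aa.cgi_ezh2_joint_enrichment(both, probes, cgi, ez)
        assert res["both_vs_either"].significant
        assert res["both_vs_either"].odds_ratio > 5

    def test_joint_counts_conserve_restricted_background(self):
        probes = [f"p{i}" for i in range(400)]
        rng = np.random.default_rng(9)
        cgi = pd.Series(rng.choice(["island", "shore", "non_CGI"], 400),
                        index=probes)
        ez = pd.Series(rng.random(400) < 0.3, index=probes)
        admp = probes[:40]
        res = aa.cgi_ezh2_joint_enrichment(admp, probes, cgi, ez)
        r = res["both_vs_either"]
        n_both = int(((cgi == "island") & ez).sum())
        n_single = int(((cgi == "island") ^ ez).sum())
        assert r.a + r.b + r.c + r.d == n_both + n_single

    def test_cgi_membership_ids_probes_inside_islands(self, genome3):
        ids = cgi_membership(genome3.probes, genome3.cgi)
        cc = genome3.cgi_class()
        assert ids.notna().equals(cc == "island")
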