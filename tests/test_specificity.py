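"""Unit tests for cross-tissue sharing/specificity operations."""

import numpy as np
import pandas as pd
import pytest

import admp_atlas as aa
from admp_atlas.specificity import SpecificityError, round_pct

from .conftest import make_admp_table


@pytest.fixture()
def three_tissue_tables():
    """Hand-built calls: p1 gain in brain only; p2 gain everywhere;
    p3 gain in liver + loss in kidney; p4 loss in kidney."""
    gain = {"class": "gain", "slope_per_year": 0.004, "p": 1e-12,
            "p_bonf": 1e-8}
    loss = {"class": "loss", "slope_per_year": -0.004, "p": 1e-12,
            "p_bonf": 1e-8}
    return {
        "brain": make_admp_table("brain", {"p1": gain, "p2": gain, "p3": {},
                                           "p4": {}}),
        "liver": make_admp_table("liver", {"p1": {}, "p2": gain, "p3": gain,
                                           "p4": {}}),
        "kidney": make_admp_table("kidney", {"p1": {}, "p2": gain, "p3": loss,
                                             "p4": loss}),
    }


class TestBuildSpecificity:
    def test_tissue_sets(self, three_tissue_tables):
        st = aa.build_specificity(three_tissue_tables, "gain")
        assert st.table.loc["p1", "n_tissues"] == 1
        assert st.table.loc["p2", "n_tissues"] == 3
        assert st.table.loc["p2", "tissues"] == frozenset(
            {"brain", "liver", "kidney"})

    def test_direction_stratification_and_discordance(self, three_tissue_tables):
        gain = aa.build_specificity(three_tissue_tables, "gain")
        loss = aa.build_specificity(three_tissue_tables, "loss")
        # p3 gains in liver and loses in kidney: once in each table, flagged
        assert gain.table.loc["p3", "n_tissues"] == 1
        assert loss.table.loc["p3", "n_tissues"] == 1
        assert bool(gain.table.loc["p3", "discordant"])
        assert not bool(gain.table.loc["p1", "discordant"])

    def test_union_equals_per_tissue_union(self, admps3):
        st = aa.build_specificity(admps3, "gain")
        union = set()
        for tab in admps3.values():
            union |= set(tab.probes("gain"))
        assert set(st.table.index) == union

    def test_requires_two_tissues(self, three_tissue_tables):
        with pytest.raises(SpecificityError):
            aa.build_specificity({"brain": three_tissue_tables["brain"]}, "gain")

    def test_invalid_direction(self, three_tissue_tables):
        with pytest.raises(SpecificityError):
            aa.build_specificity(three_tissue_tables, "sideways")


class TestPercentAndHistogram:
    def test_printed_catalogue_arithmetic(self):
        """7850 gain-aDMPs with 1161 shared -> 85.2% tissue-specific;
        4287 loss with 111 shared -> 97.4%."""
        def table(total, shared):
            n1 = [1] * (total - shared) + [2] * shared
            df = pd.DataFrame({
                "tissues": [frozenset({"a"}) if k == 1 else frozenset({"a", "b"})
                            for k in n1],
                "n_tissues": n1,
                "discordant": False,
            }, index=[f"cg{i}" for i in range(total)])
            return aa.SpecificityTable("gain", df, ("a", "b"))
        assert round_pct(aa.percent_tissue_specific(table(7850, 1161))) == 85.2
        assert round_pct(aa.percent_tissue_specific(table(4287, 111))) == 97.4

    def test_all_specific_is_100(self, three_tissue_tables):
        st = aa.build_specificity(three_tissue_tables, "loss")
        assert aa.percent_tissue_specific(st) == 100.0  # p3, p4 kidney-only

    def test_empty_table_rejected(self, three_tissue_tables):
        st = aa.build_specificity(
            {k: three_tissue_tables[k] for k in ("brain", "liver")}, "loss")
        with pytest.raises(SpecificityError):
            aa.percent_tissue_specific(st)

    def test_histogram_counts_and_conservation(self, three_tissue_tables):
        st = aa.build_specificity(three_tissue_tables, "gain")
        hist = aa.sharing_histogram(st)
        assert hist.to_dict() == {1: 2, 2: 0, 3: 1}
        assert hist.sum() == len(st)

    def test_histogram_conserves_on_simulated_calls(self, admps3):
        st = aa.build_specificity(admps3, "gain")
        assert aa.sharing_histogram(st).sum() == len(st)

    def test_round_pct_half_up(self):
        assert round_pct(85.15) == 85.2
        assert round_pct(2.589) == 2.6


class TestOverlapMatrix:
    def test_disjoint_sets(self):
        tabs = {
            "a": make_admp_table("a", {"p1": {"class": "gain"}, "p2": {"class": "gain"}}),
            "b": make_admp_table("b", {"p3": {"class": "gain"}}),
        }
        om = aa.overlap_matrix(tabs, "gain")
        assert om.counts.loc["a", "a"] == 2 and om.counts.loc["b", "b"] == 1
        assert om.counts.loc["a", "b"] == 0
        assert om.percent.loc["a", "a"] == 100.0

    def test_identical_sets(self):
        rows = {"p1": {"class": "gain"}, "p2": {"class": "gain"}}
        tabs = {"a": make_admp_table("a", rows), "b": make_admp_table("b", rows)}
        om = aa.overlap_matrix(tabs, "gain")
        assert om.counts.loc["a", "a"] == 0 and om.counts.loc["b", "b"] == 0
        assert om.counts.loc["a", "b"] == 2

    def test_unique_means_unique_against_all(self, three_tissue_tables):
        om = aa.overlap_matrix(three_tissue_tables, "gain")
        # brain holds p1 (unique) and p2 (shared with both others)
        assert om.counts.loc["brain", "brain"] == 1
        assert om.counts.loc["brain", "liver"] == 1  # p2

    def test_matches_brute_force_sets(self, admps3):
        om = aa.overlap_matrix(admps3, "gain")
        sets = {t: set(tab.probes("gain")) for t, tab in admps3.items()}
        for ti in sets:
            others = set().union(*(sets[t] for t in sets if t != ti))
            assert om.counts.loc[ti, ti] == len(sets[ti] - others)
            for tj in sets:
                if ti != tj:
                    assert om.counts.loc[ti, tj] == len(sets[ti] & sets[tj])

    def test_symmetric_off_diagonal(self, admps3):
        om = aa.overlap_matrix(admps3, "loss")
        c = om.counts.to_numpy()
        off = c - np.diag(np.diag(c))
        np.testing.assert_array_equal(off, off.T)


class TestCrossTissue:
    def test_relaxed_significance_indicators(self, three_tissue_tables):
        tabs = dict(three_tissue_tables)
        # p1 gain in brain; in liver give it p=1e-5 same-sign, kidney p=0.5
        tabs["liver"].table.loc["p1", ["p", "slope_per_year"]] = [1e-5, 0.001]
        tabs["kidney"].table.loc["p1", ["p", "slope_per_year"]] = [0.5, 0.001]
        st = aa.build_specificity(tabs, "gain")
        ind, frac, skipped = aa.cross_tissue_significance(st, tabs, 0.001)
        assert ind.loc["p1", "liver"] == 1.0
        assert ind.loc["p1", "kidney"] == 0.0
        assert skipped == 0

    def test_opposite_sign_not_counted(self, three_tissue_tables):
        tabs = dict(three_tissue_tables)
        tabs["liver"].table.loc["p1", ["p", "slope_per_year"]] = [1e-9, -0.003]
        st = aa.build_specificity(tabs, "gain")
        ind, _, _ = aa.cross_tissue_significance(st, tabs, 0.001)
        assert ind.loc["p1", "liver"] == 0.0

    def test_untested_pairs_skipped_and_counted(self, three_tissue_tables):
        tabs = dict(three_tissue_tables)
        tabs["liver"].table.loc["p1", "class"] = "untested"
        tabs["liver"].table.loc["p1", "p"] = np.nan
        st = aa.build_specificity(tabs, "gain")
        ind, _, skipped = aa.cross_tissue_significance(st, tabs, 0.001)
        assert skipped == 1 and np.isnan(ind.loc["p1", "liver"])

    def test_slope_matrix_universal_effect(self, three_tissue_tables):
        st = aa.build_specificity(three_tissue_tables, "gain")
        mat = aa.cross_tissue_slope_matrix(st, three_tissue_tables)
        assert (mat.loc["p2"] > 0).all()  # same sign in every tissue
        # home-tissue entry satisfies the calling criteria
        assert mat.loc["p1", "brain"] >= 2.0

    def test_slope_matrix_missing_is_nan_not_zero(self, three_tissue_tables):
        tabs = dict(three_tissue_tables)
        tabs["liver"].table.loc["p1", "class"] = "untested"
        st = aa.build_specificity(tabs, "gain")
        mat = aa.cross_tissue_slope_matrix(st, tabs)
        assert np.isnan(mat.loc["p1", "liver"])


class TestRegions:
    def test_union_semantics(self):
        tabs = {
            "A": make_admp_table("A", {"p1": {"class": "gain"}, "p2": {}}),
            "B": make_admp_table("B", {"p1": {}, "p2": {"class": "gain"}}),
        }
        st = aa.build_specificity(tabs, "gain")
        mapping = pd.Series({"p1": "CGI_1", "p2": "CGI_1"})
        reg = aa.aggregate_to_regions(st, mapping, unit="cgi")
        assert reg.table.loc["CGI_1", "tissues"] == frozenset({"A", "B"})
        assert reg.table.loc["CGI_1", "n_tissues"] == 2

    def test_gene_count_pattern_brain_heavy(self):
        """A gene with many aDMPs in one tissue and none elsewhere keeps
        that per-tissue count profile (DIP2C-like pattern)."""
        brain_rows = {f"p{i}": {"class": "loss", "slope_per_year": -0.004,
                                "p_bonf": 1e-8} for i in range(24)}
        brain_rows["q1"] = {}
        other_rows = {f"p{i}": {} for i in range(24)}
        other_rows["q1"] = {"class": "loss", "slope_per_year": -0.003,
                            "p_bonf": 1e-8}
        tabs = {"brain": make_admp_table("brain", brain_rows),
                "buccal": make_admp_table("buccal", other_rows)}
        st = aa.build_specificity(tabs, "loss")
        mapping = pd.Series({f"p{i}": "DIP2C" for i in range(24)} | {"q1": "DIP2C"})
        reg = aa.aggregate_to_regions(st, mapping, unit="gene")
        assert reg.counts.loc["DIP2C", "brain"] == 24
        assert reg.counts.loc["DIP2C", "buccal"] == 1

    def test_region_sharing_at_least_probe_sharing(self, admps3, genome3):
        from admp_atlas.annotation import nearest_gene

        st = aa.build_specificity(admps3, "gain")
        mapping = nearest_gene(genome3.probes, genome3.genes)["nearest_gene"]
        reg = aa.aggregate_to_regions(st, mapping, unit="gene")
        for unit, row in reg.table.iterrows():
            members = st.table.index[
                mapping.reindex(st.table.index) == unit]
            assert row["n_tissues"] >= max(
                st.table.loc[members, "n_tissues"])

    def test_unmapped_probes_logged_not_fatal(self, three_tissue_tables):
        st = aa.build_specificity(three_tissue_tables, "gain")
        mapping = pd.Series({"p1": "G1"})  # p2 and p3 unmapped
        reg = aa.aggregate_to_regions(st, mapping)
        assert reg.n_unmapped == 2 and len(reg.table) == 1

    def test_empty_mapping_rejected(self, three_tissue_tables):
        st = aa.build_specificity(three_tissue_tables, "gain")
        with pytest.raises(SpecificityError):
            aa.aggregate_to_regions(st, pd.Series(dtype=object))


class TestInvariances:
    def test_tissue_order_invariance(self, admps3):
        fwd = aa.build_specificity(dict(admps3), "gain")
        rev = aa.build_specificity(dict(reversed(list(admps3.items()))), "gain")
        assert fwd.table["n_tissues"].equals(rev.table["n_tissues"])
        assert aa.percent_tissue_specific(fwd) == aa.percent_tissue_specific(rev)

    def test_external_overlap_reports_both_denominators(self):
        res = aa.external_overlap({"a", "b", "c", "d"}, {"c", "d", "e"})
        assert res["n_shared"] == 2
        assert res["pct_of_admps"] == pytest.approx(50.0)
        assert res["pct_of_external"] == pytest.approx(200 / 3)
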