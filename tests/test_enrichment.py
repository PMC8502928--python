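"""Exact Fisher test, XCI enrichment, SNP prioritization, window partition,
functional overlap, consensus enhancers and the enhancer-gene association."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from hapsweep.core import Interval
from hapsweep.enrichment import (
    Enhancer,
    XCIRecord,
    consensus_enhancers,
    enhancer_selection_association,
    fisher_exact_2x2,
    functional_overlap_odds,
    partition_windows,
    prioritize_snps,
    selected_genes,
    xci_enrichment,
)
from hapsweep.simulate import FixtureConfig, make_annotation_fixtures
from oracles import brute_fisher_two_sided


class TestFisherExact:
    def test_balanced_table(self):
        res = fisher_exact_2x2([[5, 5], [5, 5]])
        assert res.odds_ratio == 1.0 and res.p_value == 1.0

    def test_enumeration_example(self):
        table = [[1, 9], [11, 3]]
        res = fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(brute_fisher_two_sided(table), abs=1e-14)

    def test_row_and_column_swap_symmetry(self, rng):
        for _ in range(30):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact_2x2(t).p_value
            assert fisher_exact_2x2(t[::-1, ::-1]).p_value == pytest.approx(p, abs=1e-14)
            assert fisher_exact_2x2(t.T).p_value == pytest.approx(p, abs=1e-14)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum() == 0:
                continue
            mine = fisher_exact_2x2(t)
            ref_or, ref_p = scipy_fisher(t)
            assert mine.p_value == pytest.approx(ref_p, rel=1e-9, abs=1e-12)

    def test_zero_margin_gives_p_one(self):
        res = fisher_exact_2x2([[0, 0], [3, 7]])
        assert res.p_value == 1.0 and math.isnan(res.odds_ratio)

    def test_zero_cell_infinite_odds(self):
        res = fisher_exact_2x2([[5, 0], [2, 7]])
        assert math.isinf(res.odds_ratio)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


def _xci_records(n_escape, n_inactive):
    recs = [XCIRecord(f"E{i}", None, "escape") for i in range(n_escape)]
    recs += [XCIRecord(f"I{i}", None, "inactive") for i in range(n_inactive)]
    return recs


class TestXCIEnrichment:
    def test_contingency_layout(self):
        recs = _xci_records(4, 6) + [XCIRecord("V0", None, "variable")]
        res = xci_enrichment({"E0", "E1", "I0"}, recs)
        np.testing.assert_array_equal(res.table, [[2, 2], [1, 5]])

    def test_variable_excluded_by_default(self):
        recs = _xci_records(2, 2) + [XCIRecord("V0", None, "variable")]
        res = xci_enrichment({"V0"}, recs)
        assert res.table.sum() == 4

    def test_all_genes_selected_degenerate(self):
        recs = _xci_records(3, 5)
        res = xci_enrichment({r.gene for r in recs}, recs)
        assert res.p_value == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            xci_enrichment(set(), [])

    def test_planted_or_recovered_from_fixture(self):
        """Downstream of the fixture generator, the estimated odds ratio is
        centred on the planted value (median over seeds)."""
        ors = []
        for seed in range(40):
            f = make_annotation_fixtures(FixtureConfig(xci_odds_ratio=5.0), seed)
            gene_ivs = [Interval(r.chrom, int(r.start), int(r.end), r.gene)
                        for r in f["genes"].itertuples()]
            cand = selected_genes(gene_ivs, f["candidate_regions"])
            recs = [XCIRecord(r.gene, None, r.xci_status)
                    for r in f["genes"].itertuples()]
            res = xci_enrichment(cand, recs)
            if math.isfinite(res.odds_ratio):
                ors.append(res.odds_ratio)
        assert 3.0 < np.median(ors) < 8.0


class TestPrioritizeSnps:
    def _scores(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "chrom": "X", "pos": np.arange(n) * 50, "id": [f"s{i}" for i in range(n)],
            "ihs_std": rng.normal(size=n), "nsl_std": rng.normal(size=n),
            "ihh12_std": rng.normal(size=n),
        })

    def test_deleteriousness_boundary(self):
        df = self._scores()
        df.loc[0, "ihs_std"] = 50.0
        out_low = prioritize_snps(df, {**{f"s{i}": 0.0 for i in range(1000)}, "s0": 9.9})
        assert "s0" not in set(out_low["id"])
        out_hi = prioritize_snps(df, {**{f"s{i}": 0.0 for i in range(1000)}, "s0": 10.0})
        assert "s0" in set(out_hi["id"])

    def test_planted_snps_recovered_exactly(self):
        cfg = FixtureConfig()
        f = make_annotation_fixtures(cfg, seed=5)
        sc = f["snp_scores"]
        delet = dict(zip(sc["id"], sc["deleteriousness"]))
        out = prioritize_snps(sc, delet, tail_q=0.01, del_cutoff=cfg.cadd_cutoff)
        assert set(out["id"]) == set(f["truth"]["planted_snp_ids"])

    def test_zero_cutoff_tail_only(self):
        df = self._scores(n=200, seed=1)
        delet = {f"s{i}": 0.0 for i in range(200)}
        out = prioritize_snps(df, delet, tail_q=0.05, del_cutoff=0.0)
        per_stat = out.groupby("statistic").size()
        for stat in ("ihs", "nsl", "ihh12"):
            assert per_stat[stat] >= 10  # ~5% of 200 per statistic

    def test_missing_deleteriousness_excluded(self):
        df = self._scores(n=100, seed=2)
        out = prioritize_snps(df, {}, tail_q=0.1, del_cutoff=0.0)
        assert len(out) == 0


class TestPartitionWindows:
    GENES = [Interval("X", 10_000, 30_000), Interval("X", 30_000, 42_000),
             Interval("X", 80_000, 90_000)]

    def test_window_inside_gene(self):
        out = partition_windows([Interval("X", 12_000, 28_000)], self.GENES)
        assert out.iloc[0]["label"] == "genic"

    def test_bookended_genes_cover_jointly(self):
        out = partition_windows([Interval("X", 25_000, 40_000)], self.GENES)
        assert out.iloc[0]["label"] == "genic"

    def test_straddling_window_partial_with_snp_counts(self):
        pos = np.array([85_000, 89_999, 90_000, 95_000])
        out = partition_windows([Interval("X", 84_000, 96_000)], self.GENES, pos)
        row = out.iloc[0]
        assert row["label"] == "partial"
        assert row["genic_snps"] == 2 and row["intergenic_snps"] == 2

    def test_empty_gene_list_all_intergenic(self):
        out = partition_windows([Interval("X", 0, 20_000)], [])
        assert out.iloc[0]["label"] == "intergenic"

    def test_matches_bruteforce_on_random_sets(self, rng):
        genes = []
        for _ in range(20):
            s = int(rng.integers(0, 500_000))
            genes.append(Interval("X", s, s + int(rng.integers(1_000, 50_000))))
        wins = [Interval("X", s, s + 20_000) for s in range(0, 480_000, 16_000)]
        pos = np.sort(rng.choice(500_000, size=300, replace=False))
        out = partition_windows(wins, genes, pos)
        for row, w in zip(out.itertuples(), wins):
            covered = sum(
                1 for p in range(w.start, w.end, 997)
                if any(g.start <= p < g.end for g in genes)
            )
            in_w = [p for p in pos if w.start <= p < w.end]
            genic = sum(1 for p in in_w if any(g.start <= p < g.end for g in genes))
            assert row.genic_snps == genic
            if row.label == "genic":
                assert covered == len(range(w.start, w.end, 997))
            elif row.label == "intergenic":
                assert covered == 0


class TestFunctionalOverlap:
    def test_elements_cover_everything(self):
        out = functional_overlap_odds(
            {"a": np.array([5, 50])}, [Interval("X", 0, 100)], np.array([1, 2, 99]))
        assert out.iloc[0]["proportion"] == 1.0

    def test_disjoint_elements(self):
        out = functional_overlap_odds(
            {"a": np.array([500, 600])}, [Interval("X", 0, 100)], np.array([5, 700]))
        assert out.iloc[0]["proportion"] == 0.0 and out.iloc[0]["odds_ratio"] == 0.0

    def test_planted_two_fold_enrichment(self, rng):
        """Estimated odds against the background are centred on the planted 2x."""
        elements = [Interval("X", s, s + 1_000) for s in range(0, 1_000_000, 4_000)]
        # background uniform: P(in element) = 0.25; focal set enriched to odds 2x
        bg = rng.integers(0, 1_000_000, size=20_000)
        p_focal = 0.4  # odds 0.667 vs background odds 0.333 -> ratio 2
        inside = rng.random(4_000) < p_focal
        focal = np.where(
            inside,
            (rng.integers(0, 250) * 4_000 + rng.integers(0, 1_000, size=4_000)),
            (rng.integers(0, 250) * 4_000 + rng.integers(1_000, 4_000, size=4_000)),
        )
        out = functional_overlap_odds({"focal": focal}, elements, bg)
        assert out.iloc[0]["odds_ratio"] == pytest.approx(2.0, rel=0.15)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            functional_overlap_odds({"a": np.array([1])}, [], np.array([]))


def _enh(start, end, gene, cell, db=1):
    return Enhancer(Interval("X", start, end), gene, frozenset([cell]), db)


class TestConsensusEnhancers:
    def test_one_bp_overlap_same_gene_merges(self):
        out = consensus_enhancers([_enh(100, 200, "A", "c1"), _enh(199, 300, "A", "c2")])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (100, 300)
        assert out[0].cell_lines == frozenset({"c1", "c2"})

    def test_hand_fixture_six_records_three_consensus(self):
        records = [
            # gene A: two overlapping + one in a contiguous window -> 1 consensus
            _enh(100_000, 101_000, "A", "c1", db=1),
            _enh(100_500, 101_500, "A", "c2", db=3),
            _enh(118_000, 119_000, "A", "c3", db=2),  # windows touch A's run
            # gene A again but far away -> its own consensus
            _enh(500_000, 501_000, "A", "c1", db=1),
            # gene B at the same coordinates as A's first cluster -> separate
            _enh(100_000, 101_000, "B", "c1", db=4),
            _enh(100_200, 101_200, "B", "c2", db=1),
        ]
        out = consensus_enhancers(records)
        assert len(out) == 3
        by_gene = {}
        for e in out:
            by_gene.setdefault(e.target_gene, []).append(e)
        assert len(by_gene["A"]) == 2 and len(by_gene["B"]) == 1
        a_first = min(by_gene["A"], key=lambda e: e.interval.start)
        assert a_first.interval.end == 119_000  # contiguous-window merge
        assert a_first.db_support == 3  # max over merged records
        assert by_gene["B"][0].db_support == 4

    def test_different_gene_same_coordinates_not_merged(self):
        out = consensus_enhancers([_enh(0, 1_000, "A", "c1"), _enh(0, 1_000, "B", "c1")])
        assert len(out) == 2

    def test_idempotence(self, rng):
        records = [
            _enh(int(s), int(s) + int(rng.integers(200, 3_000)),
                 rng.choice(["A", "B", "C"]), rng.choice(["c1", "c2"]),
                 int(rng.integers(1, 5)))
            for s in rng.integers(0, 400_000, size=40)
        ]
        once = consensus_enhancers(records)
        twice = consensus_enhancers(once)
        key = lambda e: (e.target_gene, e.interval.start, e.interval.end,
                         tuple(sorted(e.cell_lines)), e.db_support)
        assert sorted(map(key, once)) == sorted(map(key, twice))

    def test_per_gene_output_disjoint(self, rng):
        records = [
            _enh(int(s), int(s) + 2_000, "A", "c1") for s in rng.integers(0, 300_000, 30)
        ]
        out = sorted(consensus_enhancers(records), key=lambda e: e.interval.start)
        for e1, e2 in zip(out, out[1:]):
            assert e1.interval.end <= e2.interval.start


class TestEnhancerAssociation:
    def test_chi2_closed_form(self):
        # engineer consensus/windows/genes giving the table [[10,20],[30,40]]
        enhancers = []
        windows = []
        genes = set()
        idx = 0
        for (e_sel, g_sel), count in {(True, True): 10, (True, False): 20,
                                      (False, True): 30, (False, False): 40}.items():
            for _ in range(count):
                start = idx * 10_000
                enh = _enh(start, start + 1_000, f"g{idx}", "c1")
                enhancers.append(enh)
                if e_sel:
                    windows.append(Interval("X", start, start + 500))
                if g_sel:
                    genes.add(f"g{idx}")
                idx += 1
        res = enhancer_selection_association(enhancers, windows, genes)
        obs = np.array([[10, 20], [30, 40]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2_hand = ((obs - expected) ** 2 / expected).sum()
        assert res.extras["chi2"] == pytest.approx(chi2_hand)
        np.testing.assert_array_equal(res.table, obs)

    def test_perfect_association(self):
        enhancers, windows, genes = [], [], set()
        for i in range(20):
            start = i * 10_000
            enhancers.append(_enh(start, start + 1_000, f"g{i}", "c1"))
            if i < 10:
                windows.append(Interval("X", start, start + 500))
                genes.add(f"g{i}")
        res = enhancer_selection_association(enhancers, windows, genes)
        assert res.p_value < 1e-4
        assert res.table[0, 0] > res.expected[0, 0]

    def test_null_p_uniformity(self, rng):
        """Independence fixture: p-values roughly uniform over seeds."""
        ps = []
        for _ in range(200):
            enhancers, windows, genes = [], [], set()
            for i in range(60):
                start = i * 10_000
                enhancers.append(_enh(start, start + 1_000, f"g{i}", "c1"))
                if rng.random() < 0.4:
                    windows.append(Interval("X", start, start + 500))
                if rng.random() < 0.4:
                    genes.add(f"g{i}")
            ps.append(enhancer_selection_association(enhancers, windows, genes).p_value)
        ps = np.array(ps)
        assert 0.01 < (ps < 0.05).mean() < 0.11  # chi2 approximation tolerance

    def test_distance_diagnostics_reported(self):
        enhancers = [_enh(0, 1_000, "g0", "c1"), _enh(50_000, 51_000, "g1", "c1")]
        spans = {"g0": Interval("X", 10_000, 12_000), "g1": Interval("X", 60_000, 62_000)}
        with pytest.warns(UserWarning, match="expected cell count"):
            res = enhancer_selection_association(
                enhancers, [Interval("X", 0, 500)], {"g0"}, gene_spans=spans)
        assert res.extras["mean_distance"]["YY"] == pytest.approx(10_500)

    def test_min_db_filter_on_top_hits(self):
        enhancers = [_enh(0, 1_000, "g0", "c1", db=4), _enh(2_000, 3_000, "g1", "c1", db=1)]
        with pytest.warns(UserWarning, match="expected cell count"):
            res = enhancer_selection_association(
                enhancers, [Interval("X", 0, 3_000)], {"g0", "g1"}, min_db=3)
        assert [e.db_support for e in res.extras["top_hits"]] == [4]
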