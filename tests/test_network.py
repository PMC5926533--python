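import numpy as np
import pandas as pd
import pytest

from oceanc.network import (
    build_network,
    categorize_pairs,
    distance_summary,
    exact_median,
    interactions_per_peak,
    network_to_edgelist,
)
from conftest import make_pairs_frame

HOCIS = pd.DataFrame({
    "chrom": ["c1", "c1", "c1"],
    "start": [1000, 5000, 9000],
    "end": [2000, 6000, 10000],
    "hoci_class": ["PROMOTER", "ENHANCER", "OTHER"],
})


def _p(pos1, pos2):
    return ("c1", pos1, "+", "c1", pos2, "-")


class TestBuildNetwork:
    def test_edges_degrees_and_interaction_counts(self):
        valid = make_pairs_frame([
            _p(1500, 5500), _p(1200, 5200),   # A-B x2
            _p(1500, 9500),                   # A-C x1
        ])
        g = build_network(valid, HOCIS)
        assert g[0][1]["weight"] == 2 and g[0][2]["weight"] == 1
        assert g.degree(0) == 2
        assert g.nodes[0]["interaction_count"] == 3

    def test_within_hoci_pair_counts_but_no_edge(self):
        valid = make_pairs_frame([_p(1100, 1900)])
        g = build_network(valid, HOCIS)
        assert g.number_of_edges() == 0
        assert g.nodes[0]["interaction_count"] == 1

    def test_no_pairs_gives_nodes_only(self):
        g = build_network(make_pairs_frame([]), HOCIS)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_min_weight_drops_light_edges(self):
        valid = make_pairs_frame([_p(1500, 5500), _p(1200, 5200), _p(1500, 9500)])
        g = build_network(valid, HOCIS, min_weight=2)
        assert g.number_of_edges() == 1

    def test_overlapping_hocis_rejected(self):
        bad = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 50], "end": [100, 150]})
        with pytest.raises(ValueError):
            build_network(make_pairs_frame([]), bad)

    def test_edge_bookkeeping_conservation(self, default_products):
        valid = default_products["valid"]
        hocis = default_products["annotated"]
        g = build_network(valid, hocis)
        from oceanc.network import assign_ends_to_hocis

        ends = assign_ends_to_hocis(valid, hocis)
        h1, h2 = ends["hoci1"].to_numpy(), ends["hoci2"].to_numpy()
        incidences = int((h1 >= 0).sum() + (h2 >= 0).sum())
        both_same = int(((h1 >= 0) & (h1 == h2)).sum())
        single = int((((h1 >= 0) ^ (h2 >= 0))).sum())
        edge_weight_sum = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert 2 * edge_weight_sum + 2 * both_same + single == incidences


class TestCategorize:
    def test_precedence_rules(self):
        valid = make_pairs_frame([
            _p(1500, 5500),   # promoter + enhancer
            _p(1500, 20000),  # promoter + none
            _p(5500, 20000),  # enhancer + none
            _p(1500, 1800),   # promoter both
            _p(5500, 5900),   # enhancer both
            _p(20000, 30000), # none
            _p(1500, 9500),   # promoter + other -> promoter related
        ])
        cat = categorize_pairs(valid, HOCIS)["pair_category"].tolist()
        assert cat == ["PROMOTER_ENHANCER_HOCI", "PROMOTER_HOCI_RELATED",
                       "ENHANCER_HOCI_RELATED", "PROMOTER_HOCI", "ENHANCER_HOCI",
                       "OTHER", "PROMOTER_HOCI_RELATED"]

    def test_category_partition(self, default_products):
        cat = categorize_pairs(default_products["valid"], default_products["annotated"])
        assert cat["pair_category"].value_counts().sum() == len(default_products["valid"])


class TestDistanceSummary:
    def test_exact_median_convention(self):
        assert exact_median(np.array([10, 30, 50])) == 30
        assert exact_median(np.array([10, 30, 50, 70])) == 30  # lower middle
        assert exact_median(np.array([42])) == 42

    def test_summary_rows(self):
        valid = make_pairs_frame([_p(1500, 1800), _p(1100, 1900)])
        valid["cis_distance"] = np.abs(valid["pos2"] - valid["pos1"]).astype(float)
        cat = categorize_pairs(valid, HOCIS)
        ds = distance_summary(cat)
        assert ds["category"].tolist() == ["PROMOTER_HOCI"]
        assert ds["median"].iloc[0] == 300.0

    def test_absent_category_not_reported_as_zero(self):
        valid = make_pairs_frame([_p(1500, 1800)])
        valid["cis_distance"] = 300.0
        ds = distance_summary(categorize_pairs(valid, HOCIS))
        assert "ENHANCER_HOCI" not in ds["category"].tolist()


class TestInteractionsPerPeak:
    def test_mean_counts(self):
        intervals = HOCIS.iloc[:2]
        valid = make_pairs_frame(
            [_p(1500, 30000)] * 3 + [_p(5500, 30000)] * 5)
        res = interactions_per_peak(valid, intervals)
        assert res["counts"].tolist() == [3, 5]
        assert res["mean"] == 4.0

    def test_identical_sets_null_p(self):
        rng = np.random.default_rng(0)
        intervals = pd.DataFrame({"chrom": "c1",
                                  "start": np.arange(50) * 10_000,
                                  "end": np.arange(50) * 10_000 + 1000})
        pos = rng.integers(0, 500_000, 400)
        valid = make_pairs_frame([("c1", int(p), "+", "c1", 600_000 + i, "-")
                                  for i, p in enumerate(pos)])
        res = interactions_per_peak(valid, intervals, valid)
        assert res["pvalue"] > 0.5

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(11)
        n_iv = 200
        intervals = pd.DataFrame({"chrom": "c1",
                                  "start": np.arange(n_iv) * 10_000,
                                  "end": np.arange(n_iv) * 10_000 + 1000})
        def draws(rate):
            rows = []
            for i in range(n_iv):
                for _ in range(rng.poisson(rate)):
                    p = int(intervals["start"][i] + rng.integers(0, 1000))
                    rows.append(("c1", p, "+", "c1", 2_500_000 + len(rows), "-"))
            return make_pairs_frame(rows)
        rich = draws(10)
        poor = draws(1)
        res = interactions_per_peak(rich, intervals, poor)
        assert res["pvalue"] < 1e-6
        assert res["mean"] > res["other_mean"]

    def test_empty_intervals_error(self):
        with pytest.raises(ValueError):
            interactions_per_peak(make_pairs_frame([]), HOCIS.iloc[:0])


def test_edgelist_deterministic_order(default_products):
    g = build_network(default_products["valid"], default_products["annotated"])
    e1 = network_to_edgelist(g)
    e2 = network_to_edgelist(g)
    assert e1.equals(e2)
    assert (e1["weight"] >= 1).all()
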