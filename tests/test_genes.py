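import numpy as np
import pandas as pd
import pytest

from oceanc.genes import (
    compare_conditions,
    expression_by_type,
    type_genes,
)
from conftest import make_pairs_frame

HOCIS = pd.DataFrame({
    "chrom": ["c1", "c1"],
    "start": [10_000, 50_000],
    "end": [11_000, 51_000],
    "hoci_class": ["PROMOTER", "ENHANCER"],
})


def genes_at(tss_list):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(tss_list))],
        "chrom": "c1",
        "strand": "+",
        "tss": tss_list,
    })


class TestTypeGenes:
    def test_hub_when_promoter_overlaps_hoci(self):
        genes = genes_at([11_500])  # window [9500, 11500] overlaps HOCI
        t = type_genes(genes, HOCIS, make_pairs_frame([]))
        assert t["g0"] == "HUB"

    def test_interacting_via_link_pair(self):
        genes = genes_at([30_000])
        link = make_pairs_frame([("c1", 29_000, "+", "c1", 50_500, "-")])
        t = type_genes(genes, HOCIS, link)
        assert t["g0"] == "INTERACTING"

    def test_dissociative_without_overlap_or_link(self):
        genes = genes_at([30_000])
        stray = make_pairs_frame([("c1", 29_000, "+", "c1", 40_000, "-")])
        t = type_genes(genes, HOCIS, stray)  # partner end not in any HOCI
        assert t["g0"] == "DISSOCIATIVE"

    def test_min_link_pairs_threshold(self):
        genes = genes_at([30_000])
        link = make_pairs_frame([("c1", 29_000, "+", "c1", 50_500, "-")])
        t = type_genes(genes, HOCIS, link, min_link_pairs=2)
        assert t["g0"] == "DISSOCIATIVE"

    def test_type_partition(self):
        genes = genes_at([11_500, 30_000, 70_000])
        link = make_pairs_frame([("c1", 29_500, "+", "c1", 50_500, "-")])
        t = type_genes(genes, HOCIS, link)
        assert sorted(t.tolist()) == ["DISSOCIATIVE", "HUB", "INTERACTING"]

    def test_adding_hocis_never_demotes(self):
        genes = genes_at([11_500, 30_000, 70_000])
        link = make_pairs_frame([("c1", 29_500, "+", "c1", 50_500, "-")])
        order = {"DISSOCIATIVE": 0, "INTERACTING": 1, "HUB": 2}
        t_small = type_genes(genes, HOCIS.iloc[:1], link)
        t_full = type_genes(genes, HOCIS, link)
        for g in genes["gene_id"]:
            assert order[t_full[g]] >= order[t_small[g]]

    def test_planted_types_recovered(self, default_products):
        b = default_products["bundle"]
        t = type_genes(b.genes, default_products["annotated"],
                       default_products["valid"], b.assembly)
        match = (b.genes["gene_id"].map(t).to_numpy()
                 == b.genes["planted_type"].to_numpy()).mean()
        assert match >= 0.95


class TestExpressionByType:
    def test_planted_ordering_recovered(self):
        rng = np.random.default_rng(3)
        n = 300
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(3 * n)],
            "chrom": "c1", "strand": "+", "tss": np.arange(3 * n) * 10,
        })
        types = pd.Series(["HUB"] * n + ["INTERACTING"] * n + ["DISSOCIATIVE"] * n,
                          index=genes["gene_id"].to_numpy())
        med = np.repeat([20.0, 5.0, 0.2], n)
        expr = pd.Series(med * np.exp(rng.standard_normal(3 * n)),
                         index=genes["gene_id"].to_numpy())
        out = expression_by_type(genes, types, expr)
        m = out["per_type"]
        assert (m["HUB"]["median_rpkm"] > m["INTERACTING"]["median_rpkm"]
                > m["DISSOCIATIVE"]["median_rpkm"])
        assert out["tests"]["HUB>INTERACTING"] < 1e-10
        assert out["tests"]["INTERACTING>DISSOCIATIVE"] < 1e-10

    def test_single_type_skips_comparisons(self):
        genes = genes_at([100, 200])
        types = pd.Series(["HUB", "HUB"], index=genes["gene_id"].to_numpy())
        expr = pd.Series([1.0, 2.0], index=genes["gene_id"].to_numpy())
        out = expression_by_type(genes, types, expr)
        assert out["tests"]["HUB>INTERACTING"] is None

    def test_expressed_cutoff_is_strict(self):
        genes = genes_at([100])
        types = pd.Series(["HUB"], index=["g0"])
        expr = pd.Series([0.5], index=["g0"])
        out = expression_by_type(genes, types, expr)
        assert out["n_expressed"] == 0


class TestCompareConditions:
    def _fixture(self):
        genes = genes_at([100, 200, 300])
        ta = pd.Series(["HUB", "HUB", "INTERACTING"], index=genes["gene_id"].to_numpy())
        tb = pd.Series(["DISSOCIATIVE", "HUB", "DISSOCIATIVE"],
                       index=genes["gene_id"].to_numpy())
        ea = pd.Series([10.0, 5.0, 4.0], index=genes["gene_id"].to_numpy())
        eb = pd.Series([0.5, 5.0, 4.0], index=genes["gene_id"].to_numpy())
        return genes, ta, tb, ea, eb

    def test_change_categories(self):
        genes, ta, tb, ea, eb = self._fixture()
        df, _ = compare_conditions(genes, ta, tb, ea, eb)
        assert df.set_index("gene_id")["change_category"].tolist() == [
            "hub-dissociative", "same-type", "other-change"]

    def test_promoter_hoci_changed_flag(self):
        genes, ta, tb, ea, eb = self._fixture()
        df, summary = compare_conditions(genes, ta, tb, ea, eb)
        assert df.set_index("gene_id")["promoter_hoci_changed"].tolist() == [
            True, False, False]
        assert summary["n_promoter_hoci_changed"] == 1

    def test_missing_gene_excluded_and_counted(self):
        genes, ta, tb, ea, eb = self._fixture()
        eb = eb.drop("g2")
        df, summary = compare_conditions(genes, ta, tb, ea, eb)
        assert len(df) == 2 and summary["n_dropped"] == 1

    def test_planted_hub_loss_fold_change_detected(self):
        rng = np.random.default_rng(5)
        n = 200
        genes = genes_at(list(range(100, 100 + 10 * 2 * n, 10)))
        gid = genes["gene_id"].to_numpy()
        changed = gid[:n]
        ta = pd.Series("HUB", index=gid)
        tb = pd.Series(np.where(np.isin(gid, changed), "DISSOCIATIVE", "HUB"),
                       index=gid)
        ea = pd.Series(10.0 * np.exp(0.2 * rng.standard_normal(2 * n)), index=gid)
        drop = np.where(np.isin(gid, changed), 0.25, 1.0)
        eb = pd.Series(ea.to_numpy() * drop * np.exp(0.2 * rng.standard_normal(2 * n)),
                       index=gid)
        df, summary = compare_conditions(genes, ta, tb, ea, eb)
        assert summary["down_changed_vs_unchanged_p"] < 0.01
        assert (summary["down_changed_median_abs_log2fc"]
                > summary["down_unchanged_median_abs_log2fc"])
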