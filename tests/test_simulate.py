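import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oceanc.genome import digest, read_bed, read_fasta
from oceanc.genes import read_expression, read_genes_bed
from oceanc.pairs import filter_pairs, read_bedpe
from oceanc.simulate import (
    SimulationConfig,
    simulate,
    two_condition_bundle,
    write_bundle,
)


def small_config(seed=1, **kw):
    base = dict(seed=seed, chrom_length=1_000_000, n_modules_per_chrom=1,
                n_other_hubs_per_chrom=1, n_pairs=20_000, n_genes=60,
                d_max=400_000, pe_median=60_000, compartment_block=200_000)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_bundle(self):
        b1 = simulate(small_config())
        b2 = simulate(small_config())
        assert b1.pairs.equals(b2.pairs)
        assert b1.genes.equals(b2.genes)
        assert b1.expression.equals(b2.expression)
        assert b1.truth == b2.truth

    def test_different_seed_differs(self):
        b1 = simulate(small_config(seed=1))
        b2 = simulate(small_config(seed=2))
        assert not b1.pairs.equals(b2.pairs)

    def test_two_condition_truth_deterministic(self):
        a1, b1 = two_condition_bundle(small_config(n_hub_loss_genes=5))
        a2, b2 = two_condition_bundle(small_config(n_hub_loss_genes=5))
        assert b1.truth["hub_loss_genes"] == b2.truth["hub_loss_genes"]
        assert b1.pairs.equals(b2.pairs)


class TestConfigValidation:
    def test_artifact_fractions_checked(self):
        with pytest.raises(ValueError):
            simulate(small_config(frac_dangling=0.9, frac_self_circle=0.2))

    def test_allocation_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate(small_config(frac_background=0.9))

    def test_decay_range_checked(self):
        with pytest.raises(ValueError):
            simulate(small_config(d_min=500_000, d_max=400_000))


class TestPlantedClasses:
    def test_artifact_fractions_recovered(self):
        cfg = small_config(seed=1, n_pairs=10_000, frac_dangling=0.1,
                           frac_self_circle=0.1, frac_same_strand=0.1,
                           frac_too_close=0.1, frac_low_mapq=0.0)
        b = simulate(cfg)
        fm = digest(b.assembly, "GATC")
        _, counts = filter_pairs(b.pairs, fm, deduplicate=False)
        n = counts["input_pairs"]
        for cls in ["DANGLING_END", "SELF_CIRCLE", "SAME_STRAND_DUMPED", "TOO_CLOSE"]:
            assert abs(counts[cls] / n - 0.1) < 0.015, cls

    def test_no_hubs_yields_few_peaks(self):
        from oceanc.hoci import build_coverage, call_hoci

        cfg = small_config(seed=3, n_modules_per_chrom=0, n_other_hubs_per_chrom=0,
                           frac_background=1.0, frac_hub_hub=0.0,
                           frac_hub_background=0.0, frac_promoter_link=0.0,
                           frac_hub_genes=0.0, frac_interacting_genes=0.0)
        b = simulate(cfg)
        fm = digest(b.assembly, "GATC")
        valid, _ = filter_pairs(b.pairs, fm)
        peaks = call_hoci(build_coverage(valid, b.assembly))
        assert len(peaks) <= 2  # at most the BH false-positive budget

    def test_background_distance_decay_fits_power_law(self):
        cfg = SimulationConfig(seed=5, n_pairs=100_000, frac_background=1.0,
                               frac_hub_hub=0.0, frac_hub_background=0.0,
                               frac_promoter_link=0.0, trans_fraction=0.0,
                               compartment_bias=0.0, frac_hub_genes=0.02,
                               frac_interacting_genes=0.02)
        b = simulate(cfg)
        bg = b.pairs[b.pairs["provenance"] == "background"]
        d = np.abs(bg["pos2"] - bg["pos1"]).to_numpy()[:50_000]
        lo, hi = cfg.d_min, cfg.d_max
        cdf = lambda x: np.log(x / lo) / np.log(hi / lo)  # alpha = 1
        res = stats.ks_1samp(d, cdf)
        assert res.pvalue > 0.01

    def test_hub_widths_and_classes(self, default_bundle):
        hubs = pd.DataFrame(default_bundle.truth["hubs"])
        assert len(hubs) == 40
        assert (hubs["end"] > hubs["start"]).all()
        assert hubs["hub_class"].value_counts().to_dict() == {
            "PROMOTER": 16, "ENHANCER": 16, "OTHER": 8}


class TestTwoCondition:
    def test_removed_hubs_silenced_in_b(self):
        a, b = two_condition_bundle(small_config(n_hub_loss_genes=5))
        removed = set(b.truth["removed_hubs"])
        assert removed
        hubs = pd.DataFrame(a.truth["hubs"]).set_index("hub_id")
        for hub_id in removed:
            h = hubs.loc[hub_id]
            in_hub1 = (b.pairs["chrom1"] == h["chrom"]) & \
                (b.pairs["pos1"] >= h["start"]) & (b.pairs["pos1"] < h["end"])
            in_hub2 = (b.pairs["chrom2"] == h["chrom"]) & \
                (b.pairs["pos2"] >= h["start"]) & (b.pairs["pos2"] < h["end"])
            planted = b.pairs["provenance"].str.startswith(("hub_", "promoter_"))
            assert not (planted & (in_hub1 | in_hub2)).any()

    def test_affected_gene_expression_scaled_down(self):
        a, b = two_condition_bundle(small_config(n_hub_loss_genes=5))
        lost = b.truth["hub_loss_genes"]
        fc = np.log2(a.expression[lost] / b.expression[lost])
        assert np.median(fc) == pytest.approx(2.0, abs=0.5)  # 4x drop

    def test_zero_planted_changes_shares_everything(self):
        a, b = two_condition_bundle(small_config(n_hub_loss_genes=0))
        assert b.truth["hub_loss_genes"] == []
        assert b.truth["removed_hubs"] == []
        assert a.genes.equals(b.genes)


class TestRoundTrip:
    def test_emitted_files_reparse(self, tmp_path):
        b = simulate(small_config())
        paths = write_bundle(b, tmp_path)
        seqs = read_fasta(paths["genome"])
        assert seqs == b.assembly.sequence
        pairs = read_bedpe(paths["pairs"])
        assert pairs["pos1"].tolist() == b.pairs["pos1"].tolist()
        assert pairs["strand1"].tolist() == b.pairs["strand1"].tolist()
        genes = read_genes_bed(paths["genes"])
        assert genes["tss"].tolist() == b.genes["tss"].tolist()
        expr = read_expression(paths["expression"])
        assert np.allclose(expr.to_numpy(), b.expression.to_numpy())
        for mark in ("h3k4me3", "h3k4me1", "h3k27ac"):
            bed = read_bed(paths[mark])
            assert len(bed) == len(getattr(b, mark))
        truth = json.loads(paths["truth"].read_text())
        assert truth["link_distance_medians"] == b.truth["link_distance_medians"]
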