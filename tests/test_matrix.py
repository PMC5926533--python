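import numpy as np
import pandas as pd
import pytest

from oceanc.genome import GenomeAssembly
from oceanc.matrix import (
    ContactMatrix,
    bin_pairs,
    boundary_hoci_enrichment,
    compartments,
    hoci_compartment_proportions,
    hoci_filtered_pairs,
    ice_balance,
    insulation_boundaries,
    reorder_by_compartment,
)
from oceanc.simulate import checkerboard_matrix, planted_bias_matrix, tad_block_matrix
from conftest import make_pairs_frame


def _p(pos1, pos2, chrom="c1"):
    return (chrom, pos1, "+", chrom, pos2, "-")


class TestBinPairs:
    def test_single_pair_off_diagonal(self):
        ga = GenomeAssembly({"c1": 200_000})
        m = bin_pairs(make_pairs_frame([_p(10_000, 90_000)]), ga, 40_000)["c1"]
        assert m.counts[0, 2] == 1 and m.counts[2, 0] == 1

    def test_diagonal_pair_counted_once(self):
        ga = GenomeAssembly({"c1": 200_000})
        m = bin_pairs(make_pairs_frame([_p(10_000, 20_000)]), ga, 40_000)["c1"]
        assert m.counts[0, 0] == 1

    def test_empty_pairs_zero_matrix(self):
        ga = GenomeAssembly({"c1": 200_000})
        m = bin_pairs(make_pairs_frame([]), ga, 40_000)["c1"]
        assert m.counts.sum() == 0

    def test_pair_count_conservation(self, default_products):
        b = default_products["bundle"]
        valid = default_products["valid"]
        mats = bin_pairs(valid, b.assembly, 40_000)
        total = sum(np.triu(m.counts).sum() for m in mats.values())
        n_cis = int((valid["chrom1"] == valid["chrom2"]).sum())
        assert total == n_cis


class TestIceBalance:
    def test_row_sum_cv_contract(self):
        rng = np.random.default_rng(1)
        raw = rng.random((200, 200)) + 0.1
        raw = (raw + raw.T) / 2
        bal = ice_balance(ContactMatrix("c", 40_000, raw), mask_quantile=0.0)
        s = bal.counts.sum(axis=1)
        assert s.std() / s.mean() < 1e-4

    def test_planted_bias_recovered(self):
        m, b = planted_bias_matrix(200, seed=1)
        bal = ice_balance(m, mask_quantile=0.0)
        recovered = 1.0 / bal.weights  # correction undoes the bias
        ratio = recovered / b
        assert np.abs(ratio / ratio.mean() - 1).max() < 0.05

    def test_already_balanced_is_fixed_point(self):
        m, _ = planted_bias_matrix(100, seed=2)
        bal1 = ice_balance(m, mask_quantile=0.0)
        bal2 = ice_balance(bal1, mask_quantile=0.0)
        assert np.allclose(bal2.weights, 1.0, atol=1e-3)

    def test_zeros_stay_zero_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        raw = rng.random((50, 50))
        raw = (raw + raw.T) / 2
        raw[5, :] = raw[:, 5] = 0
        m = ContactMatrix("c", 40_000, raw)
        bal = ice_balance(m)
        assert np.all(bal.counts[5, :] == 0)
        scaled = ice_balance(ContactMatrix("c", 40_000, raw * 7.0))
        ratio = scaled.counts[bal.counts > 0] / bal.counts[bal.counts > 0]
        assert np.allclose(ratio, ratio.mean(), rtol=1e-3)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ice_balance(ContactMatrix("c", 40_000, np.zeros((10, 10))))


class TestCompartments:
    def test_checkerboard_recovered(self):
        m, classes = checkerboard_matrix(100, seed=4)
        bal = ice_balance(m)
        track = pd.DataFrame({
            "chrom": "synthetic",
            "start": np.nonzero(classes == 0)[0] * 40_000,
            "end": (np.nonzero(classes == 0)[0] + 1) * 40_000,
        })
        comp = compartments(bal, track)
        lab = comp["label"].to_numpy()
        pred = np.where(lab == "A", 0, np.where(lab == "B", 1, -1))
        ok = pred >= 0
        assert ok.sum() >= 90
        assert (pred[ok] == classes[ok]).mean() >= 0.95

    def test_orientation_flip_flips_labels(self):
        m, classes = checkerboard_matrix(100, seed=4)
        bal = ice_balance(m)
        t0 = pd.DataFrame({"chrom": "synthetic",
                           "start": np.nonzero(classes == 0)[0] * 40_000,
                           "end": (np.nonzero(classes == 0)[0] + 1) * 40_000})
        t1 = pd.DataFrame({"chrom": "synthetic",
                           "start": np.nonzero(classes == 1)[0] * 40_000,
                           "end": (np.nonzero(classes == 1)[0] + 1) * 40_000})
        c0 = compartments(bal, t0)["label"].to_numpy()
        c1 = compartments(bal, t1)["label"].to_numpy()
        both = (c0 != "") & (c1 != "")
        assert np.all(c0[both] != c1[both])

    def test_uniform_matrix_flagged_unreliable(self):
        m = ContactMatrix("c", 40_000, np.ones((50, 50)))
        bal = ice_balance(m, mask_quantile=0.0)
        comp = compartments(bal)
        assert (~comp["reliable"]).all()

    def test_too_few_bins_rejected(self):
        m = ContactMatrix("c", 40_000, np.ones((5, 5)))
        with pytest.raises(ValueError):
            compartments(m)


class TestInsulation:
    def test_planted_boundary_found(self):
        m = tad_block_matrix(60, [30], seed=2)
        bnd = insulation_boundaries(ice_balance(m), window_bins=8,
                                    delta_threshold=0.2)
        assert bnd["bin"].tolist() == [30]

    def test_uniform_matrix_no_boundaries(self):
        m = ContactMatrix("c", 40_000, np.full((60, 60), 10.0))
        bnd = insulation_boundaries(ice_balance(m, mask_quantile=0.0),
                                    window_bins=8, delta_threshold=0.1)
        assert len(bnd) == 0

    def test_window_larger_than_matrix_rejected(self):
        m = ContactMatrix("c", 40_000, np.ones((10, 10)))
        with pytest.raises(ValueError):
            insulation_boundaries(m, window_bins=10)

    def test_boundary_hoci_enrichment(self):
        m = tad_block_matrix(90, [30, 60], seed=2)
        bnd = insulation_boundaries(ice_balance(m), window_bins=8,
                                    delta_threshold=0.2)
        hocis = pd.DataFrame({
            "chrom": "synthetic",
            "start": [b * 40_000 + 1000 for b in bnd["bin"] for _ in range(5)],
            "end": [b * 40_000 + 2000 for b in bnd["bin"] for _ in range(5)],
        })
        res = boundary_hoci_enrichment(bnd, hocis, m, n_permutations=1000, seed=9)
        assert res["fold_enrichment"] > 2
        assert res["p_value"] <= 0.005


class TestReorderAndProportions:
    def test_all_a_identity(self):
        m, _ = checkerboard_matrix(20, seed=0)
        track = pd.DataFrame({"bin": range(20), "label": ["A"] * 20})
        r, order = reorder_by_compartment(m, track)
        assert order.tolist() == list(range(20))
        assert np.array_equal(r.counts, m.counts)

    def test_hand_checked_permutation(self):
        m = ContactMatrix("c", 40_000, np.arange(16, dtype=float).reshape(4, 4))
        track = pd.DataFrame({"bin": range(4), "label": ["B", "A", "B", "A"]})
        _, order = reorder_by_compartment(m, track)
        assert order.tolist() == [1, 3, 0, 2]

    def test_permutation_preserves_spectrum(self):
        m, classes = checkerboard_matrix(30, seed=1)
        track = pd.DataFrame({"bin": range(30),
                              "label": np.where(classes == 0, "A", "B")})
        r, _ = reorder_by_compartment(m, track)
        ev1 = np.sort(np.linalg.eigvalsh(m.counts))
        ev2 = np.sort(np.linalg.eigvalsh(r.counts))
        assert np.allclose(ev1, ev2)

    def test_track_size_mismatch_rejected(self):
        m, _ = checkerboard_matrix(20, seed=0)
        with pytest.raises(ValueError):
            reorder_by_compartment(m, pd.DataFrame({"bin": [0], "label": ["A"]}))

    def test_all_hocis_in_a(self):
        hocis = pd.DataFrame({"chrom": ["c1", "c1"], "start": [1000, 90_000],
                              "end": [2000, 91_000]})
        track = pd.DataFrame({"bin": range(5), "label": ["A", "A", "A", "B", "B"]})
        res = hoci_compartment_proportions(hocis, make_pairs_frame([]), track,
                                           "c1", 40_000)
        assert res["hoci"]["A"] == 1.0

    def test_unlabeled_track_rejected(self):
        hocis = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10]})
        track = pd.DataFrame({"bin": range(3), "label": ["", "", ""]})
        with pytest.raises(ValueError):
            hoci_compartment_proportions(hocis, make_pairs_frame([]), track,
                                         "c1", 40_000)


class TestHociFiltered:
    HOCIS = pd.DataFrame({"chrom": ["c1"], "start": [1000], "end": [2000]})

    def test_no_touching_pairs_empty(self):
        pairs = make_pairs_frame([_p(5000, 9000)])
        assert len(hoci_filtered_pairs(pairs, self.HOCIS)) == 0

    def test_all_touching_identity(self):
        pairs = make_pairs_frame([_p(1500, 9000), _p(1100, 1900)])
        assert len(hoci_filtered_pairs(pairs, self.HOCIS)) == 2

    def test_partial_subset(self):
        pairs = make_pairs_frame([_p(1500, 9000), _p(5000, 9000), _p(1100, 1900),
                                  _p(7000, 9000), _p(8000, 9000)])
        assert len(hoci_filtered_pairs(pairs, self.HOCIS)) == 2
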