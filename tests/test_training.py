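"""Label transforms, losses, metrics, splits, and label file parsing."""

import numpy as np
import pytest

from dtbind.autodiff import Tensor
from dtbind.fixtures import make_toy_protein
from dtbind.structure_io import write_pdb
from dtbind.training import (binary_cross_entropy, binding_imbalance_ratio,
                             compute_metrics, focal_loss, paffinity,
                             read_site_labels, split_dataset)


class TestPaffinity:
    @pytest.mark.parametrize("molar,expected", [
        (1.0, 0.0),
        (1e-6, 6.0),
        (5e-8, 7.30103),
    ])
    def test_reference_values(self, molar, expected):
        assert paffinity(molar) == pytest.approx(expected, abs=1e-5)

    def test_nonpositive_raises(self):
        for bad in (0.0, -1e-9):
            with pytest.raises(ValueError):
                paffinity(bad)


class TestFocalLoss:
    def test_gamma_zero_alpha_half_is_half_bce(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=50)
        y = rng.integers(0, 2, size=50)
        focal = float(focal_loss(p, y, alpha=0.5, gamma=0.0).data)
        bce = float(binary_cross_entropy(Tensor(p), y).data)
        assert focal == pytest.approx(0.5 * bce, abs=1e-9)

    def test_hand_evaluated_single_positive(self):
        # p=0.9, y=1, alpha=0.25, gamma=2: 0.25 * 0.1^2 * (−ln 0.9)
        val = float(focal_loss(np.array([0.9]), np.array([1]),
                               alpha=0.25, gamma=2.0).data)
        assert val == pytest.approx(0.25 * 0.01 * -np.log(0.9), abs=1e-12)
        assert val == pytest.approx(2.634e-4, abs=1e-6)

    def test_vanishes_for_perfect_predictions(self):
        p = np.array([1 - 1e-9, 1e-9])
        y = np.array([1, 0])
        assert float(focal_loss(p, y).data) < 1e-6

    def test_focal_bounded_by_alpha_weighted_bce(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 0.99, size=200)
        y = rng.integers(0, 2, size=200)
        for gamma in (0.5, 1.0, 2.0):
            for pi, yi in zip(p, y):
                f = float(focal_loss(np.array([pi]), np.array([yi]),
                                     alpha=0.25, gamma=gamma).data)
                alpha_t = 0.25 if yi else 0.75
                p_t = pi if yi else 1 - pi
                assert f <= alpha_t * -np.log(p_t) + 1e-12

    def test_out_of_range_probabilities_clipped(self):
        val = float(focal_loss(np.array([1.0, 0.0]), np.array([1, 0])).data)
        assert np.isfinite(val)

    def test_misaligned_shapes_raise(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([0.5, 0.5]), np.array([1]))


class TestMetrics:
    def test_perfect_binary_predictions(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([0.9, 0.8, 0.1, 0.2, 0.95])
        report = compute_metrics(p, y, "occurrence")
        for key in ("mcc", "f1", "auroc", "auprc", "accuracy"):
            assert report[key] == pytest.approx(1.0)

    def test_balanced_confusion_counts(self):
        # TP=1, TN=1, FP=1, FN=1
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.1, 0.9, 0.1])
        report = compute_metrics(p, y, "occurrence")
        assert report["mcc"] == pytest.approx(0.0)
        assert report["f1"] == pytest.approx(0.5)
        assert report["accuracy"] == pytest.approx(0.5)
        assert report["specificity"] == pytest.approx(0.5)

    def test_perfect_regression(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        report = compute_metrics(y, y, "affinity")
        assert report["rmse"] == 0.0 and report["mae"] == 0.0
        assert report["pearson"] == pytest.approx(1.0)
        assert report["spearman"] == pytest.approx(1.0)

    def test_single_class_auroc_is_nan(self):
        report = compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]),
                                 "occurrence")
        assert np.isnan(report["auroc"])

    def test_auroc_matches_pairwise_rank_counting(self):
        """Rank-integral AUROC against the brute-force pair-count oracle."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(4, 25)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.uniform(size=n)
            report = compute_metrics(p, y, "occurrence")
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((pi > ni) + 0.5 * (pi == ni)
                       for pi in pos for ni in neg)
            brute = wins / (len(pos) * len(neg))
            assert report["auroc"] == pytest.approx(brute, abs=1e-9)

    def test_spearman_uses_average_tie_ranks(self):
        p = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        report = compute_metrics(p, y, "affinity")
        from scipy.stats import spearmanr
        assert report["spearman"] == pytest.approx(spearmanr(p, y)[0])


class TestSplit:
    def test_ten_records_split_7_1_2(self):
        train, val, test = split_dataset(list(range(10)), seed=4)
        assert (len(train), len(val), len(test)) == (7, 1, 2)

    def test_large_split_sizes_by_rounding(self):
        records = list(range(13_920))
        train, val, test = split_dataset(records, seed=5)
        assert (len(train), len(val), len(test)) == (9744, 1392, 2784)
        assert sorted(train + val + test) == records

    def test_reproducible_and_disjoint(self):
        a = split_dataset(list(range(50)), seed=6)
        b = split_dataset(list(range(50)), seed=6)
        assert a == b
        assert not (set(a[0]) & set(a[1]) or set(a[0]) & set(a[2])
                    or set(a[1]) & set(a[2]))

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], seed=0)


class TestSiteLabels:
    def test_empty_file_gives_zero_vector(self, tmp_path, toy_protein):
        path = tmp_path / "labels.txt"
        path.write_text("")
        labels = read_site_labels(path, toy_protein)
        assert labels.shape == (toy_protein.n_residues,)
        assert labels.sum() == 0

    def test_listed_residues_marked(self, tmp_path, toy_protein):
        path = tmp_path / "labels.txt"
        path.write_text("A:3\nA:7\nA:15\n")
        labels = read_site_labels(path, toy_protein)
        assert labels.sum() == 3
        assert labels[2] == labels[6] == labels[14] == 1

    def test_unknown_residue_strict_vs_lenient(self, tmp_path, toy_protein):
        path = tmp_path / "labels.txt"
        path.write_text("A:3\nA:7\nB:99\n")
        with pytest.raises(KeyError):
            read_site_labels(path, toy_protein, strict=True)
        labels = read_site_labels(path, toy_protein, strict=False)
        assert labels.sum() == 2


def test_dataset_imbalance_ratio_rounds_to_48():
    assert binding_imbalance_ratio() == 48
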