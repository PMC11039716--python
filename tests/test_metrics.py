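"""Evaluation stack: Dice, HD95 against a brute-force surface-distance
oracle, true-positive-component filtering, exact Wilcoxon enumeration, and
Bonferroni correction."""

import math
import warnings

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from geoppe import (
    ContractError,
    DataError,
    bonferroni,
    dice,
    hd95,
    hd95_tp_components,
    summarize_scores,
    wilcoxon_signed_rank,
)
from geoppe.metrics import SegScore


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_hd95(pred, gt, spacing):
    """O(n^2) all-pairs surface-distance percentile (no KD-tree)."""
    def surface(mask):
        er = ndimage.binary_erosion(
            mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
        )
        return np.argwhere(mask & ~er) * np.asarray(spacing, dtype=float)

    a, b = surface(np.asarray(pred, bool)), surface(np.asarray(gt, bool))
    d = cdist(a, b)
    return float(np.percentile(np.concatenate([d.min(1), d.min(0)]), 95))


def enumeration_wilcoxon(a, b):
    """Exact two-sided p via explicit 2^n sign-flip enumeration."""
    from scipy.stats import rankdata
    from itertools import product

    diff = np.asarray(a, float) - np.asarray(b, float)
    diff = diff[diff != 0]
    ranks = rankdata(np.abs(diff))
    w = ranks[diff > 0].sum()
    dist = [np.dot(signs, ranks) for signs in product([0, 1], repeat=len(diff))]
    dist = np.asarray(dist)
    p_le = np.mean(dist <= w + 1e-12)
    p_ge = np.mean(dist >= w - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def _random_mask(rng, shape=(8, 8, 8), p=0.2):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


class TestDice:
    def test_identical_masks(self, rng):
        m = _random_mask(rng)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_worked_fraction(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.ravel()[:4] = True           # |P| = 4
        b.ravel()[2:10] = True         # |G| = 8, overlap 2
        assert dice(a, b) == pytest.approx(1.0 / 3.0)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0

    def test_symmetry(self, rng):
        a, b = _random_mask(rng), _random_mask(rng)
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ContractError, match="shapes"):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = _random_mask(rng)
        assert hd95(m, m, (1, 1, 1)) == 0.0

    def test_two_voxels_known_distance(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert hd95(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)
        assert hd95(a, b, (2.0, 1.0, 1.0)) == pytest.approx(6.0)

    def test_empty_mask_undefined(self, rng):
        with pytest.warns(UserWarning, match="empty"):
            assert math.isnan(hd95(np.zeros((8, 8, 8), bool), _random_mask(rng), (1, 1, 1)))

    def test_symmetry(self, rng):
        a, b = _random_mask(rng), _random_mask(rng)
        assert hd95(a, b, (1, 2, 3)) == pytest.approx(hd95(b, a, (1, 2, 3)))

    def test_axis_permutation_invariance(self, rng):
        a, b = _random_mask(rng, (6, 8, 10)), _random_mask(rng, (6, 8, 10))
        spacing = (1.0, 2.0, 3.0)
        perm = (2, 0, 1)
        assert hd95(a, b, spacing) == pytest.approx(
            hd95(
                np.transpose(a, perm),
                np.transpose(b, perm),
                tuple(spacing[i] for i in perm),
            )
        )

    def test_matches_brute_force_oracle(self, rng):
        """KD-tree implementation vs O(n^2) all-pairs oracle on 200 pairs."""
        for _ in range(200):
            a = _random_mask(rng, (6, 6, 6), p=float(rng.uniform(0.05, 0.5)))
            b = _random_mask(rng, (6, 6, 6), p=float(rng.uniform(0.05, 0.5)))
            spacing = rng.uniform(0.5, 3.0, size=3)
            assert hd95(a, b, spacing) == pytest.approx(
                brute_force_hd95(a, b, spacing), abs=1e-9
            )


class TestHD95TPComponents:
    def test_distant_false_positive_discarded(self):
        gt = np.zeros((12, 12, 12), bool)
        gt[2:4, 2:4, 2:4] = True
        pred = gt.copy()
        pred[10, 10, 10] = True  # spurious distant component
        assert hd95_tp_components(pred, gt, (1, 1, 1)) == 0.0
        # without filtering, the spurious voxel inflates the percentile
        assert hd95(pred, gt, (1, 1, 1)) > 0.0

    def test_no_overlap_undefined(self):
        gt = np.zeros((8, 8, 8), bool)
        gt[0:2, 0:2, 0:2] = True
        pred = np.zeros_like(gt)
        pred[6:8, 6:8, 6:8] = True
        with pytest.warns(UserWarning, match="overlap"):
            assert math.isnan(hd95_tp_components(pred, gt, (1, 1, 1)))

    def test_mixed_case_matches_two_step_oracle(self, rng):
        """Composition oracle: 26-connected component filter by hand, then
        plain hd95."""
        for _ in range(20):
            gt = _random_mask(rng, (8, 8, 8), 0.15)
            pred = _random_mask(rng, (8, 8, 8), 0.15)
            labels, n = ndimage.label(pred, structure=np.ones((3, 3, 3)))
            keep = np.zeros_like(pred)
            for comp in range(1, n + 1):
                if np.logical_and(labels == comp, gt).any():
                    keep |= labels == comp
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                ours = hd95_tp_components(pred, gt, (1, 1, 1))
            if not keep.any():
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(hd95(keep, gt, (1, 1, 1)), abs=1e-12)

    def test_empty_gt_rejected(self):
        with pytest.raises(DataError, match="non-empty"):
            hd95_tp_components(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool), (1, 1, 1))


class TestWilcoxon:
    def test_five_positive_differences(self):
        """n=5 one-sided tail 1/32 -> two-sided 0.0625."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.5, 0.3, 0.8, 0.1, 0.9])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.0625)

    def test_equal_samples_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError, match=">= 5"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])

    def test_exact_branch_matches_enumeration(self, rng):
        """All n <= 10 against the full 2^n sign-flip oracle, ties included."""
        for n in range(5, 11):
            for _ in range(5):
                a = np.round(rng.normal(size=n), 1)
                b = np.round(rng.normal(size=n), 1)
                if np.all(a == b):
                    continue
                diff = (a - b)[(a - b) != 0]
                if diff.size < 5:
                    continue
                assert wilcoxon_signed_rank(a, b) == pytest.approx(
                    enumeration_wilcoxon(a, b), abs=1e-12
                )

    def test_symmetric_in_sign(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(wilcoxon_signed_rank(b, a))

    def test_large_n_uses_normal_approximation(self, rng):
        from scipy import stats

        a = rng.normal(0.3, 1.0, size=40)
        b = rng.normal(0.0, 1.0, size=40)
        expected = stats.wilcoxon(a - b, zero_method="wilcox", mode="approx").pvalue
        assert wilcoxon_signed_rank(a, b) == pytest.approx(float(expected))


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni([0.01, 0.9], 2) == [0.02, 1.0]

    def test_identity_for_single_comparison(self):
        assert bonferroni([0.3], 1) == [0.3]

    def test_m_defaults_to_count(self):
        assert bonferroni([0.1, 0.2]) == [0.2, 0.4]

    def test_rejects_small_m_and_bad_p(self):
        with pytest.raises(DataError):
            bonferroni([0.1, 0.2], 1)
        with pytest.raises(DataError):
            bonferroni([1.5], 1)


class TestSummaries:
    def test_undefined_hd95_excluded_with_count(self):
        scores = [
            SegScore("a", 0.8, 2.0),
            SegScore("b", 0.6, math.nan),
            SegScore("c", 1.0, 4.0),
        ]
        s = summarize_scores(scores)
        assert s["mean_dice"] == pytest.approx(0.8)
        assert s["mean_hd95"] == pytest.approx(3.0)
        assert s["n_hd95_defined"] == 2
        assert s["n"] == 3
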