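"""ROC_MoRF evaluation against brute-force and reference oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from morf_fuse.evaluation import (
    LabeledScores,
    auc_morf,
    fpr_at_tpr,
    pool_scores,
    roc_curve,
    sens_spec_at_cutoff,
)
from morf_fuse.tracks_io import MoRFAnnotation, ResidueTrack


def random_instance(rng, with_ties=True):
    n = int(rng.integers(5, 60))
    scores = rng.random(n)
    if with_ties and rng.random() < 0.5:
        scores = np.round(scores, 1)  # force ties
    labels = rng.random(n) < rng.uniform(0.2, 0.8)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return LabeledScores(scores, labels)


def brute_mann_whitney(ls):
    """Concordance count: (concordant + ties/2) / (n_pos * n_neg)."""
    pos = ls.scores[ls.labels]
    neg = ls.scores[~ls.labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestPooling:
    def test_counting_mode_all(self):
        ann = MoRFAnnotation("s1", [(10, 19, "morf")])
        track = ResidueTrack("s1", np.linspace(0.01, 0.99, 50))
        ls = pool_scores({"s1": track}, {"s1": ann}, "all")
        assert ls.n_morf == 10
        assert ls.n_non_morf == 40

    def test_long_interval_masked_in_short_mode(self):
        ann = MoRFAnnotation("s1", [(1, 40, "morf")])
        track = ResidueTrack("s1", np.linspace(0.01, 0.99, 100))
        ls = pool_scores({"s1": track}, {"s1": ann}, "short_only")
        assert ls.n_morf == 0
        assert ls.n_non_morf == 60  # the 40 masked residues are in neither class

    def test_boundary_interval_of_30_counts_as_short(self):
        ann = MoRFAnnotation("s1", [(1, 30, "morf")])
        track = ResidueTrack("s1", np.linspace(0.01, 0.99, 50))
        assert pool_scores({"s1": track}, {"s1": ann}, "short_only").n_morf == 30
        assert pool_scores({"s1": track}, {"s1": ann}, "long_only").n_morf == 0

    def test_masked_label_always_removed(self):
        ann = MoRFAnnotation("s1", [(1, 10, "morf"), (20, 29, "masked")])
        track = ResidueTrack("s1", np.linspace(0.01, 0.99, 50))
        ls = pool_scores({"s1": track}, {"s1": ann}, "all")
        assert ls.n_morf == 10
        assert ls.n_non_morf == 30

    def test_masking_partitions_morf_residues(self):
        rng = np.random.default_rng(12)
        tracks, anns = {}, {}
        for i in range(30):
            sid = f"s{i}"
            L = int(rng.integers(60, 200))
            start = int(rng.integers(1, L - 45))
            length = int(rng.integers(5, 46))
            tracks[sid] = ResidueTrack(sid, rng.random(L))
            anns[sid] = MoRFAnnotation(sid, [(start, start + length - 1, "morf")])
        n_all = pool_scores(tracks, anns, "all").n_morf
        n_short = pool_scores(tracks, anns, "short_only").n_morf
        n_long = pool_scores(tracks, anns, "long_only").n_morf
        assert n_all == n_short + n_long

    def test_unannotated_sequence_rejected(self):
        track = ResidueTrack("s1", np.linspace(0.01, 0.99, 10))
        with pytest.raises(ValueError, match="s1"):
            pool_scores({"s1": track}, {}, "all")


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        ls = LabeledScores([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        points = roc_curve(ls)
        assert (0.0, 1.0) in points
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_all_identical_scores_two_points(self):
        ls = LabeledScores([0.5, 0.5, 0.5], [True, False, True])
        assert roc_curve(ls) == [(0.0, 0.0), (1.0, 1.0)]

    def test_monotone_coordinates(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            fpr, tpr = np.array(roc_curve(random_instance(rng))).T
            assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(LabeledScores([0.5, 0.6], [True, True]))

    def test_agreement_with_reference_implementation(self):
        """AUC from our curve matches scikit-learn on 1000 random instances."""
        rng = np.random.default_rng(14)
        for _ in range(1000):
            ls = random_instance(rng)
            ours = auc_morf(ls)
            ref = roc_auc_score(ls.labels, ls.scores)
            assert np.isclose(ours, ref, rtol=0, atol=1e-12)


class TestAuc:
    def test_perfect_and_inverted(self):
        ls = LabeledScores([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc_morf(ls) == 1.0
        ls_inv = LabeledScores([0.9, 0.8, 0.2, 0.1], [False, False, True, True])
        assert auc_morf(ls_inv) == 0.0

    def test_null_behavior(self):
        rng = np.random.default_rng(15)
        ls = LabeledScores(rng.random(20000), rng.random(20000) < 0.5)
        assert abs(auc_morf(ls) - 0.5) < 0.02

    def test_equals_brute_force_mann_whitney(self):
        rng = np.random.default_rng(16)
        for _ in range(1000):
            ls = random_instance(rng)
            assert np.isclose(
                auc_morf(ls), brute_mann_whitney(ls), rtol=0, atol=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            ls = random_instance(rng)
            warped = LabeledScores(np.exp(3.0 * ls.scores) - 0.5, ls.labels)
            assert auc_morf(warped) == auc_morf(ls)


class TestFprAtTpr:
    def test_perfect_separation(self):
        ls = LabeledScores([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert fpr_at_tpr(ls, [0.5]) == [0.0]

    def test_all_identical_scores(self):
        ls = LabeledScores([0.5, 0.5, 0.5], [True, False, True])
        assert fpr_at_tpr(ls, [0.2]) == [1.0]

    def test_brute_force_threshold_scan(self):
        rng = np.random.default_rng(18)
        targets = [0.2, 0.3, 0.4, 0.5]
        for _ in range(300):
            ls = random_instance(rng)
            got = fpr_at_tpr(ls, targets)
            # scan every distinct score as a >= threshold
            thresholds = np.unique(ls.scores)
            for t_target, fpr_got in zip(targets, got):
                best = 1.0  # threshold below everything always reaches TPR 1
                for thr in thresholds:
                    called = ls.scores >= thr
                    tpr = (called & ls.labels).sum() / ls.n_morf
                    fpr = (called & ~ls.labels).sum() / ls.n_non_morf
                    if tpr >= t_target:
                        best = min(best, fpr)
                assert np.isclose(fpr_got, best, rtol=0, atol=1e-12)

    def test_invalid_target_rejected(self):
        ls = LabeledScores([0.5, 0.6], [True, False])
        with pytest.raises(ValueError, match="outside"):
            fpr_at_tpr(ls, [0.0])


class TestSensSpec:
    def test_extreme_cutoffs(self):
        ls = LabeledScores([0.3, 0.5, 0.7], [True, False, True])
        assert sens_spec_at_cutoff(ls, 0.01) == (1.0, 0.0)
        assert sens_spec_at_cutoff(ls, 0.99) == (0.0, 1.0)

    def test_point_lies_on_roc_curve(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            ls = random_instance(rng)
            cutoff = float(rng.random())
            sens, spec = sens_spec_at_cutoff(ls, cutoff)
            points = roc_curve(ls)
            assert any(
                np.isclose(f, 1 - spec, atol=1e-12) and np.isclose(t, sens, atol=1e-12)
                for f, t in points
            )
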