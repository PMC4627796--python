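"""Tests of the conservation scores: ics fusion and the mcs window rules.

The oracle for compute_mcs is a deliberately naive per-residue
re-implementation of the two scenario rules, written directly from their
prose definition with explicit python loops.
"""

import math

import numpy as np
import pytest

from morf_fuse.conservation import McsParams, compute_ics, compute_mcs
from morf_fuse.evaluation import LabeledScores, auc_morf
from morf_fuse.fusion import bayes_combine
from morf_fuse.normalization import fit_map, apply_map
from morf_fuse.tracks_io import ResidueTrack, Space

from conftest import normalized_track


def naive_mcs(ics, disorder, params=None):
    """Independent reference implementation: per-residue loops, no numpy."""
    p = params or McsParams()
    ics = list(map(float, ics))
    dis = list(map(float, disorder))
    L = len(ics)
    out = []
    for r in range(L):
        h1 = p.disorder_window // 2
        w1 = [i for i in range(r - h1, r + h1 + 1) if 0 <= i < L]
        dis_avg1 = math.fsum(dis[i] for i in w1) / len(w1)
        conserved = [ics[i] for i in w1 if ics[i] > p.ics_conserved]
        k = len(conserved)
        if dis_avg1 > p.disorder_hi and k >= p.min_conserved:
            value = math.fsum(conserved) / k
            extras = k - p.min_conserved
            if p.root_per_extra:
                for _ in range(2 * extras):
                    value = math.sqrt(value)
            elif extras > 0:
                value = math.sqrt(math.sqrt(value))
            out.append(value)
            continue
        h2 = p.structured_window // 2
        w2 = [i for i in range(r - h2, r + h2 + 1) if 0 <= i < L]
        dis_avg2 = math.fsum(dis[i] for i in w2) / len(w2)
        if dis_avg2 < p.disorder_lo and all(ics[i] <= p.ics_cap for i in w2):
            out.append(ics[r] * dis_avg2)
            continue
        out.append(ics[r])
    return out


def mcs_values(ics_vals, dis_vals, params=None):
    return compute_mcs(
        normalized_track(ics_vals), normalized_track(dis_vals), params
    ).values


class TestWorkedExamples:
    """Hand-built 7- and 15-residue windows exercising each rule exactly."""

    def test_scenario1_without_boost(self):
        # center of a 7-window, disorder average 0.50, exactly three
        # conserved residues with ics {0.5, 0.6, 0.7} -> their mean, 0.6
        ics = [0.5, 0.6, 0.7, 0.2, 0.3, 0.1, 0.2]
        dis = [0.5] * 7
        assert np.isclose(mcs_values(ics, dis)[3], 0.6, rtol=0, atol=1e-15)

    def test_scenario1_with_boost(self):
        # four conserved residues, mean 0.65; one extra conserved residue
        # means the square root is applied twice: 0.65 ** (1/4)
        ics = [0.5, 0.6, 0.7, 0.8, 0.3, 0.1, 0.2]
        dis = [0.5] * 7
        expected = 0.65 ** 0.25
        got = mcs_values(ics, dis)[3]
        assert np.isclose(got, expected, rtol=1e-12)
        assert np.isclose(got, 0.8979, atol=5e-5)

    def test_scenario2(self):
        # structured 15-window: disorder average 0.30, all ics <= 0.60,
        # center ics 0.50 -> 0.50 * 0.30
        ics = [0.4] * 7 + [0.5] + [0.4] * 7
        dis = [0.3] * 15
        assert np.isclose(mcs_values(ics, dis)[7], 0.15, rtol=1e-12)

    def test_default_case_keeps_ics(self):
        # disorder average above 0.45 but only two conserved residues, and
        # the 15-window disorder average is also above 0.45: neither rule
        ics = [0.5, 0.6, 0.2, 0.42, 0.3, 0.1, 0.2]
        dis = [0.5] * 7
        assert mcs_values(ics, dis)[3] == 0.42

    def test_alternative_boost_reading(self):
        # with root_per_extra=False the root pair is applied once total
        params = McsParams(root_per_extra=False)
        ics = [0.5, 0.6, 0.7, 0.8, 0.46, 0.1, 0.2]  # five conserved
        dis = [0.5] * 7
        k_vals = [v for v in ics if v > 0.45]
        expected = (sum(k_vals) / len(k_vals)) ** 0.25
        assert np.isclose(mcs_values(ics, dis, params)[3], expected, rtol=1e-12)


class TestProperties:
    def test_exact_agreement_with_naive_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(300):
            L = int(rng.integers(1, 40))
            ics = rng.uniform(0.01, 0.99, L)
            dis = rng.uniform(0.01, 0.99, L)
            got = mcs_values(ics, dis)
            want = naive_mcs(ics, dis)
            assert np.array_equal(got, want), (ics, dis)

    def test_oracle_agreement_under_alternative_boost(self):
        rng = np.random.default_rng(34)
        params = McsParams(root_per_extra=False)
        for _ in range(100):
            L = int(rng.integers(5, 30))
            ics = rng.uniform(0.01, 0.99, L)
            dis = rng.uniform(0.01, 0.99, L)
            assert np.array_equal(
                mcs_values(ics, dis, params), naive_mcs(ics, dis, params)
            )

    def test_scenario1_never_below_conserved_mean(self):
        # roots of values in (0, 1) only increase them
        rng = np.random.default_rng(35)
        ics = rng.uniform(0.46, 0.99, 30)  # everything conserved
        dis = rng.uniform(0.6, 0.99, 30)  # everything disordered
        out = mcs_values(ics, dis)
        for r in range(30):
            w = [i for i in range(r - 3, r + 4) if 0 <= i < 30]
            assert out[r] >= np.mean(ics[w]) - 1e-12

    def test_scenario2_never_exceeds_ics(self):
        rng = np.random.default_rng(36)
        ics = rng.uniform(0.01, 0.44, 40)
        dis = rng.uniform(0.01, 0.3, 40)
        out = mcs_values(ics, dis)
        assert np.all(out <= ics)
        assert np.all(out < ics)  # multiplication by < 0.45 strictly shrinks

    def test_disorder_pinned_at_threshold_fires_nothing(self):
        rng = np.random.default_rng(37)
        ics = rng.uniform(0.01, 0.99, 50)
        dis = np.full(50, 0.45)
        assert np.array_equal(mcs_values(ics, dis), ics)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_mcs(normalized_track([0.5] * 3), normalized_track([0.5] * 4))


class TestMcsParams:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            McsParams(disorder_window=8)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError, match="ics_cap"):
            McsParams(ics_cap=1.5)


class TestIcs:
    def test_non_informative_fixed_point(self):
        tracks = [normalized_track([0.5] * 3) for _ in range(3)]
        out = compute_ics(*tracks)
        assert np.allclose(out.values, 0.5, atol=1e-15)
        assert out.space is Space.RAW  # before refit

    def test_three_point_six(self):
        # odds (0.6/0.4)^3 = 3.375 -> 3.375/4.375
        tracks = [normalized_track([0.6]) for _ in range(3)]
        assert np.isclose(
            compute_ics(*tracks).values[0], 3.375 / 4.375, rtol=1e-12
        )

    def test_refit_with_map(self):
        rng = np.random.default_rng(40)
        tracks = [normalized_track(rng.uniform(0.2, 0.8, 200)) for _ in range(3)]
        raw = compute_ics(*tracks)
        nmap = fit_map(raw.values, "ics")
        out = compute_ics(*tracks, ics_map=nmap)
        assert out.space is Space.NORMALIZED
        assert np.array_equal(out.values, apply_map(nmap, raw).values)

    def test_ics_auc_not_below_components(self):
        """Fusing three enriched features should not lose separating power."""
        rng = np.random.default_rng(41)
        n, frac = 4000, 0.1
        labels = rng.random(n) < frac
        comps = []
        for _ in range(3):
            v = np.where(labels, rng.beta(5, 3, n), rng.beta(3, 5, n))
            comps.append(np.clip(v, 1e-9, 1 - 1e-9))
        tracks = [normalized_track(c) for c in comps]
        ics = compute_ics(*tracks)
        auc_ics = auc_morf(LabeledScores(ics.values, labels))
        auc_comps = [auc_morf(LabeledScores(c, labels)) for c in comps]
        assert auc_ics >= max(auc_comps) - 0.02
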