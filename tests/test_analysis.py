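import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plethysym as ps
from plethysym.analysis import (RCDistribution, compare_groups,
                                marginal_profiles, rc_distribution)
from plethysym.config import OUTLIER
from plethysym.errors import ParameterError

from helpers import mw_exact_two_sided


def _sym(rows, subject="s1", group="g", phase="pre", fs=250.0):
    df = pd.DataFrame(rows, columns=["t_in_s", "t_out_s", "t_end_s",
                                     "insp_symbol", "exp_symbol",
                                     "insp_dist", "exp_dist", "outlier"])
    df.insert(0, "cycle_index", np.arange(len(df)))
    return ps.SymbolicRecording(df, subject, group, phase, fs)


class TestRcDistribution:
    def test_single_class_recording(self):
        sym = _sym([(0.0, 0.1, 0.3, "A", "0", 1.0, 1.0, False),
                    (0.3, 0.4, 0.6, "A", "0", 1.0, 1.0, False)])
        dist = rc_distribution(sym, ["A", "B"], ["0", "1"])
        assert dist.matrix[0, 0] == pytest.approx(100.0)
        assert dist.matrix.sum() == pytest.approx(100.0)

    def test_two_classes_with_equal_time_split_evenly(self):
        sym = _sym([(0.0, 0.1, 0.3, "A", "0", 1, 1, False),
                    (0.3, 0.4, 0.6, "B", "1", 1, 1, False)])
        dist = rc_distribution(sym, ["A", "B"], ["0", "1"])
        assert dist.matrix[0, 0] == pytest.approx(50.0)
        assert dist.matrix[1, 1] == pytest.approx(50.0)

    def test_outlier_time_reported_separately(self):
        sym = _sym([(0.0, 0.1, 0.3, "A", "0", 1, 1, False),
                    (0.3, np.nan, 0.9, OUTLIER, OUTLIER, np.nan, np.nan, True)])
        dist = rc_distribution(sym, ["A"], ["0"])
        assert dist.matrix[0, 0] == pytest.approx(100.0)
        assert dist.outlier_time_fraction == pytest.approx(0.6 / 0.9)

    def test_all_outlier_recording_flags_and_zeroes(self):
        sym = _sym([(0.0, np.nan, 0.5, OUTLIER, OUTLIER, np.nan, np.nan, True)])
        dist = rc_distribution(sym, ["A"], ["0"])
        assert dist.all_outliers
        np.testing.assert_array_equal(dist.matrix, 0.0)

    def test_generator_recording_matches_programmed_fractions(
            self, trio_fit, trio_archetypes):
        # symbol-perfect bookkeeping check on an alternating A0/C2 recording
        arch = [trio_archetypes["A0"], trio_archetypes["C2"]] * 15
        rec, truth = ps.generate_recording(arch, seed=5)
        seg = ps.segment_recording(rec, 0.03, 2.0, 0.05, 2.0)
        sym_rows = []
        for k in range(seg.n_cycles):
            name = truth.cycles["archetype"].iloc[
                np.abs(truth.cycles["t_in_s"] - seg.t_in[k] / seg.fs).argmin()]
            sym_rows.append((seg.t_in[k] / seg.fs, seg.t_out[k] / seg.fs,
                             seg.t_end[k] / seg.fs, name[0], name[1],
                             1.0, 1.0, False))
        sym = _sym(sym_rows)
        dist = rc_distribution(sym, ["A", "C"], ["0", "2"])
        dur = (np.array([r[2] for r in sym_rows]) - np.array([r[0] for r in sym_rows]))
        is_a = np.array([r[3] == "A" for r in sym_rows])
        expected_a = 100.0 * dur[is_a].sum() / dur.sum()
        assert dist.matrix[0, 0] == pytest.approx(expected_a, abs=1e-9)
        assert dist.matrix[1, 1] == pytest.approx(100.0 - expected_a, abs=1e-9)

    def test_invariant_to_cycle_order_reversal(self):
        rows = [(0.0, 0.1, 0.3, "A", "0", 1, 1, False),
                (0.3, 0.45, 0.5, "B", "1", 1, 1, False),
                (0.5, 0.58, 0.9, "A", "1", 1, 1, False)]
        d1 = rc_distribution(_sym(rows), ["A", "B"], ["0", "1"])
        d2 = rc_distribution(_sym(rows[::-1][:]), ["A", "B"], ["0", "1"])
        # durations are what matter, not order: rebuild times for reversal
        np.testing.assert_allclose(d1.matrix, d2.matrix)


class TestMarginals:
    def test_uniform_matrix_gives_flat_marginals(self):
        dist = RCDistribution(np.full((5, 5), 4.0), list("ABCDE"), list("01234"))
        mi, me = marginal_profiles(dist)
        np.testing.assert_allclose(mi, 20.0)
        np.testing.assert_allclose(me, 20.0)

    def test_single_class_gives_one_hot_marginals(self):
        m = np.zeros((2, 2))
        m[1, 0] = 100.0
        mi, me = marginal_profiles(RCDistribution(m, ["A", "B"], ["0", "1"]))
        np.testing.assert_allclose(mi, [0.0, 100.0])
        np.testing.assert_allclose(me, [100.0, 0.0])

    def test_random_matrix_against_direct_summation(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(size=(4, 6))
        mi, me = marginal_profiles(RCDistribution(m, list("ABCD"), list("012345")))
        np.testing.assert_allclose(mi, m.sum(axis=1))
        np.testing.assert_allclose(me, m.sum(axis=0))


def _dists_from_matrices(mats, group="g"):
    return [RCDistribution(m, list("ABCDE"), list("01234"), subject_id=f"s{i}",
                           group=group) for i, m in enumerate(mats)]


class TestCompareGroups:
    def test_identical_groups_give_no_rejections(self):
        rng = np.random.default_rng(1)
        mats = [rng.dirichlet(np.ones(25)).reshape(5, 5) * 100 for _ in range(8)]
        tm = compare_groups(_dists_from_matrices(mats),
                            _dists_from_matrices([m.copy() for m in mats]))
        assert not tm.rejected.any()
        assert np.all(tm.raw_p > 0.9)

    def test_exact_small_sample_p_matches_permutation_oracle(self):
        a = [1.0, 2.0, 3.0]
        b = [4.0, 5.0, 6.0]
        oracle = mw_exact_two_sided(a, b)
        assert oracle == pytest.approx(0.1)
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(oracle)
        # through the map machinery: plant the samples in one cell
        mats_a = [np.full((5, 5), 4.0) for _ in range(3)]
        mats_b = [np.full((5, 5), 4.0) for _ in range(3)]
        for m, v in zip(mats_a, a):
            m[1, 4] = v
        for m, v in zip(mats_b, b):
            m[1, 4] = v
        tm = compare_groups(_dists_from_matrices(mats_a), _dists_from_matrices(mats_b))
        assert tm.raw_p[1, 4] == pytest.approx(oracle)

    def test_bh_adjustment_monotone_and_above_raw(self):
        rng = np.random.default_rng(2)
        mats_a = [rng.dirichlet(np.ones(25)).reshape(5, 5) * 100 for _ in range(8)]
        mats_b = [rng.dirichlet(np.ones(25)).reshape(5, 5) * 100 for _ in range(8)]
        tm = compare_groups(_dists_from_matrices(mats_a), _dists_from_matrices(mats_b))
        assert np.all(tm.adjusted_p >= tm.raw_p - 1e-12)
        order = np.argsort(tm.raw_p.ravel())
        assert np.all(np.diff(tm.adjusted_p.ravel()[order]) >= -1e-12)
        np.testing.assert_array_equal(tm.rejected, tm.adjusted_p <= tm.level)

    def test_constant_cell_in_both_groups_gets_p_one(self):
        mats_a = [np.full((5, 5), 4.0) for _ in range(3)]
        mats_b = [np.full((5, 5), 4.0) for _ in range(3)]
        for i, m in enumerate(mats_a):
            m[0, 0] = i + 1.0
        for i, m in enumerate(mats_b):
            m[0, 0] = i + 10.0
        tm = compare_groups(_dists_from_matrices(mats_a), _dists_from_matrices(mats_b))
        assert tm.raw_p[1, 1] == 1.0   # constant cell
        assert tm.raw_p[0, 0] < 0.2    # the varying cell

    def test_single_subject_group_rejected(self):
        mats = [np.full((5, 5), 4.0)]
        with pytest.raises(ParameterError):
            compare_groups(_dists_from_matrices(mats), _dists_from_matrices(mats))

    def test_shifted_cell_detected_with_off_cell_size_controlled(self):
        """8 vs 8 subjects, one cell shifted by a large amount: that cell
        must be detected frequently while every other cell's rejection rate
        stays within the FDR level (200 seeded simulations)."""
        target = (1, 4)
        hit = 0
        off = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            A = rng.normal(4.0, 1.0, size=(8, 5, 5))
            B = rng.normal(4.0, 1.0, size=(8, 5, 5))
            B[:, target[0], target[1]] += 10.0
            tm = compare_groups(_dists_from_matrices(A), _dists_from_matrices(B))
            hit += tm.rejected[target]
            off += tm.rejected.sum() - tm.rejected[target]
        assert hit / n_sims >= 0.9
        assert off / (n_sims * 24) <= 0.05

    def test_global_null_any_rejection_rate_controlled(self):
        """Both groups from the same Dirichlet, 8 vs 8: across replicates
        the fraction with any BH rejection stays near the FDR level."""
        n_reps = 300
        any_rej = 0
        rng = np.random.default_rng(12345)
        for _ in range(n_reps):
            A = [rng.dirichlet(np.ones(25)).reshape(5, 5) * 100 for _ in range(8)]
            B = [rng.dirichlet(np.ones(25)).reshape(5, 5) * 100 for _ in range(8)]
            tm = compare_groups(_dists_from_matrices(A), _dists_from_matrices(B))
            any_rej += tm.rejected.any()
        assert any_rej / n_reps <= 0.07
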