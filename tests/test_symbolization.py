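import numpy as np
import pytest

import plethysym as ps
from plethysym.clustering import znormalize
from plethysym.config import OUTLIER
from plethysym.errors import ParameterError
from plethysym.symbolization import (classify_sequences, compute_descriptors,
                                     fit_thresholds, symbolize)


class TestThresholds:
    def test_alpha_one_is_the_per_cluster_maximum(self, trio_fit):
        model = trio_fit["insp_model"]
        thr = fit_thresholds(model, 1.0)
        for label, dists in zip(model.labels, model.within_distances):
            assert thr.thresholds[label] == pytest.approx(float(np.max(dists)))

    def test_alpha_095_leaves_exactly_five_of_hundred_above(self):
        model = ps.ClusterModel(
            phase="inspiration", references=[np.zeros(5)], labels=["A"],
            assignments=np.zeros(100, dtype=int),
            mean_durations=np.array([0.1]),
            within_distances=[np.arange(1.0, 101.0)],
            radius_s=0.01, fs=250.0, seed=0)
        thr = fit_thresholds(model, 0.95)
        assert np.sum(np.arange(1.0, 101.0) > thr.thresholds["A"]) == 5

    def test_degenerate_distance_distribution(self):
        model = ps.ClusterModel(
            phase="expiration", references=[np.zeros(5)], labels=["0"],
            assignments=np.zeros(4, dtype=int), mean_durations=np.array([0.1]),
            within_distances=[np.full(4, 2.5)], radius_s=None, fs=1.0, seed=0)
        thr = fit_thresholds(model, 0.95)
        assert thr.thresholds["0"] == pytest.approx(2.5)

    def test_alpha_out_of_range_rejected(self, trio_fit):
        with pytest.raises(ParameterError):
            fit_thresholds(trio_fit["insp_model"], 0.0)
        with pytest.raises(ParameterError):
            fit_thresholds(trio_fit["insp_model"], 1.5)


class TestSymbolize:
    def test_training_members_keep_their_cluster_under_1nn(self, trio_fit):
        """1-NN against the final references must agree with the stored
        training assignment for every non-degenerate training sequence."""
        model = trio_fit["insp_model"]
        labels, _ = classify_sequences(model.train_sequences, model)
        expected = [model.labels[k] for k in model.assignments]
        agree = np.mean([a == b for a, b in zip(labels, expected)])
        assert agree == 1.0

    def test_pure_archetype_recording_gets_one_symbol_no_outliers(
            self, trio_fit, trio_archetypes, trio_noise_sd):
        cfg = trio_fit["cfg"]
        rec, _ = ps.generate_recording([trio_archetypes["A0"]] * 30,
                                       noise_sd=trio_noise_sd, warp_pct=0.2,
                                       seed=77)
        thr_i = fit_thresholds(trio_fit["insp_model"], 1.0)
        thr_e = fit_thresholds(trio_fit["exp_model"], 1.0)
        sym = symbolize(rec, trio_fit["insp_model"], trio_fit["exp_model"],
                        thr_i, thr_e, cfg)
        classified = sym.cycles[~sym.cycles["outlier"].astype(bool)]
        assert len(classified) >= 25
        assert classified["insp_symbol"].nunique() == 1
        assert classified["exp_symbol"].nunique() == 1

    def test_alien_shapes_are_all_outliers(self, trio_fit):
        """Square-pulse cycles far from every reference must be gated out."""
        cfg = trio_fit["cfg"]
        fs = cfg.fs
        cycle = np.concatenate([np.full(40, 1.0), np.full(40, -1.0)])
        # lead-in/out so the first/last boundaries are interior extrema
        samples = np.concatenate([np.full(40, -1.0)] + [cycle] * 20
                                 + [np.full(40, 1.0)])
        rec = ps.Recording(samples, fs, subject_id="alien")
        sym = symbolize(rec, trio_fit["insp_model"], trio_fit["exp_model"],
                        trio_fit["insp_thr"], trio_fit["exp_thr"], cfg)
        assert sym.n_cycles > 0
        assert sym.cycles["outlier"].astype(bool).all()

    def test_symbols_invariant_to_amplitude_scaling(self, trio_fit):
        cfg = trio_fit["cfg"]
        rec = trio_fit["recs"][0]
        scaled = ps.Recording(rec.samples * 3.0, rec.fs, rec.subject_id,
                              rec.group, rec.phase)
        # thresholds kept, prominence scaled with the signal so the same
        # cycles are detected
        import dataclasses
        cfg3 = dataclasses.replace(cfg, prominence=cfg.prominence * 3.0)
        s1 = symbolize(rec, trio_fit["insp_model"], trio_fit["exp_model"],
                       trio_fit["insp_thr"], trio_fit["exp_thr"], cfg)
        s2 = symbolize(scaled, trio_fit["insp_model"], trio_fit["exp_model"],
                       trio_fit["insp_thr"], trio_fit["exp_thr"], cfg3)
        assert list(s1.cycles["insp_symbol"]) == list(s2.cycles["insp_symbol"])
        assert list(s1.cycles["exp_symbol"]) == list(s2.cycles["exp_symbol"])

    def test_training_outlier_fraction_bounded(self, trio_fit):
        """At level alpha the per-cluster training outlier fraction is at
        most (1 - alpha) + 1/cluster-size."""
        for which in ("insp", "exp"):
            model = trio_fit[f"{which}_model"]
            thr = fit_thresholds(model, 0.95)
            labels, _ = classify_sequences(model.train_sequences, model, thr)
            for k, lab in enumerate(model.labels):
                members = np.flatnonzero(model.assignments == k)
                flagged = sum(labels[i] == OUTLIER for i in members)
                bound = 0.05 + 1.0 / len(members)
                assert flagged / len(members) <= bound + 1e-9

    def test_unsegmentable_recording_yields_empty_symbols(self, trio_fit):
        rec = ps.Recording(np.ones(500), 250.0, subject_id="flat")
        sym = symbolize(rec, trio_fit["insp_model"], trio_fit["exp_model"],
                        trio_fit["insp_thr"], trio_fit["exp_thr"],
                        trio_fit["cfg"])
        assert sym.n_cycles == 0

    def test_symbolic_csv_round_trip(self, trio_fit, tmp_path):
        cfg = trio_fit["cfg"]
        sym = symbolize(trio_fit["recs"][0], trio_fit["insp_model"],
                        trio_fit["exp_model"], trio_fit["insp_thr"],
                        trio_fit["exp_thr"], cfg)
        path = tmp_path / "sym.csv"
        sym.to_csv(path)
        back = ps.SymbolicRecording.from_csv(path)
        assert back.subject_id == sym.subject_id
        assert list(back.cycles["insp_symbol"]) == list(sym.cycles["insp_symbol"])
        np.testing.assert_allclose(back.cycles["t_in_s"], sym.cycles["t_in_s"])


class TestDescriptors:
    def test_half_sine_inspiration_volume(self):
        fs, A, T = 250.0, 2.0, 0.2
        n = int(T * fs)
        insp = A * np.sin(np.pi * (np.arange(n) + 0.5) / n)
        exp = -insp
        rec = ps.Recording(np.concatenate([insp, exp]), fs, subject_id="m1")
        seg = ps.CycleSegmentation([0], [n], [2 * n], fs)
        desc = compute_descriptors(rec, seg)
        assert desc["Ti"].iloc[0] == pytest.approx(T)
        assert desc["Te"].iloc[0] == pytest.approx(T)
        assert desc["NIV"].iloc[0] == pytest.approx(2 * A * T / np.pi, rel=1e-3)

    def test_symmetric_cycle_has_equal_volumes(self):
        fs = 250.0
        n = 50
        insp = np.sin(np.pi * (np.arange(n) + 0.5) / n)
        rec = ps.Recording(np.concatenate([insp, -insp]), fs, subject_id="m1")
        seg = ps.CycleSegmentation([0], [n], [2 * n], fs)
        desc = compute_descriptors(rec, seg)
        assert desc["NIV"].iloc[0] == pytest.approx(desc["NEV"].iloc[0])

    def test_duration_index_arithmetic(self):
        fs = 250.0
        rec = ps.Recording(np.ones(300), fs, subject_id="m1")
        seg = ps.CycleSegmentation([100], [150], [250], fs)
        desc = compute_descriptors(rec, seg)
        assert desc["Ti"].iloc[0] == pytest.approx(0.2)
        assert desc["Te"].iloc[0] == pytest.approx(0.4)
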