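"""Calcium-imaging chain: ΔF/F₀, drift, detection, QC and response metrics."""

import numpy as np
import pytest

from striatumkit import imaging, synthkit
from striatumkit.core import Trace
from striatumkit.imaging import EventList, QCReport, RoiRecord
from striatumkit.synthkit import SimConfig


class TestDff:
    def test_constant_fluorescence_maps_to_zero(self):
        tr = Trace(t0=0.0, dt=1 / 15, values=np.full(60, 100.0))
        dff = imaging.compute_dff(tr)
        assert np.allclose(dff.values, 0.0)

    def test_single_bright_sample(self):
        vals = np.full(60, 100.0)
        vals[45] = 150.0
        dff = imaging.compute_dff(Trace(t0=0.0, dt=1 / 15, values=vals))
        assert dff.values[45] == pytest.approx(0.5)

    def test_matches_explicit_loop(self, calcium_kernel):
        cfg = SimConfig(seed=3, noise_sd=0.005, duration=8.0)
        tr, _ = synthkit.simulate_roi_trace([2.0, 5.0], calcium_kernel, cfg)
        raw = Trace(t0=0.0, dt=tr.dt, values=100.0 * (1.0 + tr.values))
        dff = imaging.compute_dff(raw, window=2.0)
        w = int(round(2.0 / raw.dt))
        for i in range(raw.values.size):
            lo = max(0, i - w)
            f0 = raw.values[lo:i].mean() if i > lo else raw.values[i]
            assert dff.values[i] == pytest.approx((raw.values[i] - f0) / f0, abs=1e-12)

    def test_invariant_to_multiplicative_rescaling(self, calcium_kernel, quiet_cfg):
        tr, _ = synthkit.simulate_roi_trace([1.0], calcium_kernel, quiet_cfg)
        raw = 100.0 * (1.0 + tr.values)
        a = imaging.compute_dff(Trace(0.0, tr.dt, raw))
        b = imaging.compute_dff(Trace(0.0, tr.dt, 7.3 * raw))
        assert np.allclose(a.values, b.values)

    def test_rejects_nonpositive_fluorescence(self):
        with pytest.raises(ValueError):
            imaging.compute_dff(Trace(0.0, 0.1, np.array([1.0, -2.0, 3.0])))


class TestDriftCorrection:
    def test_identical_frames_give_zero_shifts(self, rng):
        f = rng.random((32, 32))
        shifts, corrected = imaging.correct_drift(np.stack([f, f, f]))
        assert np.all(shifts == 0)
        assert np.allclose(corrected, f)

    def test_recovers_known_translation(self, rng):
        ref = rng.random((48, 48))
        moved = np.roll(ref, (3, -2), axis=(0, 1))
        shifts, corrected = imaging.correct_drift(np.stack([ref, moved]))
        assert tuple(shifts[1]) == (-3, 2)
        assert np.allclose(corrected[1], ref)

    def test_bruteforce_shift_search_agrees(self, rng):
        ref = rng.random((24, 24))
        moved = np.roll(ref, (-4, 5), axis=(0, 1))
        best = None
        for dy in range(-8, 9):
            for dx in range(-8, 9):
                score = float(np.sum(ref * np.roll(moved, (dy, dx), axis=(0, 1))))
                if best is None or score > best[0]:
                    best = (score, dy, dx)
        shifts, _ = imaging.correct_drift(np.stack([ref, moved]))
        assert tuple(shifts[1]) == (best[1], best[2])

    def test_uniform_frames_tie_break_to_zero(self):
        shifts, _ = imaging.correct_drift(np.ones((3, 16, 16)))
        assert np.all(shifts == 0)


class TestDetection:
    def test_template_self_match_scores_one(self, calcium_kernel, quiet_cfg):
        tr, _ = synthkit.simulate_roi_trace([1.0], calcium_kernel, quiet_cfg)
        ev = imaging.detect_calcium_events(tr, calcium_kernel, stimulus_time=0.9)
        assert ev.event_times.size == 1
        assert ev.scores[0] == pytest.approx(1.0, abs=1e-9)
        assert ev.evoked[0]

    def test_lockout_suppresses_second_event(self, calcium_kernel, quiet_cfg):
        tr, _ = synthkit.simulate_roi_trace([1.0, 1.5], calcium_kernel, quiet_cfg)
        ev = imaging.detect_calcium_events(tr, calcium_kernel, stimulus_time=0.9)
        assert ev.event_times.size == 1
        # and for any input, no pair of events is closer than the lockout
        cfg = SimConfig(seed=1, noise_sd=0.02, duration=12.0)
        tr2, _ = synthkit.simulate_roi_trace([1.0, 2.5, 4.0, 8.0], calcium_kernel, cfg)
        ev2 = imaging.detect_calcium_events(tr2, calcium_kernel, stimulus_time=0.9)
        if ev2.event_times.size >= 2:
            assert np.all(np.diff(ev2.event_times) >= 1.0 - 1e-9)

    def test_detection_is_translation_equivariant(self, calcium_kernel):
        cfg = SimConfig(seed=5, noise_sd=0.0, duration=8.0)
        tr, _ = synthkit.simulate_roi_trace([2.0], calcium_kernel, cfg)
        shifted = Trace(t0=1.0, dt=tr.dt, values=tr.values)
        a = imaging.detect_calcium_events(tr, calcium_kernel, stimulus_time=1.9)
        b = imaging.detect_calcium_events(shifted, calcium_kernel, stimulus_time=2.9)
        assert np.allclose(b.event_times, a.event_times + 1.0)

    def test_recall_increases_with_snr(self, calcium_kernel):
        noise_sd = 0.01
        recalls = []
        for snr in (3.0, 5.0, 8.0):
            kernel = synthkit.make_calcium_kernel(0.05, 0.5, snr * noise_sd, 15.0)
            hits = total = 0
            for seed in range(60):
                cfg = SimConfig(seed=seed, noise_sd=noise_sd, duration=4.0)
                tr, truth = synthkit.simulate_roi_trace([1.2], kernel, cfg)
                ev = imaging.detect_calcium_events(tr, kernel, stimulus_time=1.0)
                total += 1
                hits += int(
                    any(abs(ev.event_times - 1.2) < 0.2) if ev.event_times.size else 0
                )
            recalls.append(hits / total)
        assert recalls[0] <= recalls[1] + 0.05
        assert recalls[1] <= recalls[2] + 0.02
        assert recalls[2] >= 0.95

    def test_template_longer_than_trace_rejected(self, calcium_kernel):
        short = Trace(t0=0.0, dt=1 / 15, values=np.zeros(5))
        with pytest.raises(ValueError):
            imaging.detect_calcium_events(short, calcium_kernel, stimulus_time=0.0)


def _roi_with_sd(sd, n=600, seed=0, cell_type="dSPN", roi_id="r"):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    vals = (vals - vals.mean()) / (vals.std() if sd > 0 else 1.0) * sd  # exact SD
    return RoiRecord(
        roi_id=roi_id,
        centroid=(0.0, 0.0),
        cell_type=cell_type,
        trials=[Trace(0.0, 1 / 15, vals)],
    )


def _events(n_evoked, n_nonevoked):
    times = np.sort(
        np.concatenate(
            [1.0 + 0.01 + 0.02 * np.arange(n_evoked), 3.0 + 1.1 * np.arange(n_nonevoked)]
        )
    )
    evoked = np.concatenate([np.ones(n_evoked, bool), np.zeros(n_nonevoked, bool)])
    order = np.argsort(
        np.concatenate([1.0 + 0.01 + 0.02 * np.arange(n_evoked), 3.0 + 1.1 * np.arange(n_nonevoked)])
    )
    return EventList(
        trial_id="t",
        stimulus_time=1.0,
        event_times=times,
        scores=np.full(times.size, 0.9),
        evoked=evoked[order],
    )


class TestQC:
    def test_noise_sd_at_ceiling_excludes(self):
        roi = _roi_with_sd(0.06)
        report = imaging.qc_roi(roi, [_events(1, 0)])
        assert not report.included and "noise_sd_exceeded" in report.reasons
        # just below the ceiling passes
        ok = imaging.qc_roi(_roi_with_sd(0.05), [_events(1, 0)])
        assert ok.included

    def test_unresponsive_at_suprathreshold_excludes(self):
        report = imaging.qc_roi(_roi_with_sd(0.01), [_events(0, 0)] * 10)
        assert "unresponsive_suprathreshold" in report.reasons

    def test_nonevoked_ratio_above_ceiling_excludes(self):
        report = imaging.qc_roi(_roi_with_sd(0.01), [_events(1, 5)])
        assert "nonevoked_ratio_exceeded" in report.reasons
        ok = imaging.qc_roi(_roi_with_sd(0.01), [_events(2, 9)])  # ratio 4.5 passes
        assert ok.included

    def test_qc_is_deterministic(self):
        roi = _roi_with_sd(0.01, seed=9)
        r1 = imaging.qc_roi(roi, [_events(1, 1)])
        r2 = imaging.qc_roi(roi, [_events(1, 1)])
        assert r1 == r2

    def test_slice_requires_twelve_of_each_subtype(self):
        def make(n_d, n_i, n_bad):
            rois = []
            for k in range(n_d):
                r = _roi_with_sd(0.01, seed=k, cell_type="dSPN", roi_id=f"d{k}")
                imaging.qc_roi(r, [_events(1, 0)])
                rois.append(r)
            for k in range(n_i):
                r = _roi_with_sd(0.01, seed=100 + k, cell_type="iSPN", roi_id=f"i{k}")
                imaging.qc_roi(r, [_events(1, 0)])
                rois.append(r)
            for k in range(n_bad):
                r = _roi_with_sd(0.08, seed=200 + k, cell_type="dSPN", roi_id=f"x{k}")
                imaging.qc_roi(r, [_events(1, 0)])
                rois.append(r)
            return rois

        assert not imaging.qc_slice(make(11, 20, 0))
        assert imaging.qc_slice(make(12, 12, 0))
        # excluded ROIs do not count: brute-force tally agrees
        rois = make(13, 12, 4)
        included_d = sum(
            1 for r in rois if r.qc.included and r.cell_type == "dSPN"
        )
        assert included_d == 13
        assert imaging.qc_slice(rois)


class TestResponseMetrics:
    def _make_roi(self, event_trials, kernel, cfg):
        trials, events = [], []
        for i, ets in enumerate(event_trials):
            tr, _ = synthkit.simulate_roi_trace(ets, kernel, cfg)
            trials.append(tr)
            events.append(
                imaging.detect_calcium_events(tr, kernel, stimulus_time=1.0, trial_id=str(i))
            )
        roi = RoiRecord("r0", (0, 0), "dSPN", trials)
        roi.qc = QCReport(included=True)
        return roi, events

    def test_spike_probability_counts_evoked_trials(self, calcium_kernel, quiet_cfg):
        plans = [[1.1]] * 6 + [[]] * 4
        roi, events = self._make_roi(plans, calcium_kernel, quiet_cfg)
        resp = imaging.response_metrics(roi, events, calcium_kernel)
        assert resp.spike_probability == pytest.approx(0.6)

    def test_amplitude_of_noiseless_kernel(self, calcium_kernel, quiet_cfg):
        roi, events = self._make_roi([[1.1]], calcium_kernel, quiet_cfg)
        resp = imaging.response_metrics(roi, events, calcium_kernel)
        assert resp.amplitude == pytest.approx(0.08, rel=1e-6)

    def test_latency_matches_exhaustive_scan(self, calcium_kernel, quiet_cfg):
        roi, events = self._make_roi([[1.1]], calcium_kernel, quiet_cfg)
        resp = imaging.response_metrics(roi, events, calcium_kernel)
        tr = roi.trials[0]
        scores = imaging.correlation_scores(tr, calcium_kernel)
        found = None
        for i in range(scores.size):
            t = tr.t0 + i * tr.dt
            if t > 1.0 and scores[i] >= 0.5:
                found = t - 1.0
                break
        assert found is not None
        assert resp.latency == pytest.approx(found, abs=1e-12)

    def test_no_responding_trial_flags_nan(self, calcium_kernel, quiet_cfg):
        roi, events = self._make_roi([[]], calcium_kernel, quiet_cfg)
        resp = imaging.response_metrics(roi, events, calcium_kernel)
        assert resp.spike_probability == 0.0
        assert np.isnan(resp.amplitude) and np.isnan(resp.latency)


class TestPathwayTiming:
    def _cells(self, latencies, cell_type):
        return [
            imaging.CellResponse(f"{cell_type}{i}", cell_type, 1.0, 0.08, lat)
            for i, lat in enumerate(latencies)
        ]

    def test_constant_latency_offsets(self):
        d = self._cells([0.150] * 8, "dSPN")
        i = self._cells([0.130] * 8, "iSPN")
        diffs = imaging.pathway_timing(d, i, seed=0)
        assert np.allclose(diffs, 0.020)

    def test_identical_latency_sets_give_zero_mean(self):
        lat = [0.1, 0.12, 0.14, 0.16]
        diffs = imaging.pathway_timing(self._cells(lat, "dSPN"), self._cells(lat, "iSPN"), seed=3)
        # mean difference equals difference of means for any full pairing
        assert np.mean(diffs) == pytest.approx(0.0, abs=1e-15)

    def test_mean_difference_equals_difference_of_means(self, rng):
        d_lat = rng.uniform(0.1, 0.2, 10)
        i_lat = rng.uniform(0.1, 0.2, 10)
        diffs = imaging.pathway_timing(
            self._cells(d_lat, "dSPN"), self._cells(i_lat, "iSPN"), seed=5
        )
        assert np.mean(diffs) == pytest.approx(np.mean(d_lat) - np.mean(i_lat), abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            imaging.pathway_timing([], self._cells([0.1], "iSPN"), seed=0)
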