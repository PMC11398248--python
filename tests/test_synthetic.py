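import filecmp
from pathlib import Path

import numpy as np
import pytest

from drivestress.arousal import arousal_trace
from drivestress.hrv import compute_rmssd, mean_hr, rmssd_by_epoch
from drivestress.protocol import slice_by_epoch
from drivestress.synthetic import (
    HrvScenario,
    ThermalScenario,
    default_hrv_scenario,
    generate_rr,
    generate_thermal,
    write_session,
)
from drivestress.thermal import GroundTruthDetector, epoch_average, process_frames


class TestGenerateRr:
    def test_degenerate_noise_gives_constant_series(self, simulated_protocol):
        series = generate_rr(simulated_protocol, HrvScenario(baseline_rmssd=0.0, seed=0))
        assert np.all(series.rr == 800.0)
        assert compute_rmssd(series.rr) == 0.0

    def test_tick_schedule(self, simulated_protocol):
        series = generate_rr(simulated_protocol, HrvScenario(seed=0))
        assert len(series) == 21000  # 840 s at one sample per 40 ms
        assert np.allclose(np.diff(series.timestamps), 0.04)

    def test_rmssd_calibration(self, simulated_protocol):
        # sigma = target/sqrt(2) makes the expected RMSSD equal the target
        series = generate_rr(simulated_protocol, HrvScenario(baseline_rmssd=50.0, seed=8))
        mapping, _ = slice_by_epoch(series.timestamps, simulated_protocol)
        rr = series.rr[mapping["Baseline"]]
        assert rr.size == 3000
        assert compute_rmssd(rr) == pytest.approx(50.0, rel=0.05)

    def test_mean_hr_matches_mean_rr(self, simulated_protocol):
        series = generate_rr(simulated_protocol, HrvScenario(mean_rr=800.0, seed=1))
        assert mean_hr(series.rr) == pytest.approx(75.0, rel=0.01)

    def test_determinism(self, simulated_protocol):
        a = generate_rr(simulated_protocol, HrvScenario(seed=13))
        b = generate_rr(simulated_protocol, HrvScenario(seed=13))
        assert np.array_equal(a.rr, b.rr)

    def test_default_scenario_drops_by_kind(self, simulated_protocol):
        sc = default_hrv_scenario(simulated_protocol, seed=0)
        assert sc.rmssd_factor["CD"] == 0.5
        assert sc.rmssd_factor["BD"] == 0.85
        assert "Recovery" not in sc.rmssd_factor  # back to baseline level


class TestGenerateThermal:
    def test_frame_count_and_schedule(self, simulated_protocol):
        frames = generate_thermal(simulated_protocol, ThermalScenario(seed=0))
        assert len(frames) == 168
        assert frames[0].frame.timestamp == 0.0
        assert frames[-1].frame.timestamp == 835.0

    def test_anchor_coordinates_match_extrema(self, simulated_protocol):
        sf = generate_thermal(simulated_protocol, ThermalScenario(seed=2))[0]
        cx, cy = sf.frame.cold_xy
        hx, hy = sf.frame.hot_xy
        assert sf.field.temps[cy, cx] == sf.field.temps.min() == sf.frame.t_cold
        assert sf.field.temps[hy, hx] == sf.field.temps.max() == sf.frame.t_hot

    def test_nose_box_in_valid_band(self, simulated_protocol):
        from drivestress.thermal import validate_nose_roi

        sf = generate_thermal(simulated_protocol, ThermalScenario(seed=2))[0]
        assert validate_nose_roi(sf.nose_roi, sf.face_roi)

    def test_dropout_fraction(self, simulated_protocol):
        frames = generate_thermal(
            simulated_protocol, ThermalScenario(seed=5, dropout_rate=0.25)
        )
        n_drop = sum(1 for f in frames if f.face_roi is None)
        assert 0 < n_drop < len(frames)
        assert n_drop / len(frames) == pytest.approx(0.25, abs=0.12)

    def test_null_scenario_flat_nose_norm(self, simulated_protocol):
        frames = generate_thermal(
            simulated_protocol, ThermalScenario(stress_drop=0.0, seed=6)
        )
        det = GroundTruthDetector(
            {f.frame.timestamp: (f.face_roi, f.nose_roi) for f in frames}
        )
        avg = epoch_average(
            process_frames([f.frame for f in frames], det), simulated_protocol
        )
        vals = [avg[e]["nose_norm"] for e in avg]
        assert max(vals) - min(vals) < 0.01

    def test_stress_drop_lowers_stressor_nose_norm(self, simulated_protocol):
        frames = generate_thermal(
            simulated_protocol, ThermalScenario(stress_drop=1.5, seed=7)
        )
        det = GroundTruthDetector(
            {f.frame.timestamp: (f.face_roi, f.nose_roi) for f in frames}
        )
        avg = epoch_average(
            process_frames([f.frame for f in frames], det), simulated_protocol
        )
        for name in ("CD", "VD", "E", "E+VD"):
            assert avg[name]["nose_norm"] < avg["Baseline"]["nose_norm"]

    def test_decoded_epoch_means_match_ground_truth(self, simulated_protocol):
        # decoded nose means agree with the generator's exact fields to
        # within colormap quantization plus noise standard error
        sc = ThermalScenario(seed=9)
        frames = generate_thermal(simulated_protocol, sc)
        det = GroundTruthDetector(
            {f.frame.timestamp: (f.face_roi, f.nose_roi) for f in frames}
        )
        temps = process_frames([f.frame for f in frames], det)
        for sf, ft in zip(frames, temps):
            nose = sf.nose_roi
            truth = sf.field.temps[
                nose.y0 : nose.y0 + nose.height, nose.x0 : nose.x0 + nose.width
            ].mean()
            step = (sf.frame.t_hot - sf.frame.t_cold) / 255
            assert abs(ft.nose_mean - truth) <= step


class TestWriteSession:
    def test_outputs_present(self, synthetic_session_dir):
        assert (synthetic_session_dir / "rr.csv").exists()
        assert (synthetic_session_dir / "manifest.json").exists()
        pngs = list((synthetic_session_dir / "frames").glob("*.png"))
        sidecars = list((synthetic_session_dir / "frames").glob("*.json"))
        assert len(pngs) == 168 and len(sidecars) == 168

    def test_identical_seeds_byte_identical(self, tmp_path, simulated_protocol):
        hs = HrvScenario(seed=33)
        ts = ThermalScenario(seed=34, dropout_rate=0.1)
        a, b = tmp_path / "a", tmp_path / "b"
        write_session(a, simulated_protocol, hs, ts)
        write_session(b, simulated_protocol, hs, ts)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files == sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        for rel in files:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel

    def test_manifest_replays_through_detector(self, synthetic_session_dir, simulated_protocol):
        from drivestress.thermal import read_frames

        det = GroundTruthDetector.from_manifest(synthetic_session_dir / "manifest.json")
        frames = read_frames(synthetic_session_dir / "frames")
        temps = process_frames(frames, det)
        defined = [t for t in temps if t.nose_norm is not None]
        assert len(defined) > 0.8 * len(temps)  # only dropouts missing


class TestEndToEndRecovery:
    def test_half_rmssd_epoch_maps_to_phi_04(self, simulated_protocol):
        # ratio 50 -> bin ceil(40/11)=4 -> phi-hat 0.4, across seeds
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            scenario = HrvScenario(rmssd_factor={"CD": 0.5}, seed=seed)
            series = generate_rr(simulated_protocol, scenario)
            trace = arousal_trace(series, simulated_protocol)
            if abs(trace.per_epoch_mean["CD"] - 0.4) <= 0.1:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_report_ranks_cd_highest(self, simulated_protocol):
        scenario = HrvScenario(rmssd_factor={"CD": 0.5, "BD": 0.9}, seed=17)
        series = generate_rr(simulated_protocol, scenario)
        trace = arousal_trace(series, simulated_protocol)
        rmssd = {r.epoch_name: r.rmssd for r in rmssd_by_epoch(series, simulated_protocol)}
        non_base = [ep.name for ep in simulated_protocol.non_baseline()]
        assert max(non_base, key=lambda n: trace.per_epoch_mean[n]) == "CD"
        assert min(non_base, key=lambda n: rmssd[n]) == "CD"
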