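"""Protocol-driven synthetic sessions: R-R streams and thermal frames.

Replaces the wearable ECG belt and the thermal camera so that every stage
of the pipeline can be exercised end to end with known ground truth.

R-R generator — one sample per 40-ms tick; within each epoch the
intervals are ``mean_rr + ε`` with ε i.i.d. Gaussian of standard deviation
σ = target_rmssd/√2, where target_rmssd = baseline_rmssd · factor(epoch).
Since E[(RR_n − RR_{n−1})²] = 2σ², the expected RMSSD equals the target
exactly; stressor epochs use factors < 1 to emulate the vagal-withdrawal
RMSSD drop seen under driving stress.

Thermal generator — one frame per 5 s; a warm face rectangle with a nose
rectangle (placed inside the anatomically valid band of the face box) over
a cool cabin background, plus Gaussian pixel noise. Nasal-tip cooling under
stress is emulated by lowering the nose temperature during stressor epochs.
Each field is encoded through a temperature-bar colormap, with the per-frame
cold/hot anchors set to the field extrema as an auto-ranging camera would;
a configurable fraction of frames are detection dropouts with no
ground-truth boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

from .hrv import DEFAULT_TICK_MS, RRSeries, write_rr_csv
from .protocol import DrivingProtocol
from .thermal import Roi, TemperatureField, ThermalFrame, grayscale_colormap

__all__ = [
    "HrvScenario",
    "ThermalScenario",
    "SyntheticFrame",
    "default_hrv_scenario",
    "generate_rr",
    "generate_thermal",
    "encode_temperature",
    "write_session",
]


@dataclass(frozen=True)
class HrvScenario:
    """Controlled per-epoch RMSSD for the R-R generator.

    ``rmssd_factor`` maps epoch names to multiplicative factors applied to
    ``baseline_rmssd``; unlisted epochs use factor 1. Defaults describe a
    healthy adult at rest (75 bpm, 50 ms RMSSD).
    """

    mean_rr: float = 800.0
    baseline_rmssd: float = 50.0
    rmssd_factor: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be > 0")
        if self.baseline_rmssd < 0:
            raise ValueError("baseline_rmssd must be >= 0")
        if any(f <= 0 for f in self.rmssd_factor.values()):
            raise ValueError("rmssd factors must be > 0")

    def target_rmssd(self, epoch_name: str) -> float:
        return self.baseline_rmssd * float(self.rmssd_factor.get(epoch_name, 1.0))


def default_hrv_scenario(protocol: DrivingProtocol, seed: int = 0) -> HrvScenario:
    """Scenario with stress-typical RMSSD drops assigned by epoch kind.

    Stressor epochs drop to 50% of baseline RMSSD (a strong activation),
    plain driving to 85% (mild workload); recovery returns to baseline.
    """
    factors = {}
    for ep in protocol.epochs:
        if ep.kind == "stressor":
            factors[ep.name] = 0.5
        elif ep.kind == "driving":
            factors[ep.name] = 0.85
    return HrvScenario(rmssd_factor=factors, seed=seed)


@dataclass(frozen=True)
class ThermalScenario:
    """Scene parameters for the thermal frame generator (°C, seconds)."""

    face_base_temp: float = 34.0
    nose_base_temp: float = 33.0
    background_temp: float = 22.0
    stress_drop: float = 1.5
    frame_period: float = 5.0
    noise_sd: float = 0.15
    frame_shape: tuple[int, int] = (60, 80)  # (H, W)
    colormap: np.ndarray = field(default_factory=grayscale_colormap)
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "colormap", np.asarray(self.colormap, dtype=np.uint8))
        if self.background_temp >= min(self.face_base_temp, self.nose_base_temp):
            raise ValueError("background must be colder than face and nose")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticFrame:
    """A generated frame with its ground truth.

    ``face_roi``/``nose_roi`` are None on dropout frames (simulated
    detection failures); ``field`` is the exact pre-encoding temperature
    field, kept for round-trip checks.
    """

    frame: ThermalFrame
    face_roi: Roi | None
    nose_roi: Roi | None
    field: TemperatureField


def generate_rr(protocol: DrivingProtocol, scenario: HrvScenario) -> RRSeries:
    """Synthesize one R-R sample per 40-ms tick over the whole protocol.

    Deterministic for a fixed scenario seed. Intervals are clipped at
    1 ms to respect the positivity invariant (never triggered with
    physiological parameter values).
    """
    rng = np.random.default_rng(scenario.seed)
    tick_s = DEFAULT_TICK_MS / 1000.0
    n_total = int(round(protocol.total_duration / tick_s))
    timestamps = np.arange(n_total) * tick_s
    rr = np.full(n_total, scenario.mean_rr, dtype=float)
    for ep in protocol.epochs:
        mask = (timestamps >= ep.start) & (timestamps < ep.end)
        sigma = scenario.target_rmssd(ep.name) / np.sqrt(2.0)
        if sigma > 0:
            rr[mask] += rng.normal(0.0, sigma, size=int(mask.sum()))
    np.clip(rr, 1.0, None, out=rr)
    return RRSeries(timestamps=timestamps, rr=rr)


def _scene_geometry(shape: tuple[int, int]) -> tuple[Roi, Roi]:
    """Face and nose boxes for a frame of the given (H, W)."""
    h, w = shape
    face = Roi(x0=round(w * 0.30), y0=round(h * 0.20),
               width=round(w * 0.40), height=round(h * 0.60))
    # nose top at 55% of face height: inside the (25%, 80%) valid band
    nose_w = max(2, round(face.width * 0.25))
    nose_h = max(2, round(face.height * 0.18))
    nose = Roi(
        x0=face.x0 + (face.width - nose_w) // 2,
        y0=face.y0 + round(face.height * 0.55),
        width=nose_w,
        height=nose_h,
    )
    return face, nose


def encode_temperature(
    field: TemperatureField, colormap: np.ndarray
) -> tuple[np.ndarray, float, float, tuple[int, int], tuple[int, int]]:
    """Render a temperature field through a temperature bar.

    Anchors t_cold/t_hot are the field extrema (camera auto-ranging);
    each pixel becomes the colormap entry nearest its normalized
    temperature. Returns (rgb, t_cold, t_hot, cold_xy, hot_xy).
    """
    t = field.temps
    t_cold, t_hot = float(t.min()), float(t.max())
    if t_cold >= t_hot:
        raise ValueError("temperature field is constant; cannot auto-range")
    levels = colormap.shape[0]
    idx = np.round((t - t_cold) / (t_hot - t_cold) * (levels - 1)).astype(int)
    rgb = np.asarray(colormap, dtype=np.uint8)[idx]
    cy, cx = np.unravel_index(int(np.argmin(t)), t.shape)
    hy, hx = np.unravel_index(int(np.argmax(t)), t.shape)
    return rgb, t_cold, t_hot, (int(cx), int(cy)), (int(hx), int(hy))


def generate_thermal(
    protocol: DrivingProtocol, scenario: ThermalScenario
) -> list[SyntheticFrame]:
    """Synthesize one colormap-encoded frame per ``frame_period`` seconds.

    The nose rectangle cools by ``stress_drop`` °C during stressor epochs;
    a ``dropout_rate`` fraction of frames carry no ground-truth boxes,
    emulating detection failures. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(scenario.seed)
    face, nose = _scene_geometry(scenario.frame_shape)
    times = np.arange(0.0, protocol.total_duration, scenario.frame_period)
    frames: list[SyntheticFrame] = []
    for t in times:
        ep = protocol.epoch_of(float(t))
        stressed = ep is not None and ep.stressor
        temps = np.full(scenario.frame_shape, scenario.background_temp, dtype=float)
        temps[face.y0 : face.y0 + face.height, face.x0 : face.x0 + face.width] = (
            scenario.face_base_temp
        )
        nose_t = scenario.nose_base_temp - (scenario.stress_drop if stressed else 0.0)
        temps[nose.y0 : nose.y0 + nose.height, nose.x0 : nose.x0 + nose.width] = nose_t
        if scenario.noise_sd > 0:
            temps += rng.normal(0.0, scenario.noise_sd, size=temps.shape)
        fld = TemperatureField(temps)
        rgb, t_cold, t_hot, cold_xy, hot_xy = encode_temperature(fld, scenario.colormap)
        dropout = bool(rng.random() < scenario.dropout_rate)
        frames.append(
            SyntheticFrame(
                frame=ThermalFrame(
                    rgb=rgb,
                    colormap=scenario.colormap,
                    t_cold=t_cold,
                    t_hot=t_hot,
                    cold_xy=cold_xy,
                    hot_xy=hot_xy,
                    timestamp=float(t),
                ),
                face_roi=None if dropout else face,
                nose_roi=None if dropout else nose,
                field=fld,
            )
        )
    return frames


def _roi_dict(roi: Roi | None) -> dict | None:
    if roi is None:
        return None
    return {"x0": roi.x0, "y0": roi.y0, "width": roi.width, "height": roi.height}


def write_session(
    out_dir: str | Path,
    protocol: DrivingProtocol,
    hrv_scenario: HrvScenario,
    thermal_scenario: ThermalScenario | None = None,
) -> dict:
    """Write a full synthetic session to disk.

    Produces ``rr.csv``, a ``frames/`` directory of PNGs with JSON
    sidecars (when a thermal scenario is given), and ``manifest.json``
    holding the ground-truth boxes and scenario parameters. Output is
    byte-identical across runs with identical seeds. Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = generate_rr(protocol, hrv_scenario)
    write_rr_csv(series, str(out / "rr.csv"))
    manifest: dict = {
        "protocol": protocol.name,
        "hrv_scenario": {
            "mean_rr": hrv_scenario.mean_rr,
            "baseline_rmssd": hrv_scenario.baseline_rmssd,
            "rmssd_factor": dict(hrv_scenario.rmssd_factor),
            "seed": hrv_scenario.seed,
        },
        "frames": [],
    }
    if thermal_scenario is not None:
        frames_dir = out / "frames"
        frames_dir.mkdir(exist_ok=True)
        for i, sf in enumerate(generate_thermal(protocol, thermal_scenario)):
            stem = frames_dir / f"frame_{i:05d}"
            Image.fromarray(sf.frame.rgb, mode="RGB").save(str(stem) + ".png")
            sidecar = {
                "timestamp_s": sf.frame.timestamp,
                "t_cold_c": round(sf.frame.t_cold, 6),
                "t_hot_c": round(sf.frame.t_hot, 6),
                "cold_xy": list(sf.frame.cold_xy),
                "hot_xy": list(sf.frame.hot_xy),
                "colormap": np.asarray(sf.frame.colormap).tolist(),
            }
            with open(str(stem) + ".json", "w", encoding="utf-8", newline="\n") as fh:
                json.dump(sidecar, fh, sort_keys=True)
                fh.write("\n")
            manifest["frames"].append(
                {
                    "timestamp_s": sf.frame.timestamp,
                    "face_roi": _roi_dict(sf.face_roi),
                    "nose_roi": _roi_dict(sf.nose_roi),
                }
            )
        manifest["thermal_scenario"] = {
            "face_base_temp": thermal_scenario.face_base_temp,
            "nose_base_temp": thermal_scenario.nose_base_temp,
            "background_temp": thermal_scenario.background_temp,
            "stress_drop": thermal_scenario.stress_drop,
            "frame_period": thermal_scenario.frame_period,
            "noise_sd": thermal_scenario.noise_sd,
            "dropout_rate": thermal_scenario.dropout_rate,
            "seed": thermal_scenario.seed,
        }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest
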