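"""Thermal facial imaging: temperature restoration and ROI analysis.

Consumer thermal cameras export color-mapped RGB frames rather than
radiometric data, alongside the coldest/hottest temperatures in the frame
and their pixel coordinates. Per-pixel temperatures are restored by
inverting the color map: each pixel is indexed against the temperature
bar (nearest color), the index is normalized to [0, 1], and the affine map

    t = t_cold + (t_hot − t_cold) · index

recovers °C. Face and nose rectangular ROIs (from a pluggable detector)
are scored by their mean temperature; a nose ROI is discarded when its
top-left corner sits above 80% or below 25% of the face-box height, a
cheap guard against mis-detections. ROI means are normalized by the
whole-frame mean temperature and averaged per protocol epoch. Failed
detections propagate as missing values — gaps, not zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from PIL import Image

from .protocol import DrivingProtocol

__all__ = [
    "ThermalFrame",
    "TemperatureField",
    "Roi",
    "FrameTemps",
    "RoiDetector",
    "GroundTruthDetector",
    "ExternalDetector",
    "grayscale_colormap",
    "iron_colormap",
    "get_colormap",
    "index_image",
    "restore_temperature",
    "roi_mean",
    "validate_nose_roi",
    "detect_rois",
    "normalize_by_frame",
    "process_frame",
    "process_frames",
    "epoch_average",
    "read_frames",
    "write_frame_temps_csv",
]


# ---------------------------------------------------------------------------
# colormaps (temperature bars)

def grayscale_colormap(levels: int = 256) -> np.ndarray:
    """Linear grayscale temperature bar: (levels, 3) uint8, cold → hot."""
    g = np.round(np.linspace(0, 255, levels)).astype(np.uint8)
    return np.stack([g, g, g], axis=1)


def iron_colormap(levels: int = 256) -> np.ndarray:
    """Iron-like thermal palette (black → purple → red → yellow → white)."""
    anchors = np.array(
        [
            [0, 0, 0],
            [32, 0, 64],
            [96, 0, 128],
            [160, 16, 96],
            [208, 64, 16],
            [240, 128, 0],
            [255, 192, 32],
            [255, 255, 255],
        ],
        dtype=float,
    )
    x = np.linspace(0, 1, len(anchors))
    xi = np.linspace(0, 1, levels)
    rgb = np.stack([np.interp(xi, x, anchors[:, c]) for c in range(3)], axis=1)
    return np.round(rgb).astype(np.uint8)


_COLORMAPS = {
    "grayscale256": grayscale_colormap,
    "iron256": iron_colormap,
}


def get_colormap(colormap_id: str) -> np.ndarray:
    """Resolve a named temperature bar (``grayscale256``, ``iron256``)."""
    try:
        return _COLORMAPS[colormap_id]()
    except KeyError:
        raise ValueError(
            f"unknown colormap {colormap_id!r}; available: {sorted(_COLORMAPS)}"
        ) from None


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ThermalFrame:
    """One color-mapped thermal frame with its calibration sidecar.

    ``t_cold``/``t_hot`` are the coldest/hottest temperatures the camera
    saw in this frame (°C); ``cold_xy``/``hot_xy`` their (x, y) pixel
    coordinates. The colormap is the temperature bar the frame was
    rendered with, cold first.
    """

    rgb: np.ndarray
    colormap: np.ndarray
    t_cold: float
    t_hot: float
    cold_xy: tuple[int, int]
    hot_xy: tuple[int, int]
    timestamp: float

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        cmap = np.asarray(self.colormap)
        object.__setattr__(self, "rgb", rgb)
        object.__setattr__(self, "colormap", cmap)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError("rgb must be an H x W x 3 matrix")
        if cmap.ndim != 2 or cmap.shape[1] != 3 or cmap.shape[0] < 2:
            raise ValueError("colormap must be an L x 3 matrix with L >= 2")
        if not self.t_cold < self.t_hot:
            raise ValueError("t_cold must be < t_hot")
        h, w = rgb.shape[:2]
        for name, (x, y) in (("cold_xy", self.cold_xy), ("hot_xy", self.hot_xy)):
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"{name} {(x, y)} outside {w}x{h} frame")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass(frozen=True)
class TemperatureField:
    """H x W matrix of restored per-pixel temperatures in °C."""

    temps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "temps", t)
        if t.ndim != 2:
            raise ValueError("temps must be a 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps.shape

    def mean(self) -> float:
        """Whole-frame mean temperature, °C."""
        return float(self.temps.mean())


@dataclass(frozen=True)
class Roi:
    """Rectangular pixel box: 0-based, origin top-left, y downward.

    The box is half-open: it covers columns [x0, x0+width) and rows
    [y0, y0+height).
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("Roi width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("Roi origin must be non-negative")

    def within(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return self.x0 + self.width <= w and self.y0 + self.height <= h


@dataclass(frozen=True)
class FrameTemps:
    """Per-frame ROI temperatures; None marks a missing quantity."""

    timestamp: float
    face_mean: float | None
    nose_mean: float | None
    frame_mean: float | None
    face_norm: float | None
    nose_norm: float | None


# ---------------------------------------------------------------------------
# decoding

def index_image(rgb: np.ndarray, colormap: np.ndarray) -> np.ndarray:
    """Map each pixel to its normalized colormap index in [0, 1].

    Every pixel is matched to the nearest colormap entry in RGB space
    (Euclidean distance; ties break toward the lower, colder index) and
    the integer index is divided by L−1.
    """
    rgb = np.asarray(rgb, dtype=float)
    cmap = np.asarray(colormap, dtype=float)
    if cmap.ndim != 2 or cmap.shape[1] != 3 or cmap.shape[0] < 2:
        raise ValueError("colormap must be an L x 3 matrix with L >= 2")
    h, w = rgb.shape[:2]
    flat = rgb.reshape(-1, 3)
    idx = np.empty(flat.shape[0], dtype=np.intp)
    # chunk rows so the (pixels x L) distance matrix stays small
    chunk = max(1, 2_000_000 // cmap.shape[0])
    for lo in range(0, flat.shape[0], chunk):
        d2 = ((flat[lo : lo + chunk, None, :] - cmap[None, :, :]) ** 2).sum(axis=2)
        idx[lo : lo + chunk] = np.argmin(d2, axis=1)  # argmin: first == lowest
    return (idx / (cmap.shape[0] - 1)).reshape(h, w)


def restore_temperature(
    index: np.ndarray, t_cold: float, t_hot: float
) -> TemperatureField:
    """Affine map from normalized indices to °C: t_cold + (t_hot−t_cold)·i."""
    if not t_cold < t_hot:
        raise ValueError("t_cold must be < t_hot")
    idx = np.asarray(index, dtype=float)
    if idx.size and (idx.min() < 0 or idx.max() > 1):
        raise ValueError("indices must lie in [0, 1]")
    return TemperatureField(t_cold + (t_hot - t_cold) * idx)


def decode_frame(frame: ThermalFrame) -> TemperatureField:
    """Restore the full temperature field of one frame."""
    return restore_temperature(
        index_image(frame.rgb, frame.colormap), frame.t_cold, frame.t_hot
    )


# ---------------------------------------------------------------------------
# ROI scoring

def roi_mean(field: TemperatureField, roi: Roi) -> float:
    """Arithmetic mean temperature over the ROI's W·H pixels, °C."""
    if not roi.within(field.shape):
        raise ValueError(
            f"roi {roi} exceeds field bounds {field.shape[1]}x{field.shape[0]}"
        )
    patch = field.temps[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return float(patch.mean())


def validate_nose_roi(nose: Roi, face: Roi) -> bool:
    """Plausibility check for a detected nose box.

    With y_rel the nose top-left row relative to the face top, the nose is
    rejected iff y_rel < 0.25·H_face or y_rel > 0.8·H_face (strict
    inequalities): an anatomically placed nose starts in the middle band
    of the face.
    """
    y_rel = nose.y0 - face.y0
    return not (y_rel < 0.25 * face.height or y_rel > 0.8 * face.height)


# ---------------------------------------------------------------------------
# detectors

class RoiDetector(Protocol):
    """Pluggable face/nose detector interface."""

    def detect(self, frame: ThermalFrame) -> tuple[Roi | None, Roi | None]:
        """Return (face, nose) ROIs in frame coordinates; None when absent."""
        ...


class GroundTruthDetector:
    """Detector backend that replays recorded ground-truth boxes.

    Built from a manifest mapping frame timestamps to boxes, as written by
    the synthetic session generator; frames absent from the manifest (or
    recorded as dropouts) yield missing ROIs.
    """

    def __init__(self, boxes: dict[float, tuple[Roi | None, Roi | None]]) -> None:
        self._boxes = dict(boxes)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "GroundTruthDetector":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        boxes: dict[float, tuple[Roi | None, Roi | None]] = {}
        for rec in doc["frames"]:
            face = Roi(**rec["face_roi"]) if rec.get("face_roi") else None
            nose = Roi(**rec["nose_roi"]) if rec.get("nose_roi") else None
            boxes[float(rec["timestamp_s"])] = (face, nose)
        return cls(boxes)

    def detect(self, frame: ThermalFrame) -> tuple[Roi | None, Roi | None]:
        return self._boxes.get(frame.timestamp, (None, None))


class ExternalDetector:
    """Adapter hook for an external face-landmark detector backend.

    The backend must expose ``detect(rgb) -> (face_box, nose_box)`` with
    boxes as (x0, y0, width, height) tuples or None.
    """

    def __init__(self, backend) -> None:
        if backend is None or not hasattr(backend, "detect"):
            raise ValueError(
                "ExternalDetector requires a backend object with a "
                "detect(rgb) method returning (face, nose) boxes"
            )
        self._backend = backend

    def detect(self, frame: ThermalFrame) -> tuple[Roi | None, Roi | None]:
        out = self._backend.detect(frame.rgb)
        face_box, nose_box = out if out is not None else (None, None)
        face = Roi(*map(int, face_box)) if face_box is not None else None
        nose = Roi(*map(int, nose_box)) if nose_box is not None else None
        return face, nose


def detect_rois(
    frame: ThermalFrame, detector: RoiDetector
) -> tuple[Roi | None, Roi | None]:
    """Run the detector on one frame; failures yield missing ROIs, never raise."""
    try:
        face, nose = detector.detect(frame)
    except Exception:
        return None, None
    if face is not None and not face.within(frame.shape):
        face = None
    if nose is not None and not nose.within(frame.shape):
        nose = None
    return face, nose


# ---------------------------------------------------------------------------
# normalization and epoch aggregation

def normalize_by_frame(value: float | None, frame_mean: float | None) -> float | None:
    """Ratio of an ROI mean to the whole-frame mean temperature.

    Missing inputs propagate; a non-positive frame mean (°C scale near
    zero) makes the ratio meaningless, so it is marked missing too.
    """
    if value is None or frame_mean is None:
        return None
    if frame_mean <= 0:
        return None
    return float(value) / float(frame_mean)


def process_frame(frame: ThermalFrame, detector: RoiDetector) -> FrameTemps:
    """Decode one frame and score its face/nose ROIs.

    A nose box failing the face-relative height check is dropped (its
    quantities become missing); the face mean is kept regardless.
    """
    field = decode_frame(frame)
    frame_mean = field.mean()
    face, nose = detect_rois(frame, detector)
    if face is not None and nose is not None and not validate_nose_roi(nose, face):
        nose = None
    face_mean = roi_mean(field, face) if face is not None else None
    nose_mean = roi_mean(field, nose) if nose is not None else None
    return FrameTemps(
        timestamp=frame.timestamp,
        face_mean=face_mean,
        nose_mean=nose_mean,
        frame_mean=frame_mean,
        face_norm=normalize_by_frame(face_mean, frame_mean),
        nose_norm=normalize_by_frame(nose_mean, frame_mean),
    )


def process_frames(
    frames: Sequence[ThermalFrame], detector: RoiDetector
) -> list[FrameTemps]:
    """Score a frame sequence; order is preserved."""
    return [process_frame(f, detector) for f in frames]


def epoch_average(
    frames: Sequence[FrameTemps], protocol: DrivingProtocol
) -> dict[str, dict[str, float | int | None]]:
    """Per-epoch temporal averages of the normalized ROI temperatures.

    For each protocol epoch, the mean of ``face_norm``/``nose_norm`` (and
    the raw °C means) is taken over the frames whose timestamps fall in
    the epoch and whose value is defined; an epoch with no defined frames
    is marked missing (None). Frames past the protocol end are ignored.
    """
    out: dict[str, dict[str, float | int | None]] = {}
    for ep in protocol.epochs:
        in_ep = [f for f in frames if ep.contains(f.timestamp)]
        rec: dict[str, float | int | None] = {"n_frames": len(in_ep)}
        for key in ("face_norm", "nose_norm", "face_mean", "nose_mean"):
            vals = [getattr(f, key) for f in in_ep if getattr(f, key) is not None]
            rec[key] = float(np.mean(vals)) if vals else None
        out[ep.name] = rec
    return out


# ---------------------------------------------------------------------------
# frame I/O: one PNG per frame + JSON sidecar

def _load_sidecar(path: Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def read_frames(directory: str | Path) -> list[ThermalFrame]:
    """Load a frame directory: ``*.png`` images with ``*.json`` sidecars.

    Each sidecar carries ``{timestamp_s, t_cold_c, t_hot_c, cold_xy,
    hot_xy, colormap_id | colormap}``. Frames are returned sorted by
    timestamp.
    """
    directory = Path(directory)
    frames = []
    for png in sorted(directory.glob("*.png")):
        sidecar = png.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar for frame {png}")
        meta = _load_sidecar(sidecar)
        if "colormap" in meta:
            cmap = np.asarray(meta["colormap"], dtype=np.uint8)
        else:
            cmap = get_colormap(meta["colormap_id"])
        rgb = np.asarray(Image.open(png).convert("RGB"))
        frames.append(
            ThermalFrame(
                rgb=rgb,
                colormap=cmap,
                t_cold=float(meta["t_cold_c"]),
                t_hot=float(meta["t_hot_c"]),
                cold_xy=tuple(meta["cold_xy"]),
                hot_xy=tuple(meta["hot_xy"]),
                timestamp=float(meta["timestamp_s"]),
            )
        )
    frames.sort(key=lambda f: f.timestamp)
    return frames


def write_frame_temps_csv(frames: Sequence[FrameTemps], path: str) -> None:
    """Write per-frame temperatures as CSV (°C at 2 decimals, ratios at 4)."""
    def c(v):  # °C or blank
        return "" if v is None else f"{v:.2f}"

    def r(v):  # ratio or blank
        return "" if v is None else f"{v:.4f}"

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("timestamp_s,face_mean_c,nose_mean_c,frame_mean_c,face_norm,nose_norm\n")
        for f in frames:
            fh.write(
                f"{f.timestamp:.3f},{c(f.face_mean)},{c(f.nose_mean)},"
                f"{c(f.frame_mean)},{r(f.face_norm)},{r(f.nose_norm)}\n"
            )
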