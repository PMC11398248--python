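"""Session-level orchestration: one report per driving session.

Reads an R-R CSV (and optionally a directory of thermal frames), runs the
HRV, arousal and thermal stages, and emits a per-epoch table: mean HR,
RMSSD, mean arousal φ̂, and epoch-averaged normalized face/nose
temperatures. Missing quantities stay explicitly missing; stage boundaries
are logged with counts (samples per epoch, frames kept or dropped, nose
boxes rejected by the validity rule).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .arousal import ArousalConfig, arousal_trace
from .hrv import read_rr_csv, rmssd_by_epoch
from .protocol import DrivingProtocol, slice_by_epoch
from .thermal import (
    GroundTruthDetector,
    RoiDetector,
    detect_rois,
    epoch_average,
    process_frames,
    read_frames,
    validate_nose_roi,
)

__all__ = ["EpochRecord", "SessionReport", "run_session", "write_report_json", "write_report_csv"]

log = logging.getLogger(__name__)

#: Tail of the rest recordings analysed for the on-road protocol (s): only
#: the last 5 min of the 10-min baseline/recovery phases are summarised.
REAL_BASELINE_TAIL_S = 300.0


@dataclass(frozen=True)
class EpochRecord:
    """Per-epoch summary row; None marks a missing quantity."""

    epoch: str
    mean_hr: float | None
    rmssd: float | None
    n_samples: int
    phi_hat: float | None
    face_norm_avg: float | None
    nose_norm_avg: float | None


@dataclass(frozen=True)
class SessionReport:
    """All per-epoch quantities for one session, in protocol order."""

    protocol: str
    records: tuple[EpochRecord, ...]
    provenance: dict

    def epoch_names(self) -> tuple[str, ...]:
        return tuple(r.epoch for r in self.records)

    def __getitem__(self, epoch: str) -> EpochRecord:
        for r in self.records:
            if r.epoch == epoch:
                return r
        raise KeyError(epoch)


def _config_digest(protocol: DrivingProtocol, cfg: ArousalConfig) -> str:
    doc = {
        "protocol": [
            [ep.name, ep.start, ep.duration, ep.kind, ep.stressor]
            for ep in protocol.epochs
        ],
        "arousal": asdict(cfg),
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]


def run_session(
    rr_path: str,
    frames_path: str | None,
    protocol: DrivingProtocol,
    arousal_cfg: ArousalConfig | None = None,
    detector: RoiDetector | None = None,
) -> SessionReport:
    """Run the full pipeline on one session.

    Parameters
    ----------
    rr_path : str
        R-R CSV (``timestamp_s,rr_ms[,hr_bpm]``).
    frames_path : str or None
        Directory of thermal PNG frames with JSON sidecars; None for an
        HRV-only session (thermal columns then stay missing).
    protocol : DrivingProtocol
        For the builtin on-road protocol (name ``"real"``) the baseline
        and recovery summaries use only the last 5 min of each rest
        recording.
    arousal_cfg : ArousalConfig, optional
    detector : RoiDetector, optional
        Defaults to the ground-truth detector replaying
        ``manifest.json`` found next to (or inside) ``frames_path``.

    Raises
    ------
    FileNotFoundError / ValueError
        With the offending path; inputs are never silently skipped.
    """
    cfg = arousal_cfg or ArousalConfig()
    tail = REAL_BASELINE_TAIL_S if protocol.name == "real" else None
    if cfg.baseline_tail_s is None and tail is not None:
        cfg = replace(cfg, baseline_tail_s=tail)

    try:
        series = read_rr_csv(rr_path)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"cannot read R-R input {rr_path!r}: {exc}") from exc
    except OSError as exc:
        raise OSError(f"cannot read R-R input {rr_path!r}: {exc}") from exc
    mapping, n_discarded = slice_by_epoch(series.timestamps, protocol)
    for ep in protocol.epochs:
        log.info("epoch %s: %d R-R samples", ep.name, mapping[ep.name].size)
    if n_discarded:
        log.info("%d R-R samples beyond protocol end discarded", n_discarded)

    hrv_results = {
        r.epoch_name: r
        for r in rmssd_by_epoch(series, protocol, baseline_tail_s=cfg.baseline_tail_s)
    }
    trace = arousal_trace(series, protocol, cfg)
    if trace.short_epochs:
        log.info("epochs with no arousal emissions: %s", ", ".join(trace.short_epochs))

    thermal_avg = None
    if frames_path is not None:
        frames_dir = Path(frames_path)
        try:
            frames = read_frames(frames_dir)
        except OSError as exc:
            raise OSError(f"cannot read thermal frames {frames_path!r}: {exc}") from exc
        if detector is None:
            manifest = frames_dir / "manifest.json"
            if not manifest.exists():
                manifest = frames_dir.parent / "manifest.json"
            if not manifest.exists():
                raise FileNotFoundError(
                    f"no detector supplied and no manifest.json near {frames_path!r}"
                )
            detector = GroundTruthDetector.from_manifest(manifest)
        n_no_face = n_rejected_nose = 0
        for f in frames:
            face, nose = detect_rois(f, detector)
            if face is None:
                n_no_face += 1
            elif nose is not None and not validate_nose_roi(nose, face):
                n_rejected_nose += 1
        log.info(
            "%d thermal frames: %d without face detection, %d nose boxes "
            "rejected by the face-relative height rule",
            len(frames), n_no_face, n_rejected_nose,
        )
        thermal_avg = epoch_average(process_frames(frames, detector), protocol)

    records = []
    for ep in protocol.epochs:
        h = hrv_results[ep.name]
        if ep.kind == "baseline":
            phi_hat = 0.0  # arousal is measured relative to this epoch
        else:
            phi_hat = trace.per_epoch_mean.get(ep.name)
        t = thermal_avg.get(ep.name) if thermal_avg else None
        records.append(
            EpochRecord(
                epoch=ep.name,
                mean_hr=h.mean_hr,
                rmssd=h.rmssd,
                n_samples=h.n_samples,
                phi_hat=phi_hat,
                face_norm_avg=None if t is None else t["face_norm"],
                nose_norm_avg=None if t is None else t["nose_norm"],
            )
        )
    provenance = {
        "rr_path": str(rr_path),
        "frames_path": None if frames_path is None else str(frames_path),
        "config_digest": _config_digest(protocol, cfg),
    }
    return SessionReport(
        protocol=protocol.name, records=tuple(records), provenance=provenance
    )


def _fmt(value: float | None, decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def write_report_json(report: SessionReport, path: str) -> None:
    """Write the report as JSON (stable key order, fixed rounding)."""
    doc = {
        "protocol": report.protocol,
        "provenance": report.provenance,
        "epochs": [
            {
                "epoch": r.epoch,
                "mean_hr_bpm": None if r.mean_hr is None else round(r.mean_hr, 2),
                "rmssd_ms": None if r.rmssd is None else round(r.rmssd, 2),
                "n_samples": r.n_samples,
                "phi_hat": None if r.phi_hat is None else round(r.phi_hat, 2),
                "face_norm_avg": None if r.face_norm_avg is None else round(r.face_norm_avg, 4),
                "nose_norm_avg": None if r.nose_norm_avg is None else round(r.nose_norm_avg, 4),
            }
            for r in report.records
        ],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def write_report_csv(report: SessionReport, path: str) -> None:
    """Write the per-epoch table as CSV.

    ms/bpm at 2 decimals (the precision physiological summaries are
    conventionally printed at), φ̂ at 2 decimals, normalized temperature
    ratios at 4.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("epoch,mean_hr_bpm,rmssd_ms,n_samples,phi_hat,face_norm_avg,nose_norm_avg\n")
        for r in report.records:
            fh.write(
                f"{r.epoch},{_fmt(r.mean_hr, 2)},{_fmt(r.rmssd, 2)},{r.n_samples},"
                f"{_fmt(r.phi_hat, 2)},{_fmt(r.face_norm_avg, 4)},{_fmt(r.nose_norm_avg, 4)}\n"
            )
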