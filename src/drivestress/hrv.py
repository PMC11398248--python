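"""R-R interval series and time-domain heart-rate-variability indices.

The central index is the RMSSD — the root mean square of successive R-R
interval differences,

    RMSSD = sqrt( Σ_{n=2..N} (RR_n − RR_{n−1})² / (N−1) )   [ms],

a short-term HRV measure reflecting vagal (parasympathetic) activity:
lower RMSSD indicates sympathetic activation, i.e. stress. RMSSD is
computed per protocol epoch over the samples falling in that epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import DrivingProtocol, slice_by_epoch

__all__ = [
    "RRSeries",
    "RmssdResult",
    "compute_rmssd",
    "phase_sample_count",
    "mean_hr",
    "rmssd_by_epoch",
    "read_rr_csv",
    "write_rr_csv",
    "write_rmssd_csv",
]

#: Nominal sensor tick: one R-R sample delivered every 40 ms.
DEFAULT_TICK_MS = 40.0


@dataclass(frozen=True)
class RRSeries:
    """Timestamped R-R intervals for one session.

    Parameters
    ----------
    timestamps : array of float
        Sample times in seconds from session start, non-decreasing.
    rr : array of float
        R-R interval durations in ms, strictly positive.
    hr : array of float, optional
        Heart rate in bpm per sample, if the sensor supplies it.
    tick : float
        Nominal sampling period in ms (default 40).
    """

    timestamps: np.ndarray
    rr: np.ndarray
    hr: np.ndarray | None = None
    tick: float = DEFAULT_TICK_MS

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "rr", rr)
        if self.hr is not None:
            object.__setattr__(self, "hr", np.asarray(self.hr, dtype=float))
        if ts.shape != rr.shape or ts.ndim != 1:
            raise ValueError("timestamps and rr must be 1-D arrays of equal length")
        if self.hr is not None and self.hr.shape != rr.shape:
            raise ValueError("hr must match rr length")
        if rr.size and np.any(rr <= 0):
            raise ValueError("R-R intervals must be strictly positive")
        if ts.size and np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.tick <= 0:
            raise ValueError("tick must be > 0")

    def __len__(self) -> int:
        return int(self.rr.size)


@dataclass(frozen=True)
class RmssdResult:
    """Per-epoch HRV summary: RMSSD (ms), sample count, optional mean HR."""

    epoch_name: str
    rmssd: float | None
    n_samples: int
    mean_hr: float | None = None

    @property
    def missing(self) -> bool:
        """True when the epoch had too few samples to define RMSSD."""
        return self.rmssd is None


def compute_rmssd(rr: Sequence[float]) -> float:
    """Root mean square of successive R-R differences, in ms.

    Requires at least two strictly positive intervals; a constant series
    gives 0. The divisor is N−1, the number of successive differences.
    """
    arr = np.asarray(rr, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rr must be one-dimensional")
    if arr.size < 2:
        raise ValueError("RMSSD requires at least 2 R-R intervals")
    if np.any(arr <= 0):
        raise ValueError("R-R intervals must be strictly positive")
    diffs = np.diff(arr)
    return float(math.sqrt(float(diffs @ diffs) / diffs.size))


def phase_sample_count(duration_s: float, tick_ms: float = DEFAULT_TICK_MS) -> int:
    """Number of R-R samples N in a phase: floor(duration_ms / tick_ms).

    At the nominal 40-ms tick a 2-min phase holds N=3000 samples and a
    5-min phase N=7500.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if tick_ms <= 0:
        raise ValueError("tick_ms must be > 0")
    return int(duration_s * 1000.0 // tick_ms)


def mean_hr(rr: Sequence[float]) -> float:
    """Mean heart rate in bpm implied by R-R intervals: 60000 / mean(rr)."""
    arr = np.asarray(rr, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_hr requires at least one interval")
    if np.any(arr <= 0):
        raise ValueError("R-R intervals must be strictly positive")
    return float(60000.0 / arr.mean())


def rmssd_by_epoch(
    series: RRSeries,
    protocol: DrivingProtocol,
    baseline_tail_s: float | None = None,
) -> list[RmssdResult]:
    """Per-epoch RMSSD and mean HR for a session.

    Epochs with fewer than two samples yield a missing result (``rmssd``
    None) rather than zero — absence of data is not absence of
    variability.

    Parameters
    ----------
    series : RRSeries
    protocol : DrivingProtocol
    baseline_tail_s : float, optional
        When given, baseline-kind and recovery-kind epochs are summarised
        over only their last ``baseline_tail_s`` seconds (used for the
        on-road protocol, where the final 5 min of the 10-min rest
        recordings are analysed).
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    mapping, _ = slice_by_epoch(series.timestamps, protocol)
    out: list[RmssdResult] = []
    for ep in protocol.epochs:
        idx = mapping[ep.name]
        if baseline_tail_s is not None and ep.kind in ("baseline", "recovery"):
            cutoff = ep.end - baseline_tail_s
            idx = idx[series.timestamps[idx] >= cutoff]
        rr = series.rr[idx]
        if rr.size < 2:
            out.append(RmssdResult(ep.name, None, int(rr.size), None))
        else:
            out.append(
                RmssdResult(ep.name, compute_rmssd(rr), int(rr.size), mean_hr(rr))
            )
    return out


def read_rr_csv(path: str, tick: float = DEFAULT_TICK_MS) -> RRSeries:
    """Read an R-R CSV with header ``timestamp_s,rr_ms[,hr_bpm]``."""
    df = pd.read_csv(path)
    required = {"timestamp_s", "rr_ms"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    hr = df["hr_bpm"].to_numpy(dtype=float) if "hr_bpm" in df.columns else None
    return RRSeries(
        timestamps=df["timestamp_s"].to_numpy(dtype=float),
        rr=df["rr_ms"].to_numpy(dtype=float),
        hr=hr,
        tick=tick,
    )


def write_rr_csv(series: RRSeries, path: str) -> None:
    """Write an R-R series as ``timestamp_s,rr_ms[,hr_bpm]`` (fixed formatting)."""
    cols = {"timestamp_s": series.timestamps, "rr_ms": series.rr}
    if series.hr is not None:
        cols["hr_bpm"] = series.hr
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def write_rmssd_csv(results: Sequence[RmssdResult], path: str) -> None:
    """Write per-epoch results as ``epoch,rmssd_ms,n,mean_hr_bpm`` (2 decimals)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("epoch,rmssd_ms,n,mean_hr_bpm\n")
        for r in results:
            rmssd = "" if r.rmssd is None else f"{r.rmssd:.2f}"
            hr = "" if r.mean_hr is None else f"{r.mean_hr:.2f}"
            fh.write(f"{r.epoch_name},{rmssd},{r.n_samples},{hr}\n")
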