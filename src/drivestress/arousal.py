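"""Arousal index φ from baseline-relative RMSSD change.

The arousal index quantifies psycho-physiological activation in [0, 1].
A reference RMSSD_B is computed over the baseline epoch; during each later
epoch the current RMSSD_C is compared against it through the percent
statistic

    Δrat = |RMSSD_B − RMSSD_C| · 100 / RMSSD_B.

When RMSSD has dropped below baseline (stress direction), Δrat is quantized
onto 10 equal bins of width (Δmax − Δmin)·s over (Δmin, Δmax], yielding
φ ∈ {s, 2s, …, 1}; Δrat at or below Δmin maps to 0 and Δrat at or above
Δmax saturates at 1 (maximum activation). A rise of RMSSD above baseline
(relaxation) always maps to φ = 0.

φ is emitted every ``update_period`` seconds (default 5 s) over an
expanding window from the start of the current epoch, after a short warmup
that lets the windowed RMSSD estimate stabilise; the per-epoch mean φ̂ is
the arithmetic average of the emitted values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hrv import RRSeries, compute_rmssd
from .protocol import DrivingProtocol, slice_by_epoch

__all__ = [
    "ArousalConfig",
    "ArousalTrace",
    "delta_rmssd",
    "delta_ratio",
    "quantize_arousal",
    "arousal_trace",
    "write_trace_csv",
]


@dataclass(frozen=True)
class ArousalConfig:
    """Tunable parameters of the arousal quantizer.

    Parameters
    ----------
    s : float
        Granularity of φ (default 0.1, giving 10 nonzero levels).
    delta_min, delta_max : float
        Minimum and maximum measurable percent RMSSD change (defaults
        10 and 120); Δrat ≤ delta_min maps to φ=0 and Δrat ≥ delta_max
        saturates at φ=1.
    update_period : float
        Seconds between φ emissions (default 5).
    warmup : float
        Seconds from epoch start before the first emission (default 30);
        shorter windows give too noisy an RMSSD estimate.
    baseline_tail_s : float, optional
        When set, RMSSD_B is computed over only the last this-many seconds
        of the baseline epoch (used with the on-road protocol's 10-min
        baseline, of which the final 5 min are analysed).
    """

    s: float = 0.1
    delta_min: float = 10.0
    delta_max: float = 120.0
    update_period: float = 5.0
    warmup: float = 30.0
    baseline_tail_s: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.s <= 1:
            raise ValueError("granularity s must be in (0, 1]")
        if not self.delta_min < self.delta_max:
            raise ValueError("delta_min must be < delta_max")
        if self.update_period <= 0:
            raise ValueError("update_period must be > 0")
        if self.warmup < 0:
            raise ValueError("warmup must be >= 0")

    @property
    def n_levels(self) -> int:
        """Number of nonzero quantization levels (10 at default s=0.1)."""
        return int(round(1.0 / self.s))

    @property
    def bin_width(self) -> float:
        """Width of one quantization bin in percent: (Δmax − Δmin)·s."""
        return (self.delta_max - self.delta_min) * self.s


@dataclass(frozen=True)
class ArousalTrace:
    """Time-stamped φ values plus per-epoch means.

    ``short_epochs`` lists epochs too short (or too empty) to emit any φ;
    their φ̂ is reported as 0.
    """

    timestamps: np.ndarray
    phi: np.ndarray
    per_epoch_mean: dict[str, float]
    rmssd_baseline: float
    short_epochs: tuple[str, ...] = field(default_factory=tuple)


def delta_rmssd(rmssd_baseline: float, rmssd_current: float) -> float:
    """Baseline-minus-current RMSSD change in ms (positive under stress)."""
    return float(rmssd_baseline - rmssd_current)


def delta_ratio(delta: float, rmssd_baseline: float) -> float:
    """Percent RMSSD change: |delta| · 100 / RMSSD_B.

    The baseline RMSSD must be strictly positive — a baseline with no
    measurable variability gives the statistic no scale.
    """
    if rmssd_baseline <= 0:
        raise ValueError("rmssd_baseline must be > 0 to form the percent ratio")
    return abs(float(delta)) * 100.0 / float(rmssd_baseline)


def quantize_arousal(delta: float, ratio: float, cfg: ArousalConfig | None = None) -> float:
    """Map the percent RMSSD change onto the discrete arousal scale.

    Parameters
    ----------
    delta : float
        Signed RMSSD change (baseline − current), ms. Non-positive values
        (relaxation direction) always give φ = 0.
    ratio : float
        Percent change |delta|·100/RMSSD_B, must be ≥ 0.
    cfg : ArousalConfig, optional

    Returns
    -------
    float
        φ ∈ {0} ∪ {s, 2s, …, 1}.
    """
    cfg = cfg or ArousalConfig()
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if delta <= 0:  # RMSSD at or above baseline: no activation
        return 0.0
    if ratio <= cfg.delta_min:
        return 0.0
    if ratio >= cfg.delta_max:
        return 1.0
    k = math.ceil((ratio - cfg.delta_min) / cfg.bin_width)
    return round(min(k, cfg.n_levels) * cfg.s, 10)


def arousal_trace(
    series: RRSeries,
    protocol: DrivingProtocol,
    cfg: ArousalConfig | None = None,
) -> ArousalTrace:
    """Run the arousal algorithm over a full session.

    RMSSD_B is fixed from the baseline epoch (optionally only its tail,
    see :class:`ArousalConfig`). Then, in every non-baseline epoch, φ is
    emitted at epoch-relative offsets warmup, warmup+period, … over an
    expanding window from the epoch start.

    Raises
    ------
    ValueError
        If the baseline epoch holds fewer than two samples.
    """
    cfg = cfg or ArousalConfig()
    mapping, _ = slice_by_epoch(series.timestamps, protocol)
    base = protocol.baseline
    idx_b = mapping[base.name]
    if cfg.baseline_tail_s is not None:
        cutoff = base.end - cfg.baseline_tail_s
        idx_b = idx_b[series.timestamps[idx_b] >= cutoff]
    if idx_b.size < 2:
        raise ValueError(
            f"baseline epoch {base.name!r} holds {idx_b.size} samples; "
            "at least 2 are required to establish RMSSD_B"
        )
    rmssd_b = compute_rmssd(series.rr[idx_b])

    times: list[float] = []
    phis: list[float] = []
    per_epoch: dict[str, float] = {}
    short: list[str] = []
    for ep in protocol.epochs:
        if ep.kind == "baseline":
            continue
        idx = mapping[ep.name]
        ep_ts = series.timestamps[idx]
        ep_rr = series.rr[idx]
        emitted: list[float] = []
        offset = cfg.warmup
        while offset < ep.duration:
            t = ep.start + offset
            window = ep_rr[ep_ts <= t]
            if window.size >= 2:
                rmssd_c = compute_rmssd(window)
                delta = delta_rmssd(rmssd_b, rmssd_c)
                if delta <= 0:
                    phi = 0.0
                else:
                    phi = quantize_arousal(delta, delta_ratio(delta, rmssd_b), cfg)
                times.append(t)
                phis.append(phi)
                emitted.append(phi)
            offset += cfg.update_period
        if emitted:
            per_epoch[ep.name] = float(np.mean(emitted))
        else:
            per_epoch[ep.name] = 0.0
            short.append(ep.name)
    return ArousalTrace(
        timestamps=np.asarray(times, dtype=float),
        phi=np.asarray(phis, dtype=float),
        per_epoch_mean=per_epoch,
        rmssd_baseline=rmssd_b,
        short_epochs=tuple(short),
    )


def write_trace_csv(trace: ArousalTrace, path: str) -> None:
    """Write the φ trace as ``timestamp_s,phi`` (φ at 1 decimal)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("timestamp_s,phi\n")
        for t, p in zip(trace.timestamps, trace.phi):
            fh.write(f"{t:.3f},{p:.1f}\n")
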