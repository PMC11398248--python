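"""Driving protocols: ordered epoch schedules and epoch-wise slicing.

A driving session is divided into contiguous epochs (baseline, driving,
stressor, recovery), each with a fixed duration. Two builtin protocols are
provided: a 45-min on-road protocol (10-min baseline, two beltway drives,
three co-driver urban segments — the middle one with induced stress — and a
10-min recovery) and a 14-min simulator protocol of seven 2-min epochs in
which cognitive, visual and emotional distraction tasks act as stressors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Epoch",
    "DrivingProtocol",
    "builtin_protocol",
    "slice_by_epoch",
    "load_protocol",
]

EPOCH_KINDS = ("baseline", "driving", "stressor", "recovery")


@dataclass(frozen=True)
class Epoch:
    """One contiguous phase of a driving protocol.

    Parameters
    ----------
    name : str
        Phase label (e.g. ``"Baseline"``, ``"CD"``).
    start : float
        Offset of the epoch start from session start, in seconds.
    duration : float
        Epoch length in seconds; must be positive.
    kind : str
        One of ``baseline``, ``driving``, ``stressor``, ``recovery``.
    stressor : bool
        Whether an explicit stress-inducing task (co-driver comments,
        distraction exercise) is active during the epoch.
    """

    name: str
    start: float
    duration: float
    kind: str = "driving"
    stressor: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"epoch {self.name!r}: duration must be > 0")
        if self.start < 0:
            raise ValueError(f"epoch {self.name!r}: start must be >= 0")
        if self.kind not in EPOCH_KINDS:
            raise ValueError(
                f"epoch {self.name!r}: kind {self.kind!r} not in {EPOCH_KINDS}"
            )

    @property
    def end(self) -> float:
        """Exclusive end time in seconds (epochs are half-open intervals)."""
        return self.start + self.duration

    def contains(self, t: float) -> bool:
        """True if time ``t`` (s) falls in the half-open [start, end)."""
        return self.start <= t < self.end


@dataclass(frozen=True)
class DrivingProtocol:
    """An ordered, contiguous, non-overlapping sequence of epochs.

    The first epoch must be a baseline; epoch *k* must start exactly where
    epoch *k−1* ends, so the epochs partition [0, total_duration).
    """

    name: str
    epochs: tuple[Epoch, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol must contain at least one epoch")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if self.epochs[0].kind != "baseline":
            raise ValueError("first epoch must have kind 'baseline'")
        expected = self.epochs[0].start
        if expected != 0:
            raise ValueError("first epoch must start at t=0")
        for ep in self.epochs:
            if not np.isclose(ep.start, expected):
                raise ValueError(
                    f"epoch {ep.name!r} starts at {ep.start} s, expected "
                    f"{expected} s (epochs must be contiguous)"
                )
            expected = ep.start + ep.duration
        names = [ep.name for ep in self.epochs]
        if len(set(names)) != len(names):
            raise ValueError("epoch names must be unique")

    @property
    def total_duration(self) -> float:
        """Session length in seconds (sum of epoch durations)."""
        return sum(ep.duration for ep in self.epochs)

    @property
    def baseline(self) -> Epoch:
        """The (first) baseline epoch."""
        return self.epochs[0]

    def non_baseline(self) -> tuple[Epoch, ...]:
        """Epochs after the baseline — the phases scored for arousal."""
        return tuple(ep for ep in self.epochs if ep.kind != "baseline")

    def epoch_names(self) -> tuple[str, ...]:
        return tuple(ep.name for ep in self.epochs)

    def __getitem__(self, name: str) -> Epoch:
        for ep in self.epochs:
            if ep.name == name:
                return ep
        raise KeyError(name)

    def epoch_of(self, t: float) -> Epoch | None:
        """Epoch whose half-open interval contains time ``t``, else None."""
        for ep in self.epochs:
            if ep.contains(t):
                return ep
        return None


def _from_durations(name: str, rows: Iterable[tuple[str, float, str, bool]]) -> DrivingProtocol:
    epochs = []
    t = 0.0
    for ep_name, dur, kind, stressor in rows:
        epochs.append(Epoch(ep_name, t, dur, kind, stressor))
        t += dur
    return DrivingProtocol(name, tuple(epochs))


# 45-min on-road protocol: 10-min baseline at rest, beltway, three 5-min
# urban co-driver segments (stress induced in the middle one), beltway,
# 10-min recovery at rest.
_REAL = _from_durations(
    "real",
    [
        ("Baseline", 600, "baseline", False),
        ("B1", 300, "driving", False),
        ("C1", 300, "driving", False),
        ("C2", 300, "stressor", True),
        ("C3", 300, "driving", False),
        ("B2", 300, "driving", False),
        ("Recovery", 600, "recovery", False),
    ],
)

# 14-min simulator protocol: seven 2-min epochs; distraction tasks
# (cognitive, visual, emotional) act as stressors.
_SIMULATED = _from_durations(
    "simulated",
    [
        ("Baseline", 120, "baseline", False),
        ("BD", 120, "driving", False),
        ("CD", 120, "stressor", True),
        ("VD", 120, "stressor", True),
        ("E", 120, "stressor", True),
        ("E+VD", 120, "stressor", True),
        ("Recovery", 120, "recovery", False),
    ],
)

_BUILTINS = {"real": _REAL, "simulated": _SIMULATED}


def builtin_protocol(which: str) -> DrivingProtocol:
    """Return a builtin driving protocol.

    Parameters
    ----------
    which : {"real", "simulated"}
        ``"real"`` is the 45-min on-road protocol (2700 s, 7 epochs);
        ``"simulated"`` is the 14-min simulator protocol (840 s, 7 epochs).
    """
    try:
        return _BUILTINS[which]
    except KeyError:
        raise ValueError(
            f"unknown protocol {which!r}; available: {sorted(_BUILTINS)}"
        ) from None


def slice_by_epoch(
    timestamps: Sequence[float],
    protocol: DrivingProtocol,
) -> tuple[dict[str, np.ndarray], int]:
    """Assign timestamped samples to protocol epochs.

    Each sample belongs to the unique epoch whose half-open interval
    [start, start+duration) contains its timestamp; samples at or beyond
    the protocol end are discarded and counted.

    Parameters
    ----------
    timestamps : sequence of float
        Non-decreasing sample times in seconds from session start.
    protocol : DrivingProtocol

    Returns
    -------
    mapping : dict of epoch name -> integer index array into ``timestamps``
        Every epoch of the protocol appears as a key (possibly with an
        empty index array).
    n_discarded : int
        Number of samples outside [0, total_duration).
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size and np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be non-decreasing")
    mapping: dict[str, np.ndarray] = {}
    in_range = np.zeros(ts.shape, dtype=bool)
    for ep in protocol.epochs:
        mask = (ts >= ep.start) & (ts < ep.end)
        mapping[ep.name] = np.flatnonzero(mask)
        in_range |= mask
    return mapping, int(ts.size - in_range.sum())


def _protocol_from_dict(doc: Mapping) -> DrivingProtocol:
    rows = []
    for item in doc["epochs"]:
        rows.append(
            (
                str(item["name"]),
                float(item["duration_s"]),
                str(item.get("kind", "driving")),
                bool(item.get("stressor", False)),
            )
        )
    return _from_durations(str(doc.get("name", "custom")), rows)


def load_protocol(path: str) -> DrivingProtocol:
    """Load a protocol from a YAML or JSON document.

    Expected shape: ``{name, epochs: [{name, duration_s, kind, stressor}]}``;
    epoch starts are derived from the listed order.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    doc = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "epochs" not in doc:
        raise ValueError(f"{path}: protocol document must map 'epochs' to a list")
    return _protocol_from_dict(doc)
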