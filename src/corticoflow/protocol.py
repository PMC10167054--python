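"""Experimental protocol and block timeline.

A session is a single relaxation phase followed by repeated task/rest
cycles, performed once per condition (force level x arm side). Both
modalities (EMG at 1 kHz, fNIRS at 11 Hz) share the same wall-clock block
boundaries; per-modality sample intervals are derived from them as
half-open ``[start, end)`` ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOMINANT = "dominant"
NON_DOMINANT = "non-dominant"

#: condition = (force level as fraction of MVC, side)
DEFAULT_CONDITIONS: tuple[tuple[float, str], ...] = (
    (0.2, DOMINANT),
    (0.8, DOMINANT),
    (0.2, NON_DOMINANT),
    (0.8, NON_DOMINANT),
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Session structure: 3-min relaxation, then repeated 15-s task / 30-s rest."""

    relaxation_s: float = 180.0
    task_s: float = 15.0
    rest_s: float = 30.0
    repetitions: int = 5
    conditions: tuple[tuple[float, str], ...] = DEFAULT_CONDITIONS
    emg_rate: float = 1000.0
    nirs_rate: float = 11.0

    def __post_init__(self) -> None:
        if self.task_s <= 0 or self.rest_s <= 0:
            raise ValueError("task_s and rest_s must be positive")
        if self.relaxation_s < 0:
            raise ValueError("relaxation_s must be non-negative")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.emg_rate <= 0 or self.nirs_rate <= 0:
            raise ValueError("sampling rates must be positive")
        for force, side in self.conditions:
            if not (0 < force <= 1):
                raise ValueError(f"force level {force} outside (0, 1]")
            if side not in (DOMINANT, NON_DOMINANT):
                raise ValueError(f"unknown side {side!r}")

    @property
    def session_s(self) -> float:
        return self.relaxation_s + self.repetitions * (self.task_s + self.rest_s)


@dataclass(frozen=True)
class Block:
    """One labeled interval of the session, in seconds (half-open)."""

    label: str  # "relaxation" | "task" | "rest"
    start_s: float
    end_s: float

    def sample_range(self, rate: float) -> tuple[int, int]:
        return int(round(self.start_s * rate)), int(round(self.end_s * rate))


@dataclass(frozen=True)
class Timeline:
    blocks: tuple[Block, ...]

    @property
    def duration_s(self) -> float:
        return self.blocks[-1].end_s if self.blocks else 0.0

    def n_samples(self, rate: float) -> int:
        return int(round(self.duration_s * rate))

    def blocks_of(self, label: str) -> list[Block]:
        return [b for b in self.blocks if b.label == label]

    def mask(self, label: str, rate: float) -> np.ndarray:
        """Boolean sample mask for all blocks with the given label."""
        out = np.zeros(self.n_samples(rate), dtype=bool)
        for b in self.blocks_of(label):
            lo, hi = b.sample_range(rate)
            out[lo:hi] = True
        return out

    def sample_ranges(self, label: str, rate: float) -> list[tuple[int, int]]:
        return [b.sample_range(rate) for b in self.blocks_of(label)]

    def to_records(self) -> list[dict]:
        return [
            {"label": b.label, "start_s": b.start_s, "end_s": b.end_s}
            for b in self.blocks
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "Timeline":
        return cls(
            tuple(Block(r["label"], float(r["start_s"]), float(r["end_s"])) for r in records)
        )


def build_timeline(protocol: ProtocolSpec) -> Timeline:
    """Lay out the session blocks for one condition.

    Blocks tile the session without gaps or overlap; EMG and fNIRS sample
    intervals are derived from the identical wall-clock boundaries.
    """
    blocks: list[Block] = []
    t = 0.0
    if protocol.relaxation_s > 0:
        blocks.append(Block("relaxation", t, t + protocol.relaxation_s))
        t += protocol.relaxation_s
    for _ in range(protocol.repetitions):
        blocks.append(Block("task", t, t + protocol.task_s))
        t += protocol.task_s
        blocks.append(Block("rest", t, t + protocol.rest_s))
        t += protocol.rest_s
    return Timeline(tuple(blocks))
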