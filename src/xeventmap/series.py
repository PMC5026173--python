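"""Ordered challenge-series container shared by the simulator and the metrics.

A challenge series is the sequence of single-inhalation acquisitions taken
during a cumulative methacholine (MCh) provocation protocol: one or more
baseline frames, an optional vehicle/fluid frame, one frame per MCh dose, and
an optional bronchodilator-reversal frame. Frames may hold raw complex
k-space or reconstructed magnitude images; the bookkeeping (roles, per-step
dose increments, running cumulative dose) is identical in either state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

ROLES = ("baseline", "fluid", "dose", "reversal")


@dataclass
class ChallengeSeries:
    """Ordered frames of a bronchoprovocation imaging protocol.

    Parameters
    ----------
    frames
        Frame objects in acquisition order. Each must expose a 2D array via
        either a ``data`` (complex k-space) or ``values`` (magnitude)
        attribute.
    roles
        One of ``baseline``, ``fluid``, ``dose``, ``reversal`` per frame.
    dose_increments_ug
        MCh increment (µg) for each ``dose`` frame, in order.
    cumulative_dose_ug
        Running cumulative MCh dose (µg) per frame; 0 for baseline/fluid
        frames, held at the maximum for the reversal frame.
    phantom
        Optional ground-truth phantom the series was simulated from.
    """

    frames: list
    roles: list
    dose_increments_ug: list
    cumulative_dose_ug: list
    phantom: Optional[Any] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.roles):
            raise ValueError("one role per frame required")
        if len(self.frames) != len(self.cumulative_dose_ug):
            raise ValueError("one cumulative dose per frame required")
        for r in self.roles:
            if r not in ROLES:
                raise ValueError(f"unknown frame role {r!r}")
        if sum(r == "baseline" for r in self.roles) < 1:
            raise ValueError("at least one baseline frame required")
        if len(self.dose_increments_ug) != sum(r == "dose" for r in self.roles):
            raise ValueError("one dose increment per dose frame required")
        shapes = {self._array(f).shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed grid shapes: {shapes}")
        cum = np.asarray(self.cumulative_dose_ug, dtype=float)
        if np.any(np.diff(cum) < 0):
            raise ValueError("cumulative doses must be non-decreasing")

    @staticmethod
    def _array(frame) -> np.ndarray:
        if hasattr(frame, "values"):
            return frame.values
        if hasattr(frame, "data"):
            return frame.data
        return np.asarray(frame)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def grid_shape(self):
        return self._array(self.frames[0]).shape

    def indices(self, role: str) -> list:
        """Frame indices holding the given role, in acquisition order."""
        return [i for i, r in enumerate(self.roles) if r == role]

    @property
    def labels(self) -> list:
        return [getattr(f, "label", f"frame{i}") for i, f in enumerate(self.frames)]


def cumulative_doses(increments: Sequence[float]) -> list:
    """Running cumulative dose from per-step MCh increments.

    The printed protocol 10, 25, 50, 75, 100, 200, 400 µg accumulates to
    10, 35, 85, 160, 260, 460, 860 µg.
    """
    out: list = []
    total = 0.0
    for inc in increments:
        if inc < 0:
            raise ValueError(f"negative dose increment {inc}")
        total += float(inc)
        out.append(total)
    return out
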