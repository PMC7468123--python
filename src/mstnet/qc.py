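"""Subject-level head-motion quality control.

Subjects are excluded before connectivity analysis when their per-frame
relative RMS displacement is too high: either the mean over frames exceeds
0.2 mm, or at least 20 individual frames exceed 0.25 mm.  The mean rule is
evaluated first; a decision carries exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MEAN_THRESHOLD_MM = 0.2
SPIKE_THRESHOLD_MM = 0.25
MAX_SPIKE_FRAMES = 20

__all__ = [
    "MotionTrace",
    "QCDecision",
    "mean_relative_displacement",
    "apply_exclusion",
]


@dataclass
class MotionTrace:
    """Per-frame relative RMS displacement values, in mm."""

    displacements: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 1:
            raise ValueError("motion trace must be one-dimensional")
        if np.any(self.displacements < 0):
            raise ValueError("displacements must be nonnegative")

    @property
    def frame_count(self) -> int:
        return int(self.displacements.size)


@dataclass(frozen=True)
class QCDecision:
    subject_id: str
    included: bool
    reason: str  # "ok" | "mean_displacement" | "frame_spikes"
    mean_displacement: float
    spike_frames: int

    def __post_init__(self) -> None:
        if self.included != (self.reason == "ok"):
            raise ValueError("included must be true iff reason is 'ok'")


def mean_relative_displacement(trace: MotionTrace) -> float:
    """Arithmetic mean of the per-frame displacements (mm)."""
    if trace.frame_count == 0:
        raise ValueError("empty motion trace")
    return float(np.mean(trace.displacements))


def apply_exclusion(
    trace: MotionTrace,
    mean_threshold: float = MEAN_THRESHOLD_MM,
    spike_threshold: float = SPIKE_THRESHOLD_MM,
    max_spike_frames: int = MAX_SPIKE_FRAMES,
) -> QCDecision:
    """Decide inclusion of a subject from its motion trace.

    Excluded with reason ``mean_displacement`` if the mean displacement
    strictly exceeds ``mean_threshold`` (default 0.2 mm); otherwise with
    reason ``frame_spikes`` if at least ``max_spike_frames`` (default 20)
    frames strictly exceed ``spike_threshold`` (default 0.25 mm).
    """
    mean_disp = mean_relative_displacement(trace)
    spikes = int(np.count_nonzero(trace.displacements > spike_threshold))
    if mean_disp > mean_threshold:
        return QCDecision(trace.subject_id, False, "mean_displacement", mean_disp, spikes)
    if spikes >= max_spike_frames:
        return QCDecision(trace.subject_id, False, "frame_spikes", mean_disp, spikes)
    return QCDecision(trace.subject_id, True, "ok", mean_disp, spikes)
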