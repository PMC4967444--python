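"""Dynamic acquisition protocols.

A DCE-MRI protocol is a regular train of 3D volumes: ``n_frames`` frames
``frame_interval_s`` apart, with the contrast bolus injected between two
frames so that ``contrast_arrival_frame`` (1-based) is the first frame that
can show enhancement.  Two protocols are supported: the standard sequence
(18 frames every ~22 s, bolus between frames 3 and 4) and the lower
temporal resolution (LTR) sequence used for large knees (12 frames every
~39 s, bolus between frames 2 and 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionProtocol", "STANDARD", "LTR", "get_protocol"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing description of one dynamic series.

    Parameters
    ----------
    name
        Protocol label, ``"standard"`` or ``"LTR"``.
    n_frames
        Number of dynamic frames acquired.
    frame_interval_s
        Spacing between consecutive frames, seconds.
    contrast_arrival_frame
        1-based index of the first post-contrast frame.
    """

    name: str
    n_frames: int
    frame_interval_s: float
    contrast_arrival_frame: int

    def __post_init__(self) -> None:
        if self.contrast_arrival_frame < 2:
            raise ValueError("contrast_arrival_frame must be >= 2 (need a pre-contrast baseline)")
        if self.n_frames < self.contrast_arrival_frame:
            raise ValueError("n_frames must be >= contrast_arrival_frame")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def precontrast_frames(self) -> int:
        """Number of frames acquired before contrast arrival."""
        return self.contrast_arrival_frame - 1

    @property
    def duration_s(self) -> float:
        """Time of the last frame on the scan clock (first frame at t=0)."""
        return (self.n_frames - 1) * self.frame_interval_s

    def frame_times(self) -> np.ndarray:
        """Frame acquisition times in seconds, first frame at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def default_bolus_delay_s(self) -> float:
        """Bolus arrival halfway between the last pre- and first post-contrast frame."""
        return (self.contrast_arrival_frame - 1.5) * self.frame_interval_s


STANDARD = AcquisitionProtocol("standard", n_frames=18, frame_interval_s=22.0, contrast_arrival_frame=4)
LTR = AcquisitionProtocol("LTR", n_frames=12, frame_interval_s=39.0, contrast_arrival_frame=3)

_BY_NAME = {"standard": STANDARD, "LTR": LTR}


def get_protocol(name: str) -> AcquisitionProtocol:
    """Look up a built-in protocol by name (``standard`` or ``LTR``)."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown protocol {name!r}; expected one of {sorted(_BY_NAME)}") from None
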