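"""Rigid (translation-only) drift registration and drift-based QC.

The contract is alignment of every frame to frame 0 of a reference channel
by pure translation, estimated with phase cross-correlation at sub-pixel
precision. Feature-based (SIFT-style) matching is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .stack import DriftTrace, FrameStack

__all__ = ["register_rigid", "qc_drift", "QCVerdict"]

# paper-derived defaults: discard series drifting > 300 px XY or > 50 px Z
XY_DRIFT_LIMIT_PX = 300.0
Z_DRIFT_LIMIT_PX = 50.0


def register_rigid(
    stack: FrameStack,
    reference_channel: int | str = 0,
    upsample_factor: int = 20,
) -> tuple[FrameStack, DriftTrace]:
    """Estimate per-frame translation on the reference channel and undo it.

    Returns the corrected stack and the estimated :class:`DriftTrace`
    (offset of each frame relative to frame 0; frame 0 is (0, 0) by
    construction). Sub-pixel precision <= 0.5 px on clean fixtures.
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ref_ch = stack.channel_index(reference_channel)
    ref_planes = stack.pixels[:, ref_ch]
    if stack.has_z:
        ref_planes = ref_planes.max(axis=1)  # register on the MIP

    reference = ref_planes[0]
    if np.ptp(reference) == 0:
        raise ValueError("reference frame is flat; cannot register")

    n = stack.n_frames
    dy = np.zeros(n)
    dx = np.zeros(n)
    for k in range(1, n):
        shift, _, _ = phase_cross_correlation(
            reference, ref_planes[k], upsample_factor=upsample_factor
        )
        # phase_cross_correlation returns the shift to apply to frame k to
        # match the reference; the drift itself is the negative
        dy[k], dx[k] = -shift[0], -shift[1]

    corrected = np.empty_like(stack.pixels, dtype=float)
    corrected[0] = stack.pixels[0]
    for k in range(1, n):
        for c in range(stack.n_channels):
            plane = stack.pixels[k, c]
            if stack.has_z:
                corrected[k, c] = np.stack(
                    [
                        ndimage.shift(z, (-dy[k], -dx[k]), order=1, mode="nearest")
                        for z in plane
                    ]
                )
            else:
                corrected[k, c] = ndimage.shift(
                    plane, (-dy[k], -dx[k]), order=1, mode="nearest"
                )

    return stack.with_pixels(corrected), DriftTrace(dy=dy, dx=dx)


@dataclass
class QCVerdict:
    passed: bool
    reason: str
    failing_frame: int | None = None

    def __bool__(self) -> bool:
        return self.passed


def qc_drift(
    drift: DriftTrace,
    xy_limit: float = XY_DRIFT_LIMIT_PX,
    z_limit: float = Z_DRIFT_LIMIT_PX,
) -> QCVerdict:
    """Apply the drift exclusion rule: fail iff any frame *exceeds* a limit.

    'Exceeds' is strict — a frame exactly at the limit passes.
    """
    xy = drift.xy_magnitude
    over = np.nonzero(xy > xy_limit)[0]
    if over.size:
        k = int(over[0])
        return QCVerdict(
            False, f"XY drift {xy[k]:.1f} px > {xy_limit:g} px at frame {k}", k
        )
    if drift.dz is not None:
        over = np.nonzero(np.abs(drift.dz) > z_limit)[0]
        if over.size:
            k = int(over[0])
            return QCVerdict(
                False,
                f"Z drift {abs(drift.dz[k]):.1f} px > {z_limit:g} px at frame {k}",
                k,
            )
    return QCVerdict(True, "drift within limits")
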