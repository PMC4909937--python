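"""Rigid translation registration between head-fixation sessions.

The tapered head-bar track constrains rotation, and within a 30 s epoch the
preparation is stable, so alignment reduces to estimating one integer-pixel
translation per session (landmarks drift about one pixel between sessions)
and discarding the initial frames contaminated by mechanical settling.

Shift convention: ``estimate_shift(ref, mov)`` returns ``(dy, dx)`` such
that ``mov(y, x) ≈ ref(y - dy, x - dx)`` — the displacement of the moving
frame's content relative to the reference.  ``align_stack`` applies the
inverse shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session_io import FrameStack

__all__ = [
    "ShiftEstimate",
    "UndefinedCorrelationError",
    "AlignmentFailureError",
    "EmptyTrialError",
    "estimate_shift",
    "align_stack",
    "discard_settling",
    "translate_frame",
    "shifts_to_csv",
]


class UndefinedCorrelationError(ValueError):
    """Correlation of a zero-variance frame is undefined."""


class AlignmentFailureError(RuntimeError):
    """A session's estimated shift exceeded the allowed maximum."""


class EmptyTrialError(ValueError):
    """Discarding the settling window would leave no frames."""


@dataclass(frozen=True)
class ShiftEstimate:
    """An estimated rigid translation with its correlation peak."""

    dy: int
    dx: int
    peak_corr: float
    method: str

    def as_tuple(self) -> tuple[int, int]:
        return (self.dy, self.dx)


def _zero_mean(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float64)
    sd = f.std()
    if sd == 0:
        raise UndefinedCorrelationError("flat frame: correlation undefined")
    return f - f.mean()


def _pearson_at_shift(ref: np.ndarray, mov: np.ndarray,
                      dy: int, dx: int) -> float:
    """Pearson r between mov and ref displaced by (dy, dx), on the overlap."""
    h, w = ref.shape
    ry0, ry1 = max(0, -dy), min(h, h - dy)
    rx0, rx1 = max(0, -dx), min(w, w - dx)
    a = ref[ry0:ry1, rx0:rx1]
    b = mov[ry0 + dy:ry1 + dy, rx0 + dx:rx1 + dx]
    if a.size < 4:
        return -np.inf
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -np.inf
    return float((a * b).sum() / denom)


def estimate_shift(reference_frame: np.ndarray, moving_frame: np.ndarray,
                   method: str = "fft", max_shift: int = 10) -> ShiftEstimate:
    """Integer shift maximizing zero-mean normalized cross-correlation.

    ``direct`` evaluates the Pearson correlation on the overlap for every
    shift in ``[-max_shift, max_shift]^2`` (its own oracle); ``fft``
    computes the circular cross-correlation spectrum and restricts the
    argmax to the same window.  Both return the Pearson correlation at the
    optimum so estimates are comparable across methods.
    """
    ref = np.asarray(reference_frame, dtype=np.float64)
    mov = np.asarray(moving_frame, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError("frames must share a shape")
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    _zero_mean(ref)  # variance checks
    _zero_mean(mov)

    if method == "direct":
        best = (-np.inf, 0, 0)
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                r = _pearson_at_shift(ref, mov, dy, dx)
                if r > best[0]:
                    best = (r, dy, dx)
        return ShiftEstimate(best[1], best[2], best[0], "direct")
    if method == "fft":
        a = ref - ref.mean()
        b = mov - mov.mean()
        xc = np.fft.irfft2(np.fft.rfft2(b) * np.conj(np.fft.rfft2(a)),
                           s=a.shape)
        # wrap the circular correlation into signed shift coordinates
        shifts = np.arange(-max_shift, max_shift + 1)
        window = xc[np.ix_(shifts % a.shape[0], shifts % a.shape[1])]
        iy, ix = np.unravel_index(np.argmax(window), window.shape)
        dy, dx = int(shifts[iy]), int(shifts[ix])
        return ShiftEstimate(dy, dx, _pearson_at_shift(ref, mov, dy, dx), "fft")
    raise ValueError(f"unknown method {method!r}")


def translate_frame(frame: np.ndarray, dy: int, dx: int,
                    valid: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Integer translation with replicate edge fill.

    Returns the shifted frame and a boolean mask of pixels that carry real
    (non-padded) data; padded pixels must be excluded from downstream
    statistics.
    """
    h, w = frame.shape
    out = frame
    mask = np.ones((h, w), dtype=bool) if valid is None else valid.copy()
    if dy:
        out = np.roll(out, dy, axis=0)
        mask = np.roll(mask, dy, axis=0)
        if dy > 0:
            out = out.copy()
            out[:dy] = out[dy]
            mask[:dy] = False
        else:
            out = out.copy()
            out[dy:] = out[dy - 1]
            mask[dy:] = False
    if dx:
        out = np.roll(out, dx, axis=1)
        mask = np.roll(mask, dx, axis=1)
        if dx > 0:
            out = out.copy()
            out[:, :dx] = out[:, dx:dx + 1]
            mask[:, :dx] = False
        else:
            out = out.copy()
            out[:, dx:] = out[:, dx - 1:dx]
            mask[:, dx:] = False
    return out, mask


def align_stack(stack: FrameStack, reference_frame: np.ndarray | None = None,
                session_boundaries: list[int] | None = None,
                per_session: bool = True, method: str = "fft",
                max_shift: int = 10,
                ) -> tuple[FrameStack, pd.DataFrame, np.ndarray]:
    """Align a (possibly concatenated) stack by integer translations.

    With ``per_session=True`` (the deployed behaviour) one shift is
    estimated per session from its mean frame and applied to all its
    frames; ``per_session=False`` estimates and applies per-frame shifts.
    The reference defaults to the mean frame of the first session.
    ``session_boundaries`` lists the starting frame index of each session
    (defaults to one session spanning the stack).

    Returns the aligned stack, a shift table (session_id, dy, dx,
    peak_corr) and the mask of pixels valid across all frames (edge-filled
    pixels are invalid).
    """
    data = np.asarray(stack.data, dtype=np.float64)
    n_frames = data.shape[0]
    bounds = sorted(session_boundaries or [0])
    if bounds[0] != 0:
        bounds = [0] + bounds
    spans = list(zip(bounds, bounds[1:] + [n_frames]))
    if reference_frame is None:
        reference_frame = data[spans[0][0]:spans[0][1]].mean(axis=0)

    out = np.empty_like(data)
    valid = np.ones(data.shape[1:], dtype=bool)
    rows = []
    for sid, (a, b) in enumerate(spans):
        if per_session:
            est = estimate_shift(reference_frame, data[a:b].mean(axis=0),
                                 method=method, max_shift=max_shift)
            if max(abs(est.dy), abs(est.dx)) >= max_shift:
                raise AlignmentFailureError(
                    f"session {sid}: shift {est.as_tuple()} at max_shift limit")
            rows.append({"session_id": sid, "dy": est.dy, "dx": est.dx,
                         "peak_corr": est.peak_corr})
            for i in range(a, b):
                out[i], m = translate_frame(data[i], -est.dy, -est.dx)
                valid &= m
        else:
            for i in range(a, b):
                est = estimate_shift(reference_frame, data[i],
                                     method=method, max_shift=max_shift)
                rows.append({"session_id": sid, "frame": i, "dy": est.dy,
                             "dx": est.dx, "peak_corr": est.peak_corr})
                out[i], m = translate_frame(data[i], -est.dy, -est.dx)
                valid &= m

    aligned = FrameStack(out, frame_rate_hz=stack.frame_rate_hz, t0=stack.t0,
                         t0_iso=stack.t0_iso, source=stack.source,
                         channel=stack.channel)
    return aligned, pd.DataFrame(rows), valid


def discard_settling(trial_stack: FrameStack, discard_s: float = 1.0,
                     ) -> FrameStack:
    """Drop the leading frames contaminated by mechanical settling.

    Removes ``ceil(discard_s * fps)`` frames and advances the timebase.
    The deployed discard window lies between 0.3 and 3 s; 1 s by default.
    """
    if discard_s < 0:
        raise ValueError("discard_s must be >= 0")
    n_drop = int(np.ceil(discard_s * trial_stack.frame_rate_hz - 1e-9))
    if n_drop >= trial_stack.n_frames:
        raise EmptyTrialError(
            f"discarding {discard_s}s ({n_drop} frames) empties a "
            f"{trial_stack.n_frames}-frame trial")
    if n_drop == 0:
        return trial_stack
    return FrameStack(trial_stack.data[n_drop:],
                      frame_rate_hz=trial_stack.frame_rate_hz,
                      t0=trial_stack.t0 + n_drop / trial_stack.frame_rate_hz,
                      t0_iso=trial_stack.t0_iso, source=trial_stack.source,
                      channel=trial_stack.channel)


def shifts_to_csv(shifts: pd.DataFrame, path) -> None:
    shifts.to_csv(path, index=False)
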