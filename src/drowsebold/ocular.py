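"""Eye-openness scoring from facial landmarks.

This module turns per-frame eye landmarks into the signals the drowsiness
index is built from:

* the eye aspect ratio (EAR) of a six-point eye contour,
  ``EAR = (|p2-p6| + |p3-p5|) / (2 |p1-p4|)``, which is near zero when the
  eye is closed and largest when fully open;
* blink segmentation of the EAR trace (contiguous dips below a rolling
  open-eye baseline);
* participant-wise normalization of the EAR to [0, 1] using the extreme
  values reached within blinks, so the scale is comparable across
  participants with different eye geometry;
* binarization of the normalized EAR into a closure signal
  (closed iff normalized EAR <= threshold, default 0.8).

Landmark ordering follows the usual convention: p1 = lateral corner,
p4 = medial corner, p2/p3 on the upper lid, p6/p5 on the lower lid, so
|p2-p6| and |p3-p5| are vertical lid distances and |p1-p4| the eye width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LANDMARK_COLUMNS",
    "EarTrace",
    "Blink",
    "BlinkSegmentation",
    "ClosureSignal",
    "DegenerateFrameError",
    "NormalizationError",
    "landmark_error",
    "ear_from_landmarks",
    "landmarks_to_ear_trace",
    "segment_blinks",
    "normalize_ear",
    "binarize_closure",
]

#: Column order for landmark tables: x/y for each of the six eye points.
LANDMARK_COLUMNS = [f"p{i}{ax}" for i in range(1, 7) for ax in ("x", "y")]


class DegenerateFrameError(ValueError):
    """A frame whose eye width |p1 - p4| is zero (EAR undefined)."""


class NormalizationError(ValueError):
    """EAR normalization impossible (no blinks, or degenerate extremes)."""


@dataclass
class EarTrace:
    """Per-frame eye aspect ratio.

    ``missing`` flags frames where the EAR could not be computed (degenerate
    landmarks or an externally supplied artefact mask) and could not be
    filled by short-gap interpolation.
    """

    t_s: np.ndarray
    ear: np.ndarray
    fps: float
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.ear = np.asarray(self.ear, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.ear)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.t_s.shape != self.ear.shape:
            raise ValueError("t_s and ear must have the same length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        valid = self.ear[~self.missing]
        if valid.size and np.any(valid < 0):
            raise ValueError("EAR values must be nonnegative")

    def __len__(self) -> int:
        return self.ear.size


@dataclass(frozen=True)
class Blink:
    start_frame: int
    end_frame: int  # exclusive
    ear_min: float
    ear_max: float


@dataclass
class BlinkSegmentation:
    """Non-overlapping, ordered blink intervals with their EAR extremes."""

    blinks: list[Blink]

    def __len__(self) -> int:
        return len(self.blinks)

    def __iter__(self):
        return iter(self.blinks)

    @property
    def global_min(self) -> float:
        return min(b.ear_min for b in self.blinks)

    @property
    def global_max(self) -> float:
        return max(b.ear_max for b in self.blinks)


@dataclass
class ClosureSignal:
    """Binary eye-closure signal: 1 = closed, 0 = open, per frame."""

    t_s: np.ndarray
    closed: np.ndarray
    fps: float

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.closed = np.asarray(self.closed)
        if not np.isin(self.closed, (0, 1)).all():
            raise ValueError("closure signal must be 0/1")
        self.closed = self.closed.astype(np.uint8)

    def __len__(self) -> int:
        return self.closed.size


def landmark_error(predicted, truth) -> float:
    """Mean Euclidean pixel distance between matched landmark sets.

    Parameters are arrays of shape (N, 2) (or anything broadcastable to it)
    with matched ordering.  Returns ``(1/N) * sum_i |p̂_i - p_i|_2``.
    """
    predicted = np.asarray(predicted, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"landmark count mismatch: {predicted.shape[0]} vs {truth.shape[0]}"
        )
    if predicted.shape[0] < 1:
        raise ValueError("need at least one landmark")
    return float(np.linalg.norm(predicted - truth, axis=1).mean())


def ear_from_landmarks(points, on_degenerate: str = "raise"):
    """Eye aspect ratio of one frame or a stack of frames.

    Parameters
    ----------
    points : array-like, shape (..., 6, 2)
        The six eye landmarks (p1..p6) in pixel coordinates.
    on_degenerate : {"raise", "nan"}
        What to do when |p1 - p4| == 0.  ``"nan"`` flags the frame with NaN
        instead of raising, for batch use.

    Returns
    -------
    float or ndarray of shape (...,)

    Notes
    -----
    EAR is invariant to translation, rotation and uniform scaling of the six
    points, since it is a ratio of Euclidean distances.
    """
    p = np.asarray(points, dtype=float)
    if p.shape[-2:] != (6, 2):
        raise ValueError(f"expected landmarks of shape (..., 6, 2), got {p.shape}")
    width = np.linalg.norm(p[..., 0, :] - p[..., 3, :], axis=-1)
    v1 = np.linalg.norm(p[..., 1, :] - p[..., 5, :], axis=-1)
    v2 = np.linalg.norm(p[..., 2, :] - p[..., 4, :], axis=-1)
    degenerate = width == 0
    if np.any(degenerate):
        if on_degenerate == "raise":
            raise DegenerateFrameError("p1 == p4: eye width is zero")
        width = np.where(degenerate, np.nan, width)
    ear = (v1 + v2) / (2.0 * width)
    if ear.ndim == 0:
        return float(ear)
    return ear


def landmarks_to_ear_trace(
    table,
    fps: float | None = None,
    max_gap_s: float = 0.5,
    mask=None,
) -> EarTrace:
    """Compute a per-frame EAR trace from a landmark table.

    Parameters
    ----------
    table : DataFrame with columns ``t_s`` + p1x..p6y, or ndarray (n, 6, 2)
    fps : frames per second; inferred from the median ``t_s`` spacing if None.
    max_gap_s : degenerate/masked frames are linearly interpolated from their
        neighbours when the gap is at most this long; longer gaps stay missing.
    mask : optional boolean per-frame artefact mask (True = discard frame);
        stands in for a manual frame-correction step.
    """
    if isinstance(table, pd.DataFrame):
        missing_cols = [c for c in LANDMARK_COLUMNS if c not in table.columns]
        if missing_cols:
            raise ValueError(f"landmark table lacks columns: {missing_cols}")
        pts = table[LANDMARK_COLUMNS].to_numpy(dtype=float).reshape(-1, 6, 2)
        if "t_s" in table.columns:
            t_s = table["t_s"].to_numpy(dtype=float)
        else:
            if fps is None:
                raise ValueError("fps required when the table has no t_s column")
            t_s = np.arange(len(table)) / fps
    else:
        pts = np.asarray(table, dtype=float)
        if fps is None:
            raise ValueError("fps required for array input")
        t_s = np.arange(pts.shape[0]) / fps
    if fps is None:
        dt = np.median(np.diff(t_s))
        if not dt > 0:
            raise ValueError("cannot infer fps from t_s")
        fps = 1.0 / dt

    ear = ear_from_landmarks(pts, on_degenerate="nan")
    ear = np.atleast_1d(np.asarray(ear, dtype=float))
    if mask is not None:
        ear = np.where(np.asarray(mask, dtype=bool), np.nan, ear)

    bad = ~np.isfinite(ear)
    if bad.any() and not bad.all():
        max_gap = int(round(max_gap_s * fps))
        ear, still_missing = _fill_short_gaps(ear, max_gap)
    else:
        still_missing = bad
    return EarTrace(t_s=t_s, ear=np.where(still_missing, np.nan, ear), fps=fps,
                    missing=still_missing)


def _fill_short_gaps(x: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN runs of length <= max_gap with valid flanks."""
    x = x.copy()
    bad = ~np.isfinite(x)
    missing = bad.copy()
    idx = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):  # bad run is [a, b)
        if (b - a) <= max_gap and a > 0 and b < x.size:
            x[a:b] = np.interp(np.arange(a, b), [a - 1, b], [x[a - 1], x[b]])
            missing[a:b] = False
    return x, missing


def _rolling_open_baseline(
    ear: np.ndarray, fps: float, window_s: float, percentile: float
) -> np.ndarray:
    # Per-second upper percentile, then a rolling max over the window, as a
    # cheap monotone-robust stand-in for a full rolling percentile.
    n = ear.size
    spf = max(int(round(fps)), 1)
    n_blocks = int(np.ceil(n / spf))
    padded = np.full(n_blocks * spf, np.nan)
    padded[:n] = ear
    blocks = padded.reshape(n_blocks, spf)
    with np.errstate(all="ignore"):
        q = np.nanpercentile(blocks, percentile, axis=1)
    half = max(int(round(window_s / 2)), 1)
    base = np.empty(n_blocks)
    for i in range(n_blocks):
        seg = q[max(0, i - half): i + half + 1]
        seg = seg[np.isfinite(seg)]
        base[i] = seg.max() if seg.size else np.nan
    return np.repeat(base, spf)[:n]


def segment_blinks(
    trace: EarTrace,
    drop_frac: float = 0.5,
    baseline_window_s: float = 30.0,
    baseline_percentile: float = 95.0,
    max_extend_s: float = 1.0,
) -> BlinkSegmentation:
    """Segment blinks as contiguous dips of the EAR trace.

    A frame belongs to a dip when its EAR falls below ``drop_frac`` times a
    rolling open-eye baseline (the ``baseline_percentile``-th percentile of
    the EAR over a ``baseline_window_s`` window).  Each dip is extended
    outward to the flanking local maxima (at most ``max_extend_s`` per side)
    and its EAR extremes are recorded for normalization.

    A flat trace yields an empty segmentation; that is not an error.
    """
    if len(trace) < 3:
        raise ValueError("EAR trace too short to segment (need >= 3 frames)")
    ear = trace.ear
    finite = np.isfinite(ear)
    baseline = _rolling_open_baseline(ear, trace.fps, baseline_window_s,
                                      baseline_percentile)
    dip = finite & (ear < drop_frac * baseline)
    if not dip.any():
        return BlinkSegmentation(blinks=[])

    edges = np.flatnonzero(np.diff(np.concatenate(([0], dip.view(np.int8), [0]))))
    max_ext = int(round(max_extend_s * trace.fps))
    blinks: list[Blink] = []
    n = ear.size
    for a, b in zip(edges[::2], edges[1::2]):  # dip run [a, b)
        lo = a
        steps = 0
        while lo > 0 and steps < max_ext and finite[lo - 1] and ear[lo - 1] >= ear[lo]:
            lo -= 1
            steps += 1
        hi = b  # exclusive
        steps = 0
        while hi < n and steps < max_ext and finite[hi] and (
            hi == b or ear[hi] >= ear[hi - 1]
        ):
            hi += 1
            steps += 1
        seg = ear[lo:hi][np.isfinite(ear[lo:hi])]
        blink = Blink(start_frame=int(lo), end_frame=int(hi),
                      ear_min=float(seg.min()), ear_max=float(seg.max()))
        if blinks and blink.start_frame < blinks[-1].end_frame:
            prev = blinks.pop()
            blink = Blink(
                start_frame=prev.start_frame,
                end_frame=max(prev.end_frame, blink.end_frame),
                ear_min=min(prev.ear_min, blink.ear_min),
                ear_max=max(prev.ear_max, blink.ear_max),
            )
        blinks.append(blink)
    return BlinkSegmentation(blinks=blinks)


def normalize_ear(
    trace: EarTrace, blinks: BlinkSegmentation, clamp: bool = True
) -> EarTrace:
    """Rescale an EAR trace to [0, 1] by its blink extremes.

    The trace is mapped through ``(ear - m) / (M - m)`` where ``m`` is the
    minimum EAR within any blink and ``M`` the maximum.  Values outside
    [0, 1] can occur between blinks and are clamped by default so the
    downstream closure threshold stays well defined.
    """
    if len(blinks) == 0:
        raise NormalizationError("no blinks detected: EAR range undefined")
    lo, hi = blinks.global_min, blinks.global_max
    if not hi > lo:
        raise NormalizationError(f"degenerate blink extremes (min={lo}, max={hi})")
    norm = (trace.ear - lo) / (hi - lo)
    if clamp:
        norm = np.clip(norm, 0.0, 1.0)
    return EarTrace(t_s=trace.t_s, ear=norm, fps=trace.fps, missing=trace.missing)


def binarize_closure(norm_trace: EarTrace, threshold: float = 0.8) -> ClosureSignal:
    """Binarize a normalized EAR trace: closed (1) iff EAR <= threshold.

    The boundary is inclusive: a normalized EAR exactly at the threshold
    counts as closed.  Missing frames are treated as open so they never
    fabricate closure time.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    finite = np.isfinite(norm_trace.ear)
    vals = norm_trace.ear[finite]
    if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
        raise ValueError("normalized EAR must lie in [0, 1]; normalize first")
    closed = np.zeros(len(norm_trace), dtype=np.uint8)
    closed[finite & (norm_trace.ear <= threshold)] = 1
    return ClosureSignal(t_s=norm_trace.t_s, closed=closed, fps=norm_trace.fps)
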