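"""PERCLOS and the four-state drowsigram.

PERCLOS is the fraction of frames with closed eyes inside a sliding 60 s
window, evaluated every second (window centres on the integer-second grid).
Each second is then staged:

* ``awake``          0.00 <= PERCLOS < 0.08
* ``likely_drowsy``  0.08 <= PERCLOS < 0.15
* ``drowsy``         0.15 <= PERCLOS <= 1.00
* ``microsleep``     eyes continuously closed for strictly more than 5 s
                     (overrides the PERCLOS class for every overlapping second)

Thresholds are on the fractional scale (0.08 = 8%); boundaries belong to the
higher state. Seconds whose 60 s window is truncated by the recording edges
are marked invalid rather than computed on a partial window, so the window
length is constant everywhere the index is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ocular import ClosureSignal
from .states import (AWAKE, DROWSY, LIKELY_DROWSY, MICROSLEEP, STATE_NAMES,
                     UNDEFINED, codes_to_names)

__all__ = [
    "PerclosSeries",
    "Drowsigram",
    "compute_perclos",
    "detect_microsleep",
    "classify_drowsigram",
    "align_to_volumes",
    "state_occupancy",
]


@dataclass
class PerclosSeries:
    """Sliding-window eye-closure fraction, one value per second."""

    t_s: np.ndarray          # window-centre seconds
    perclos: np.ndarray      # fraction in [0, 1]; NaN where invalid
    window_s: float
    valid: np.ndarray        # full window available

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.perclos = np.asarray(self.perclos, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        ok = self.perclos[self.valid]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("PERCLOS must lie in [0, 1]")

    def __len__(self) -> int:
        return self.t_s.size


@dataclass
class Drowsigram:
    """One drowsiness state per second; UNDEFINED where no state applies."""

    t_s: np.ndarray
    state: np.ndarray  # integer codes; UNDEFINED = -1
    perclos: np.ndarray | None = None

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.state = np.asarray(self.state, dtype=np.int64)

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def defined(self) -> np.ndarray:
        return self.state != UNDEFINED

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_s": self.t_s, "state": codes_to_names(self.state),
                           "valid": self.defined.astype(int)})
        if self.perclos is not None:
            df["perclos"] = self.perclos
        return df


def compute_perclos(
    closure: ClosureSignal, window_s: float = 60.0, step_s: float = 1.0
) -> PerclosSeries:
    """Sliding-window mean of the closure signal on the second grid.

    For the window centred at ``t_k`` the mean runs over the
    ``N = window_s * fps`` frames at indices
    ``i_k - floor(N/2) .. i_k + floor((N-1)/2)`` where ``i_k`` is the frame
    at ``t_k``.  Centres whose window extends past the recording are marked
    invalid.  If the whole recording is shorter than one window, an
    all-invalid series is returned with a warning.
    """
    if len(closure) < 1:
        raise ValueError("empty closure signal")
    fps = closure.fps
    n = len(closure)
    nwin = int(round(window_s * fps))
    if nwin < 1:
        raise ValueError("window shorter than one frame")

    t0 = closure.t_s[0]
    duration = n / fps
    centers = t0 + np.arange(0.0, duration, step_s)
    i_k = np.round((centers - t0) * fps).astype(np.int64)
    lo = i_k - nwin // 2
    hi = i_k + (nwin - 1) // 2 + 1  # exclusive
    valid = (lo >= 0) & (hi <= n)

    csum = np.concatenate(([0], np.cumsum(closure.closed, dtype=np.int64)))
    perclos = np.full(centers.size, np.nan)
    perclos[valid] = (csum[hi[valid]] - csum[lo[valid]]) / nwin
    if not valid.any():
        warnings.warn(
            f"recording ({duration:.1f} s) shorter than the {window_s:.0f} s "
            "window: PERCLOS undefined everywhere",
            stacklevel=2,
        )
    return PerclosSeries(t_s=centers, perclos=perclos, window_s=window_s, valid=valid)


def detect_microsleep(
    closure: ClosureSignal, min_duration_s: float = 5.0
) -> list[tuple[float, float]]:
    """Maximal closure runs strictly longer than ``min_duration_s`` seconds.

    Returns ``(start_s, end_s)`` intervals relative to the recording clock.
    A run of exactly ``min_duration_s`` does not qualify.
    """
    closed = closure.closed.astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], closed, [0]))))
    runs = []
    t0 = closure.t_s[0]
    for a, b in zip(edges[::2], edges[1::2]):
        dur = (b - a) / closure.fps
        if dur > min_duration_s:
            runs.append((t0 + a / closure.fps, t0 + b / closure.fps))
    return runs


def classify_drowsigram(
    perclos: PerclosSeries,
    microsleep_runs: list[tuple[float, float]] | None = None,
    thresholds: tuple[float, float] = (0.08, 0.15),
) -> Drowsigram:
    """Stage each second from its PERCLOS value plus the microsleep override.

    Any second overlapping a qualifying closure run is labelled microsleep,
    regardless of PERCLOS (and even where PERCLOS itself is invalid).
    Remaining valid seconds are thresholded with inclusive lower boundaries;
    PERCLOS = 1.0 belongs to drowsy.
    """
    lo_t, hi_t = thresholds
    if not 0.0 < lo_t < hi_t < 1.0:
        raise ValueError(f"bad thresholds {thresholds}")
    vals = perclos.perclos[perclos.valid]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("PERCLOS outside [0, 1]")

    state = np.full(len(perclos), UNDEFINED, dtype=np.int64)
    v = perclos.valid
    p = perclos.perclos
    state[v & (p < lo_t)] = AWAKE
    state[v & (p >= lo_t) & (p < hi_t)] = LIKELY_DROWSY
    state[v & (p >= hi_t)] = DROWSY

    for start, end in microsleep_runs or []:
        # a second k covers [t_k, t_k + 1)
        overlap = (perclos.t_s < end) & (perclos.t_s + 1.0 > start)
        state[overlap] = MICROSLEEP
    return Drowsigram(t_s=perclos.t_s, state=state, perclos=perclos.perclos)


def align_to_volumes(
    d: Drowsigram, n_volumes: int, tr_s: float = 1.0, offset_s: float = 0.0
) -> np.ndarray:
    """Nearest-centre drowsigram label for each fMRI volume.

    Volume ``i`` is timestamped ``offset_s + i * tr_s``; the nearest
    drowsigram second supplies its label.  Volumes falling more than one
    label spacing outside the drowsigram raise; volumes at seconds with no
    defined state come back UNDEFINED (excluded downstream).
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    times = offset_s + np.arange(n_volumes) * tr_s
    if times[0] < d.t_s[0] - 1.0 or times[-1] > d.t_s[-1] + 1.0:
        raise ValueError("volume times extend beyond the drowsigram")
    idx = np.clip(np.round(times - d.t_s[0]).astype(np.int64), 0, len(d) - 1)
    return d.state[idx]


def state_occupancy(d: Drowsigram) -> pd.Series:
    """Fraction of defined seconds spent in each state (sums to 1)."""
    defined = d.state[d.defined]
    if defined.size == 0:
        raise ValueError("drowsigram has no defined seconds")
    counts = np.bincount(defined, minlength=len(STATE_NAMES))
    return pd.Series(counts / defined.size, index=list(STATE_NAMES), name="occupancy")
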