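"""Multitaper spectral estimation of ROI time series and state segregation.

The central estimator is a DPSS (Slepian) multitaper spectrogram with the
configuration used throughout the package: 60 s windows stepped by 1 s,
time-half-bandwidth NW = 2.5, K = 4 tapers, NFFT = 64, linear detrend per
window.  At a 1 s sampling interval this yields a one-sided grid of 33
frequencies spanning 0-0.5 Hz with a spacing of 1/64 Hz (0.016 Hz after
rounding); the first six inter-bin bands cover 0-0.1 Hz, and the band
]0.047, 0.063] is the one containing 0.05 Hz, the oscillation of interest.

Spectrogram columns are indexed by window centre on the same second grid as
PERCLOS, so each column can be matched to the drowsiness state at its
centre and per-state mean spectra accumulated per (participant, ROI).

PSD convention: one-sided density, normalized by the sampling rate and the
taper energy (tapers have unit energy), interior bins doubled.  Any fixed
convention would do for the downstream statistics, which only ever compare
like with like; the convention used is recorded in the spectrogram params.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss as _dpss

from .states import STATE_NAMES, UNDEFINED

__all__ = [
    "MultitaperSpectrogram",
    "band_grid",
    "band_containing",
    "dct_highpass_basis",
    "regress_confounds",
    "multitaper_spectrogram",
    "segregate_by_state",
    "extract_psd005",
    "participant_average",
    "state_psd_table",
    "PSD005_BAND_INDEX",
]

#: Index of the frequency band containing 0.05 Hz on the default grid
#: (fs = 1 Hz, NFFT = 64): band 4 = ]0.046875, 0.0625], printed ]0.047, 0.063].
PSD005_BAND_INDEX = 4


@dataclass
class MultitaperSpectrogram:
    """Frequency x window-time power matrix (optionally per ROI).

    ``power`` has shape (n_freq, n_windows) for a single series or
    (n_roi, n_freq, n_windows) for a matrix input.
    """

    freqs: np.ndarray
    t_s: np.ndarray
    power: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def band_grid(nfft: int = 64, fs: float = 1.0) -> pd.DataFrame:
    """One-sided frequency grid and the inter-bin bands it induces.

    Grid points are ``f_j = j * fs / nfft`` for ``j = 0 .. nfft/2``; band
    ``j`` (j >= 1) is the half-open interval ``]f_{j-1}, f_j]``.  The label
    column rounds edges to three decimals, matching how the bands are
    conventionally printed (e.g. ``]0.047, 0.063]``).
    """
    if nfft % 2:
        raise ValueError("nfft must be even")
    j = np.arange(nfft // 2 + 1)
    f = j * fs / nfft
    df = pd.DataFrame({"band": j, "freq": f})
    df["lo"] = np.concatenate(([np.nan], f[:-1]))
    df["hi"] = np.where(j == 0, 0.0, f)
    df["label"] = [
        "DC" if jj == 0 else f"]{_round3(lo)}, {_round3(hi)}]"
        for jj, lo, hi in zip(j, df["lo"], df["hi"])
    ]
    return df


def _round3(x: float) -> str:
    """Round half away from zero to 3 decimals (0.0625 prints as 0.063)."""
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def band_containing(freq_hz: float, nfft: int = 64, fs: float = 1.0) -> int:
    """Index j of the band ]f_{j-1}, f_j] containing ``freq_hz``."""
    if not 0 < freq_hz <= fs / 2:
        raise ValueError(f"{freq_hz} Hz outside the one-sided range")
    return int(np.ceil(freq_hz * nfft / fs - 1e-12))


def dct_highpass_basis(
    n_samples: int, tr_s: float = 1.0, cutoff_hz: float = 0.01
) -> pd.DataFrame:
    """Discrete-cosine drift regressors equivalent to a high-pass filter.

    Returns the ``floor(2 * n * tr * cutoff)`` lowest-frequency type-II DCT
    columns, i.e. the cosines whose period exceeds ``1 / cutoff_hz``.  The
    columns are orthonormal.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    n_cols = int(np.floor(2 * n_samples * tr_s * cutoff_hz))
    t = np.arange(n_samples)
    cols = {}
    for k in range(1, n_cols + 1):
        c = np.cos(np.pi * k * (2 * t + 1) / (2 * n_samples))
        cols[f"cosine{k:02d}"] = c / np.linalg.norm(c)
    return pd.DataFrame(cols)


def regress_confounds(values: np.ndarray, confounds) -> np.ndarray:
    """Residualize each row of ``values`` on an intercept plus confounds.

    ``values`` is (n_roi, n_time) or (n_time,); ``confounds`` a DataFrame or
    array of shape (n_time, p), or None for demeaning only.  Residuals are
    orthogonal to every regressor.  A rank-deficient design raises with the
    offending columns named.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_time = values.shape[1]
    names = None
    if confounds is None:
        X = np.ones((n_time, 1))
    else:
        if isinstance(confounds, pd.DataFrame):
            names = list(confounds.columns)
            C = confounds.to_numpy(dtype=float)
        else:
            C = np.asarray(confounds, dtype=float)
        if C.shape[0] != n_time:
            raise ValueError(
                f"confound length {C.shape[0]} != series length {n_time}"
            )
        X = np.column_stack([np.ones(n_time), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            bad = _collinear_columns(X, names)
            raise ValueError(f"rank-deficient confound design; suspects: {bad}")
    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    resid = values - (X @ beta).T
    return resid if np.asarray(values).ndim > 1 else resid[0]


def _collinear_columns(X: np.ndarray, names: list[str] | None) -> list[str]:
    # QR with pivoting: columns beyond the numerical rank are the suspects.
    from scipy.linalg import qr

    _, R, piv = qr(X, pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    bad_idx = sorted(piv[rank:])
    labels = ["intercept"] + (names or [f"col{i}" for i in range(1, X.shape[1])])
    return [labels[i] for i in bad_idx]


def _dpss_tapers(nwin: int, nw: float, k: int) -> np.ndarray:
    if k > 2 * nw - 1:
        raise ValueError(f"k = {k} tapers exceeds 2*NW - 1 = {2 * nw - 1}")
    tapers = _dpss(nwin, nw, Kmax=k)
    return tapers / np.linalg.norm(tapers, axis=1, keepdims=True)


def multitaper_spectrogram(
    series: np.ndarray,
    fs: float = 1.0,
    window_s: float = 60.0,
    step_s: float = 1.0,
    nw: float = 2.5,
    k_tapers: int = 4,
    nfft: int = 64,
    detrend: str = "linear",
    t0_s: float = 0.0,
) -> MultitaperSpectrogram:
    """DPSS multitaper spectrogram of one series or an ROI x time matrix.

    Each length-``window_s * fs`` window is linearly detrended, multiplied
    by each of ``k_tapers`` unit-energy Slepian tapers (time-half-bandwidth
    ``nw``), zero-padded to ``nfft`` and Fourier transformed; the K one-sided
    eigenspectra are averaged with uniform weights.  Columns are timestamped
    at ``t0_s + start + floor(window/2) / fs`` so they land on the same
    centre grid as the eye-closure index.
    """
    x = np.asarray(series, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values; clean first")
    nwin = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if step < 1:
        raise ValueError("step must be at least one sample")
    n = x.shape[1]
    if n < nwin:
        raise ValueError(f"series ({n} samples) shorter than window ({nwin})")
    tapers = _dpss_tapers(nwin, nw, k_tapers)

    win = np.lib.stride_tricks.sliding_window_view(x, nwin, axis=1)[:, ::step, :]
    # (n_roi, n_windows, nwin)
    if detrend == "linear":
        t = np.arange(nwin, dtype=float)
        D = np.column_stack([np.ones(nwin), t - t.mean()])
        proj = D @ np.linalg.inv(D.T @ D) @ D.T
        win = win - win @ proj.T
    elif detrend == "constant":
        win = win - win.mean(axis=-1, keepdims=True)
    elif detrend not in (None, "none"):
        raise ValueError(f"unknown detrend {detrend!r}")

    n_freq = nfft // 2 + 1
    power = np.zeros((x.shape[0], win.shape[1], n_freq))
    for taper in tapers:
        spec = np.fft.rfft(win * taper, n=nfft, axis=-1)
        power += spec.real**2 + spec.imag**2
    power /= k_tapers * fs
    scale = np.full(n_freq, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    power *= scale
    power = np.transpose(power, (0, 2, 1))  # (roi, freq, window)

    freqs = np.arange(n_freq) * fs / nfft
    centers = t0_s + (np.arange(win.shape[1]) * step + nwin // 2) / fs
    params = dict(window_s=window_s, step_s=step_s, nw=nw, k_tapers=k_tapers,
                  nfft=nfft, detrend=detrend, fs=fs,
                  convention="one-sided density, uniform taper average")
    return MultitaperSpectrogram(freqs=freqs, t_s=centers,
                                 power=power[0] if single else power,
                                 params=params)


def segregate_by_state(
    spec: MultitaperSpectrogram, label_t_s: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Average spectrogram columns by the drowsiness state at their centre.

    ``labels`` are integer state codes on the 1 Hz grid ``label_t_s``;
    columns whose centre has no defined label are dropped.  Returns one row
    per state actually present with the row-wise mean spectrum and the
    number of contributing windows; states with zero columns are omitted.
    """
    power = spec.power
    if power.ndim != 2:
        raise ValueError("segregate one ROI at a time (2-D power matrix)")
    label_t_s = np.asarray(label_t_s, dtype=float)
    labels = np.asarray(labels)
    idx = np.round(spec.t_s - label_t_s[0]).astype(np.int64)
    in_range = (idx >= 0) & (idx < labels.size)
    col_labels = np.full(spec.t_s.size, UNDEFINED, dtype=np.int64)
    col_labels[in_range] = labels[idx[in_range]]
    keep = col_labels != UNDEFINED
    if not keep.any():
        raise ValueError("no spectrogram column has a defined state label")

    rows = []
    for code, name in enumerate(STATE_NAMES):
        sel = keep & (col_labels == code)
        if not sel.any():
            continue
        rows.append({"state": name, "n_windows": int(sel.sum()),
                     **{f"band_{j}": m for j, m in
                        enumerate(power[:, sel].mean(axis=1))}})
    return pd.DataFrame(rows)


def extract_psd005(
    rows: pd.DataFrame, band_index: int = PSD005_BAND_INDEX
) -> pd.DataFrame:
    """Attach the 0.05 Hz band power (band 4 of the default grid) as psd005."""
    col = f"band_{band_index}"
    if col not in rows.columns:
        raise ValueError(f"band column {col!r} missing from state table")
    out = rows.copy()
    out["psd005"] = out[col]
    return out


def participant_average(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean spectrum per state over the participants holding it."""
    band_cols = [c for c in table.columns if c.startswith("band_") or c == "psd005"]
    return (table.groupby("state", sort=False)[band_cols]
            .mean().reset_index())


def state_psd_table(
    spec: MultitaperSpectrogram,
    label_t_s: np.ndarray,
    labels: np.ndarray,
    roi_ids,
    participant: str,
    atlas: pd.DataFrame | None = None,
    band_index: int = PSD005_BAND_INDEX,
) -> pd.DataFrame:
    """Long-format per-(participant, ROI, state) band-power table.

    ``spec.power`` must be the 3-D (roi, freq, window) stack for one
    participant; ``atlas`` (roi_id -> network) adds a network column.
    """
    if spec.power.ndim != 3:
        raise ValueError("expected an ROI-stacked spectrogram")
    label_t_s = np.asarray(label_t_s, dtype=float)
    labels = np.asarray(labels)
    idx = np.round(spec.t_s - label_t_s[0]).astype(np.int64)
    in_range = (idx >= 0) & (idx < labels.size)
    col_labels = np.full(spec.t_s.size, UNDEFINED, dtype=np.int64)
    col_labels[in_range] = labels[idx[in_range]]
    if not (col_labels != UNDEFINED).any():
        raise ValueError("no spectrogram column has a defined state label")

    net = None
    if atlas is not None:
        net = atlas.set_index("roi_id")["network"]
    n_roi, n_freq, _ = spec.power.shape
    frames = []
    for code, name in enumerate(STATE_NAMES):
        sel = col_labels == code
        if not sel.any():
            continue
        means = spec.power[:, :, sel].mean(axis=2)  # (n_roi, n_freq)
        rows = pd.DataFrame(means, columns=[f"band_{j}" for j in range(n_freq)])
        rows.insert(0, "n_windows", int(sel.sum()))
        rows.insert(0, "state", name)
        rows.insert(0, "roi", list(roi_ids))
        rows.insert(0, "participant", participant)
        if net is not None:
            rows.insert(2, "network",
                        [net.get(r, "unknown") for r in roi_ids])
        frames.append(rows)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["roi", "state"], kind="stable",
                          key=lambda s: s if s.name != "state"
                          else s.map({n: i for i, n in enumerate(STATE_NAMES)}))
    return extract_psd005(out.reset_index(drop=True), band_index)
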