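"""Synthetic participants with known vigilance dynamics, eyelid traces and
BOLD oscillations.

The generator provides the ground-truth surface every downstream stage is
validated against:

* a semi-Markov latent vigilance-state sequence over the four drowsigram
  states (exponential dwell times, configurable transition weights;
  microsleep dwells are kept strictly above the 5 s detection threshold so
  they remain recoverable);
* an eyelid (EAR) trace consistent with each state — brief full-closure
  blinks while awake, additional partial/longer closures in the drowsy
  states tuned so the windowed closure index lands in the intended staging
  band, continuous closure during microsleep — together with a six-point
  landmark table constructed so the EAR formula applied to the landmarks
  reproduces the trace exactly;
* ROI x time BOLD matrices: unit-variance AR(1) (or white) noise plus a
  band-limited oscillation at 0.05 Hz whose amplitude tracks the concurrent
  latent state for ROIs in the effect-carrying networks.

Effect sizes are specified as standardized offsets (Cohen's d units,
relative to awake) of the participant-level 0.05 Hz band power, and the
oscillation amplitudes realizing them are calibrated post hoc from a pilot
simulation, with a correction for the state mixing induced by the 60 s
analysis windows (taper-energy-weighted window occupancy).  A lognormal
between-participant power scale makes the per-participant band power
strongly correlated across states, as in real BOLD data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .ocular import LANDMARK_COLUMNS, EarTrace
from .spectral import PSD005_BAND_INDEX, _dpss_tapers, multitaper_spectrogram
from .states import (AWAKE, MICROSLEEP, NETWORK_NAMES, STATE_NAMES,
                     names_to_codes)

__all__ = [
    "SimulationConfig",
    "LatentStateSequence",
    "SimulatedParticipant",
    "SimulatedDataset",
    "simulate_state_sequence",
    "simulate_ear_and_landmarks",
    "simulate_bold",
    "calibrate_amplitudes",
    "simulate_dataset",
    "simulate_null_psd_table",
]

_EYE_WIDTH_PX = 4.0  # template eye width; EAR is scale-free so any value works


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a 45 min eyes-open resting recording at TR = 1 s with a
    25 fps eye camera: dwell means and transition weights give roughly one
    third of the time awake and about a fifth in microsleep, blinks at
    10/min while awake, and standardized 0.05 Hz power offsets in the visual
    and somatomotor networks in the 0.2-0.5 range across the drowsiness
    ladder.
    """

    n_participants: int = 41
    duration_s: float = 2700.0
    fps: float = 25.0
    tr_s: float = 1.0
    #: mean dwell time per state, seconds (awake, likely, drowsy, microsleep)
    state_dwell_means: tuple[float, float, float, float] = (100.0, 45.0, 45.0, 45.0)
    #: 4x4 nonnegative transition weights, zero diagonal, row-normalized on use
    state_transition_weights: tuple[tuple[float, ...], ...] = (
        (0.0, 3.0, 1.0, 0.0),
        (2.0, 0.0, 3.0, 1.0),
        (0.5, 2.0, 0.0, 3.0),
        (1.0, 1.0, 2.0, 0.0),
    )
    blink_rate_awake: float = 10.0            # blinks / minute (non-microsleep states)
    #: per-second probability of starting a partial closure, by state
    partial_closure_prob_by_state: tuple[float, ...] = (0.0, 0.29, 0.19, 0.0)
    #: duration of a partial closure, seconds, by state
    partial_closure_dur_s: tuple[float, ...] = (0.0, 0.2, 1.5, 0.0)
    blink_dur_s: float = 0.2
    open_ear: float = 0.32
    open_ear_noise_sd: float = 0.004
    osc_freq_hz: float = 0.05
    #: standardized psd005 offsets relative to awake, per network group
    effect_d_by_group: dict = field(default_factory=lambda: {
        "visual": (0.0, 0.10, 0.45, 0.55),
        "somatomotor": (0.0, 0.27, 0.35, 0.45),
    })
    noise_model: str = "ar1"                  # "white" | "ar1"
    ar1_rho: float = 0.3
    #: SD of the lognormal between-participant BOLD power scale (log units)
    participant_power_sd: float = 0.3
    fraction_report_no_sleep: float = 0.22
    no_sleep_awake_dwell_factor: float = 2.5
    no_sleep_microsleep_dwell_factor: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.duration_s, self.fps, self.tr_s) <= 0:
            raise ValueError("durations and rates must be positive")
        if self.fps < 5:
            raise ValueError("camera rate below 5 fps cannot resolve blinks")
        if len(self.state_dwell_means) != 4 or min(self.state_dwell_means) <= 0:
            raise ValueError("need 4 positive dwell means")
        W = np.asarray(self.state_transition_weights, dtype=float)
        if W.shape != (4, 4) or (W < 0).any() or np.diag(W).any():
            raise ValueError("transition weights must be 4x4, nonnegative, zero diagonal")
        if (W.sum(axis=1) == 0).any():
            raise ValueError("each transition-weight row needs a positive off-diagonal entry")
        probs = self.partial_closure_prob_by_state
        if len(probs) != 4 or any(not 0 <= p <= 1 for p in probs):
            raise ValueError("partial-closure probabilities must be 4 values in [0, 1]")
        for group in self.effect_d_by_group:
            if group not in NETWORK_NAMES:
                raise ValueError(f"unknown ROI group {group!r} in effect table")


@dataclass
class LatentStateSequence:
    """Ground-truth vigilance states: 1 Hz labels plus dwell segments."""

    labels: np.ndarray                       # int codes at 1 Hz
    segments: list[tuple[int, float, float]]  # (state, start_s, end_s)
    duration_s: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        ends = [seg[2] for seg in self.segments]
        starts = [seg[1] for seg in self.segments]
        if starts and (starts[0] != 0.0 or not np.isclose(ends[-1], self.duration_s)
                       or any(not np.isclose(a, b) for a, b in zip(ends[:-1], starts[1:]))):
            raise ValueError("segments must partition [0, duration_s)")

    def occupancy(self) -> np.ndarray:
        counts = np.bincount(self.labels, minlength=4)
        return counts / self.labels.size

    def transition_times(self) -> np.ndarray:
        return np.array([seg[1] for seg in self.segments[1:]])


def simulate_state_sequence(
    config: SimulationConfig, rng: np.random.Generator
) -> LatentStateSequence:
    """Semi-Markov state sequence with exponential dwell times.

    Dwells are rounded to whole seconds (>= 1 s); microsleep dwells are
    drawn as 6 + Exp so every microsleep segment exceeds the 5 s detection
    threshold.  The sequence starts awake.
    """
    T = int(round(config.duration_s))
    W = np.asarray(config.state_transition_weights, dtype=float)
    P = W / W.sum(axis=1, keepdims=True)
    dwell_means = np.asarray(config.state_dwell_means, dtype=float)

    labels = np.empty(T, dtype=np.int64)
    segments: list[tuple[int, float, float]] = []
    t = 0
    state = AWAKE
    while t < T:
        if state == MICROSLEEP:
            excess = max(dwell_means[MICROSLEEP] - 6.0, 1.0)
            dwell = 6 + int(round(rng.exponential(excess)))
            if T - t < 6:
                # a truncated tail could not satisfy the > 5 s invariant
                state = int(rng.choice(4, p=P[state]))
                continue
        else:
            dwell = max(int(round(rng.exponential(dwell_means[state]))), 1)
        end = min(t + dwell, T)
        labels[t:end] = state
        segments.append((state, float(t), float(end)))
        t = end
        state = int(rng.choice(4, p=P[state]))
    return LatentStateSequence(labels=labels, segments=segments,
                               duration_s=float(T))


def simulate_ear_and_landmarks(
    states: LatentStateSequence,
    config: SimulationConfig,
    rng: np.random.Generator,
    return_landmarks: bool = True,
) -> tuple[EarTrace, pd.DataFrame | None]:
    """Eyelid trace and landmark table consistent with the latent states.

    Blinks are short square dips to a near-zero EAR; partial closures are
    state-dependent longer dips; microsleep segments hold the eye closed
    throughout.  Landmarks place the six points on a template eye polygon
    (width 4 px, vertical pairs at ``EAR * width / 2``) plus a common
    per-frame translation jitter, so the EAR formula applied to them
    returns the trace exactly.
    """
    fps = config.fps
    n_frames = int(round(states.duration_s * fps))
    if n_frames < 1:
        raise ValueError("duration/fps mismatch: no frames to generate")
    t = np.arange(n_frames) / fps
    ear = config.open_ear + rng.normal(0.0, config.open_ear_noise_sd, n_frames)
    ear = np.clip(ear, 0.15, None)

    probs = np.asarray(config.partial_closure_prob_by_state)
    durs = np.asarray(config.partial_closure_dur_s)
    p_blink = config.blink_rate_awake / 60.0

    events: list[tuple[float, float, float]] = []  # (start_s, dur_s, depth)
    n_blinks = 0
    for sec, s in enumerate(states.labels):
        if s == MICROSLEEP:
            continue
        if rng.random() < p_blink:
            start = sec + rng.random()
            dur = max(config.blink_dur_s + rng.normal(0.0, 0.03), 2.0 / fps)
            events.append((start, dur, rng.uniform(0.02, 0.06)))
            n_blinks += 1
        if probs[s] > 0 and rng.random() < probs[s]:
            start = sec + rng.random()
            dur = max(durs[s] * rng.uniform(0.85, 1.15), 2.0 / fps)
            events.append((start, dur, rng.uniform(0.03, 0.08)))
    if n_blinks == 0:
        events.append((1.0, config.blink_dur_s, 0.02))

    for start, dur, depth in events:
        a = int(np.floor(start * fps))
        b = min(int(np.ceil((start + dur) * fps)), n_frames)
        if a < n_frames:
            ear[a:b] = np.minimum(ear[a:b], depth)
    for s, start, end in states.segments:
        if s == MICROSLEEP:
            a, b = int(round(start * fps)), int(round(end * fps))
            ear[a:b] = 0.03

    trace = EarTrace(t_s=t, ear=ear, fps=fps)
    landmarks = None
    if return_landmarks:
        landmarks = _landmarks_from_ear(trace, rng)
    return trace, landmarks


def _landmarks_from_ear(trace: EarTrace, rng: np.random.Generator) -> pd.DataFrame:
    n = len(trace)
    w = _EYE_WIDTH_PX
    v = trace.ear * (w / 2.0)
    offset = rng.normal(0.0, 2.0, size=(n, 2))  # rigid per-frame jitter
    pts = np.empty((n, 6, 2))
    pts[:, 0] = [0.0, 0.0]
    pts[:, 3] = [w, 0.0]
    pts[:, 1, 0] = w / 4.0
    pts[:, 1, 1] = v
    pts[:, 5, 0] = w / 4.0
    pts[:, 5, 1] = -v
    pts[:, 2, 0] = 3.0 * w / 4.0
    pts[:, 2, 1] = v
    pts[:, 4, 0] = 3.0 * w / 4.0
    pts[:, 4, 1] = -v
    pts += offset[:, None, :]
    df = pd.DataFrame(pts.reshape(n, 12), columns=LANDMARK_COLUMNS)
    df.insert(0, "t_s", trace.t_s)
    df.insert(0, "frame", np.arange(n))
    return df


def _ar1(rng: np.random.Generator, shape, rho: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) noise along the last axis."""
    eps = rng.standard_normal(shape)
    if rho == 0:
        return eps
    x = lfilter([1.0], [1.0, -rho], eps * np.sqrt(1 - rho**2), axis=-1)
    # burn-in replacement: draw the stationary start explicitly
    x[..., 0] = eps[..., 0]
    return x


def simulate_bold(
    states: LatentStateSequence,
    config: SimulationConfig,
    atlas: pd.DataFrame,
    rng: np.random.Generator,
    amplitudes: dict[str, np.ndarray] | None = None,
    power_scale: float = 1.0,
) -> np.ndarray:
    """ROI x time BOLD matrix whose 0.05 Hz power tracks the latent state.

    ``amplitudes`` maps network group -> per-state oscillation amplitude
    (from :func:`calibrate_amplitudes`); ROIs in unlisted networks carry no
    oscillation.  ``power_scale`` is the participant's overall signal scale
    (applied to noise and oscillation alike, so relative band power is
    preserved).
    """
    for group in (amplitudes or {}):
        if group not in NETWORK_NAMES:
            raise ValueError(f"unknown ROI group {group!r} in effect table")
    n_vol = int(round(states.duration_s / config.tr_s))
    n_roi = len(atlas)
    t = np.arange(n_vol) * config.tr_s
    sec = np.minimum(t.astype(np.int64), states.labels.size - 1)
    vol_state = states.labels[sec]

    if config.noise_model == "white":
        noise = rng.standard_normal((n_roi, n_vol))
    elif config.noise_model == "ar1":
        noise = _ar1(rng, (n_roi, n_vol), config.ar1_rho)
    else:
        raise ValueError(f"unknown noise model {config.noise_model!r}")

    signal = noise
    if amplitudes:
        phases = rng.uniform(0, 2 * np.pi, n_roi)
        carrier = np.sin(2 * np.pi * config.osc_freq_hz * t[None, :]
                         + phases[:, None])
        amp = np.zeros((n_roi, n_vol))
        networks = atlas["network"].to_numpy()
        for group, a_states in amplitudes.items():
            sel = networks == group
            if sel.any():
                amp[sel] = np.asarray(a_states)[vol_state][None, :]
        signal = noise + amp * carrier
    return power_scale * signal


def _window_weights(window_s: int = 60, nw: float = 2.5, k: int = 4) -> np.ndarray:
    tapers = _dpss_tapers(window_s, nw, k)
    w = (tapers**2).mean(axis=0)
    return w / w.sum()


def state_mixing_matrix(
    center_labels: list[np.ndarray],
    window_labels: list[np.ndarray] | None = None,
    window_s: int = 60,
) -> np.ndarray:
    """Mean taper-weighted window occupancy of each state, by centre label.

    Entry (s, s') is the expected fraction of (taper-energy-weighted) window
    time spent in state s' (per ``window_labels``, e.g. the latent states
    driving the oscillation amplitude) for analysis windows whose centre
    second is labelled s (per ``center_labels``, e.g. the recovered
    drowsigram used to segregate spectrogram columns).  Both are lists of
    per-participant 1 Hz code arrays; undefined centre labels are skipped.
    Rows for states never observed fall back to the identity.
    """
    if window_labels is None:
        window_labels = center_labels
    w = _window_weights(window_s)
    half = window_s // 2
    M = np.zeros((4, 4))
    counts = np.zeros(4)
    for centers_full, wlabels in zip(center_labels, window_labels):
        if wlabels.size < window_s:
            continue
        onehot = (wlabels[None, :] == np.arange(4)[:, None]).astype(float)
        occ = np.stack([np.convolve(row, w[::-1], mode="valid") for row in onehot])
        centers = centers_full[half: half + occ.shape[1]]
        for s in range(4):
            sel = centers == s
            if sel.any():
                M[s] += occ[:, sel].sum(axis=1)
                counts[s] += sel.sum()
    for s in range(4):
        if counts[s] > 0:
            M[s] /= counts[s]
        else:
            M[s, s] = 1.0
    return M


def calibrate_amplitudes(
    config: SimulationConfig,
    sequences: list[LatentStateSequence],
    rng: np.random.Generator,
    n_pilot: int = 32,
    measure_labels: list[np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Oscillation amplitudes realizing the requested standardized offsets.

    A pilot simulation measures, under the configured noise and
    between-participant power model, the participant-level mean and SD of
    the 0.05 Hz band power without oscillation and the power added by a
    unit-amplitude oscillation.  The requested per-state offsets (Cohen's d
    units) are converted to power increments, corrected for (i) the state
    mixing of 60 s windows via :func:`state_mixing_matrix` and (ii) the SD
    inflation that added power itself causes, mapped back to amplitudes, and
    finally rescaled against a closed-loop verification run so the contrast
    delivered through the full windowing/segregation procedure matches the
    request.  ``measure_labels`` supplies the per-participant label arrays
    the analysis will segregate with (e.g. the recovered drowsigram);
    defaults to the latent labels.
    """
    if not config.effect_d_by_group:
        return {}
    L = max(int(round(config.duration_s / 4)), 120)
    fs = 1.0 / config.tr_s
    t = np.arange(L) * config.tr_s
    psd0 = np.empty(n_pilot)
    psd1 = np.empty(n_pilot)
    for i in range(n_pilot):
        scale = np.exp(rng.normal(0.0, config.participant_power_sd))
        if config.noise_model == "ar1":
            noise = _ar1(rng, (L,), config.ar1_rho)
        else:
            noise = rng.standard_normal(L)
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * config.osc_freq_hz * t + phase)
        for which, series in ((0, scale * noise),
                              (1, scale * (noise + carrier))):
            spec = multitaper_spectrogram(series, fs=fs)
            val = spec.power[PSD005_BAND_INDEX].mean()
            (psd0 if which == 0 else psd1)[i] = val
    mu0 = psd0.mean()
    sigma0 = psd0.std(ddof=1)
    c_unit = (psd1 - psd0).mean()
    if c_unit <= 0:
        raise RuntimeError("pilot calibration failed: no power response")

    latent = [seq.labels for seq in sequences]
    if measure_labels is None:
        measure_labels = latent
    M = state_mixing_matrix(measure_labels, latent)
    out: dict[str, np.ndarray] = {}
    for group, deltas in config.effect_d_by_group.items():
        deltas = np.asarray(deltas, dtype=float)
        # M is row-stochastic, so adding a constant to the per-state powers
        # adds the same constant to every observed state mean and leaves all
        # pairwise contrasts intact; shifting the exact solution nonnegative
        # therefore preserves the targeted d values (and gives every state a
        # baseline oscillation, strongest when drowsy).
        u = np.zeros(4)
        for _ in range(3):
            # the power offsets themselves inflate the SD they are measured
            # against (participant scale multiplies signal and noise alike)
            sigma_ref = sigma0 * (mu0 + u.mean()) / mu0
            u = np.linalg.lstsq(M, deltas * sigma_ref, rcond=None)[0]
            u -= u.min()
        # closed-loop verification: measure the d actually realized through
        # 60 s windows on the cohort's own state sequences and rescale the
        # power offsets proportionally (d is linear in the offsets)
        lo_s, hi_s = int(np.argmin(deltas)), int(np.argmax(deltas))
        target_d = deltas[hi_s] - deltas[lo_s]
        if target_d > 0:
            realized = _realized_pair_d(np.sqrt(u / c_unit), (lo_s, hi_s),
                                        sequences, measure_labels, config, rng)
            if realized > 0.02:
                u *= target_d / realized
        out[group] = np.sqrt(u / c_unit)
    return out


def _realized_pair_d(
    amps: np.ndarray,
    pair: tuple[int, int],
    sequences: list[LatentStateSequence],
    measure_labels: list[np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    n_replicates: int = 12,
) -> float:
    """Cohen's d between two states delivered by a candidate amplitude set.

    Simulates ``n_replicates`` independent effect-carrying series per latent
    sequence (amplitude driven by the latent states), runs the spectrogram,
    and measures the standardized participant-level band-power contrast by
    segregating columns with ``measure_labels`` — the same labels the
    analysis itself will use.
    """
    fs = 1.0 / config.tr_s
    vals_a, vals_b = [], []
    for seq, mlab in zip(sequences, measure_labels):
        n_vol = int(round(seq.duration_s / config.tr_s))
        t = np.arange(n_vol) * config.tr_s
        sec = np.minimum(t.astype(np.int64), seq.labels.size - 1)
        amp_t = amps[seq.labels[sec]]
        for _ in range(n_replicates):
            scale = np.exp(rng.normal(0.0, config.participant_power_sd))
            if config.noise_model == "ar1":
                noise = _ar1(rng, (n_vol,), config.ar1_rho)
            else:
                noise = rng.standard_normal(n_vol)
            carrier = np.sin(2 * np.pi * config.osc_freq_hz * t
                             + rng.uniform(0, 2 * np.pi))
            spec = multitaper_spectrogram(scale * (noise + amp_t * carrier),
                                          fs=fs)
            lab = mlab[np.minimum(spec.t_s.astype(np.int64), mlab.size - 1)]
            band = spec.power[PSD005_BAND_INDEX]
            sa = band[lab == pair[0]]
            sb = band[lab == pair[1]]
            if sa.size and sb.size:
                vals_a.append(sa.mean())
                vals_b.append(sb.mean())
    a = np.asarray(vals_a)
    b = np.asarray(vals_b)
    if a.size < 3:
        return np.nan
    sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return float((b.mean() - a.mean()) / sp)


def _recovered_labels(ear: EarTrace) -> np.ndarray:
    """Drowsigram codes the analysis pipeline will assign to this trace."""
    from .pipeline import drowsigram_from_closure, score_eyes

    _, closure = score_eyes(ear)
    return drowsigram_from_closure(closure).state


@dataclass
class SimulatedParticipant:
    pid: str
    states: LatentStateSequence
    ear: EarTrace
    bold: np.ndarray                # (n_roi, n_vol)
    rsq_label: str
    power_scale: float
    landmarks: pd.DataFrame | None = None


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    atlas: pd.DataFrame
    participants: list[SimulatedParticipant]
    amplitudes: dict[str, np.ndarray]
    mixing_matrix: np.ndarray

    @property
    def rsq_labels(self) -> pd.Series:
        return pd.Series({p.pid: p.rsq_label for p in self.participants})


def simulate_dataset(
    config: SimulationConfig,
    atlas: pd.DataFrame | None = None,
    keep_landmarks: bool = False,
) -> SimulatedDataset:
    """Generate a full synthetic cohort (states, EAR, BOLD, RSQ labels).

    All randomness derives from ``config.seed``; the same configuration
    reproduces the dataset bit for bit.  Participants who will report "did
    not sleep" get proportionally longer awake dwells and shorter
    microsleep dwells, so drowsigram occupancy is concordant with the
    self-report by construction.
    """
    from .io import default_atlas

    if atlas is None:
        atlas = default_atlas()
    master = np.random.default_rng(config.seed)
    rsq_rng, calib_rng, parts_master = master.spawn(3)
    part_rngs = parts_master.spawn(config.n_participants)

    no_sleep = rsq_rng.random(config.n_participants) < config.fraction_report_no_sleep
    biased = replace(
        config,
        state_dwell_means=(
            config.state_dwell_means[0] * config.no_sleep_awake_dwell_factor,
            config.state_dwell_means[1],
            config.state_dwell_means[2],
            max(config.state_dwell_means[3]
                * config.no_sleep_microsleep_dwell_factor, 7.0),
        ),
    )
    sequences = []
    for i, rng in enumerate(part_rngs):
        cfg = biased if no_sleep[i] else config
        sequences.append(simulate_state_sequence(cfg, rng))

    # eyelid traces first: the calibration targets the contrast as measured
    # through the *recovered* drowsigram, i.e. the analysis's own procedure
    ears, landmark_tables, recovered = [], [], []
    for i, rng in enumerate(part_rngs):
        ear, landmarks = simulate_ear_and_landmarks(
            sequences[i], config, rng, return_landmarks=keep_landmarks)
        ears.append(ear)
        landmark_tables.append(landmarks)
        recovered.append(_recovered_labels(ear))

    amplitudes = calibrate_amplitudes(config, sequences, calib_rng,
                                      measure_labels=recovered)
    mixing = state_mixing_matrix(recovered, [s.labels for s in sequences])

    participants = []
    for i, rng in enumerate(part_rngs):
        ear, landmarks = ears[i], landmark_tables[i]
        scale = np.exp(rng.normal(0.0, config.participant_power_sd))
        bold = simulate_bold(sequences[i], config, atlas, rng,
                             amplitudes=amplitudes, power_scale=scale)
        participants.append(SimulatedParticipant(
            pid=f"sub-{i + 1:03d}", states=sequences[i], ear=ear, bold=bold,
            rsq_label="did_not_sleep" if no_sleep[i] else "slept",
            power_scale=scale, landmarks=landmarks))
    return SimulatedDataset(config=config, atlas=atlas,
                            participants=participants, amplitudes=amplitudes,
                            mixing_matrix=mixing)


def simulate_null_psd_table(
    n_participants: int,
    n_rois: int,
    rng: np.random.Generator,
    chi2_df: int = 8,
    states=STATE_NAMES,
) -> pd.DataFrame:
    """Null band-power table with independent participant-state draws.

    Each (participant, ROI, state) cell is an independent scaled chi-square
    (``chi2_df`` degrees of freedom, unit mean) — the marginal shape of an
    averaged multitaper band-power estimate with no state effect and no
    participant heterogeneity.  Used to check the calibration of the
    per-ROI state test under its own null model.
    """
    recs = []
    for r in range(n_rois):
        vals = rng.chisquare(chi2_df, size=(n_participants, len(states))) / chi2_df
        for p in range(n_participants):
            for j, s in enumerate(states):
                recs.append((f"sub-{p + 1:03d}", f"roi-{r + 1:03d}", s, vals[p, j]))
    return pd.DataFrame(recs, columns=["participant", "roi", "state", "psd005"])
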