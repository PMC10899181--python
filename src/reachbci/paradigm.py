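"""Experimental paradigm and synthetic-session generation.

The paradigm is a closed-loop pursuit-tracking task. Each trial of the
main ("movlook") condition starts with a *reaching* phase — the subject
shifts gaze to screen center and simultaneously attempts a reaching
movement — followed by a 23 s *tracking* phase in which a band-passed
pink-noise target ("snake") is pursued. In roughly 30% of trials the
cursor abruptly deviates from the snake at a random moment 16-21 s into
tracking (the *error* condition). "onlylook" trials contain the gaze
shift alone; "eyeblock" runs collect rest, saccades and blinks for
artifact-model fitting.

The synthetic generator emulates the statistical structure each decoder
assumes: a saccade-locked frontocentral negativity (movement-related
cortical potential) present only in "movlook" reaching, a parieto-
occipital visual component in both conditions, error-locked Pe/ERN
deflections, low-frequency EEG linearly encoding the 2-D snake
kinematics through a lagged forward model, EOG saccade/blink artifacts
bleeding into frontal EEG, and spatially-correlated pink background
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .session import Montage, RawSession, default_montage

# ---------------------------------------------------------------------------
# snake trajectories
# ---------------------------------------------------------------------------


@dataclass
class SnakeTrajectory:
    """2-D pursuit target: unit-variance positions and their velocities."""

    px: np.ndarray
    py: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    fs: float = 20.0

    @property
    def n_samples(self) -> int:
        return self.px.size

    def kinematics(self) -> np.ndarray:
        """6 x T array: px, py, vx, vy, distance, speed."""
        dist = np.hypot(self.px, self.py)
        speed = np.hypot(self.vx, self.vy)
        return np.vstack([self.px, self.py, self.vx, self.vy, dist, speed])


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent (power) noise via spectral synthesis, unit variance per row."""
    n_f = n_samples // 2 + 1
    f = np.arange(n_f, dtype=float)
    f[0] = 1.0
    amp = f ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal((n_channels, n_f))
                  + 1j * rng.standard_normal((n_channels, n_f)))
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-30)


def _bandpassed_pink(rng: np.random.Generator, n: int, fs: float,
                     band: tuple[float, float]) -> np.ndarray:
    # generate 3x longer and crop the center to avoid filter edge transients
    long = pink_noise(rng, 1, 3 * n)[0]
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, long)
    x = filt[n: 2 * n]
    x = x - x.mean()
    return x / max(x.std(), 1e-30)


def generate_snake(seed: int | np.random.Generator, duration_s: float = 23.0,
                   rate_hz: float = 20.0, band_hz: tuple[float, float] = (0.2, 0.4),
                   decorrelation_bound: float = 0.1,
                   max_attempts: int = 1000) -> SnakeTrajectory:
    """Draw a snake: band-passed pink noise with decorrelated x/y components.

    Candidate x/y pairs are resampled until all four position/velocity
    cross-correlations (px-py, px-vy, vx-py, vx-vy) fall below the bound.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    for _ in range(max_attempts):
        px = _bandpassed_pink(rng, n, rate_hz, band_hz)
        py = _bandpassed_pink(rng, n, rate_hz, band_hz)
        vx = np.gradient(px) * rate_hz
        vy = np.gradient(py) * rate_hz
        corrs = [np.corrcoef(a, b)[0, 1]
                 for a, b in ((px, py), (px, vy), (vx, py), (vx, vy))]
        if max(abs(c) for c in corrs) < decorrelation_bound:
            return SnakeTrajectory(px=px, py=py, vx=vx, vy=vy, fs=rate_hz)
    raise RuntimeError(
        f"could not decorrelate snake components below {decorrelation_bound} "
        f"in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# trial schedule
# ---------------------------------------------------------------------------

START_POSITIONS = ("up", "down", "left", "right")


@dataclass
class Trial:
    condition: str            # movlook | onlylook
    start_pos: str
    snake_seed: int | None    # None for onlylook
    error: bool = False
    error_onset_s: float | None = None  # seconds into the tracking phase


@dataclass
class Run:
    name: str
    condition: str            # movlook | onlylook | eyeblock
    phase: str                # calibration | online
    alpha: float              # EEG mixing proportion for tracking feedback
    trials: list[Trial] = field(default_factory=list)


@dataclass
class TrialSchedule:
    runs: list[Run]

    def runs_of(self, condition: str, phase: str | None = None) -> list[Run]:
        return [r for r in self.runs
                if r.condition == condition and (phase is None or r.phase == phase)]

    def trials_of(self, condition: str, phase: str | None = None) -> list[Trial]:
        return [t for r in self.runs_of(condition, phase) for t in r.trials]


ERROR_ONSET_RANGE_S = (16.0, 21.0)
TRACKING_DURATION_S = 23.0


def schedule_to_json(schedule: TrialSchedule, path) -> None:
    """Serialize a schedule as a JSON manifest."""
    import json
    from pathlib import Path

    payload = [
        {
            "name": r.name, "condition": r.condition, "phase": r.phase,
            "alpha": r.alpha,
            "trials": [
                {"condition": t.condition, "start_pos": t.start_pos,
                 "snake_seed": t.snake_seed, "error": t.error,
                 "error_onset_s": t.error_onset_s}
                for t in r.trials
            ],
        }
        for r in schedule.runs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def schedule_from_json(path) -> TrialSchedule:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    return TrialSchedule(runs=[
        Run(r["name"], r["condition"], r["phase"], r["alpha"],
            [Trial(**t) for t in r["trials"]])
        for r in payload
    ])


def build_schedule(seed: int, n_movlook_runs: int = 6, n_onlylook_runs: int = 5,
                   trials_per_run: int = 12, error_fraction: float = 0.30,
                   n_online_runs: int = 6, include_eyeblocks: bool = True,
                   ) -> TrialSchedule:
    """Build the full session schedule.

    Calibration: ``n_movlook_runs`` movlook + ``n_onlylook_runs`` onlylook runs
    of ``trials_per_run`` trials, preceded/followed by two eyeblock runs.
    Online: ``n_online_runs`` movlook runs, the first half at 50% and the
    second half at 100% EEG feedback. ``round(error_fraction * n_trials)``
    movlook trials per phase carry an error with onset uniform on [16, 21] s;
    start positions are counterbalanced within every run.
    """
    if trials_per_run % len(START_POSITIONS):
        raise ValueError("trials_per_run must be divisible by 4 for counterbalancing")
    rng = np.random.default_rng(seed)

    def make_trials(condition: str, n: int) -> list[Trial]:
        starts = rng.permutation(
            np.repeat(START_POSITIONS, n // len(START_POSITIONS)))
        return [
            Trial(condition=condition, start_pos=str(s),
                  snake_seed=(int(rng.integers(0, 2 ** 31 - 1))
                              if condition == "movlook" else None))
            for s in starts
        ]

    def assign_errors(trials: list[Trial]) -> None:
        n_err = int(round(error_fraction * len(trials)))
        for i in rng.choice(len(trials), size=n_err, replace=False):
            trials[i].error = True
            trials[i].error_onset_s = float(rng.uniform(*ERROR_ONSET_RANGE_S))

    runs: list[Run] = []
    if include_eyeblocks:
        runs.append(Run("eyeblock-01", "eyeblock", "calibration", 0.0))

    cal_movlook: list[list[Trial]] = [make_trials("movlook", trials_per_run)
                                      for _ in range(n_movlook_runs)]
    assign_errors([t for ts in cal_movlook for t in ts])
    onlylook = [make_trials("onlylook", trials_per_run) for _ in range(n_onlylook_runs)]
    order = []
    for i in range(max(n_movlook_runs, n_onlylook_runs)):
        if i < n_movlook_runs:
            order.append(("movlook", cal_movlook[i]))
        if i < n_onlylook_runs:
            order.append(("onlylook", onlylook[i]))
    for i, (cond, trials) in enumerate(order, start=1):
        runs.append(Run(f"{cond}-cal-{i:02d}", cond, "calibration", 0.0, trials))

    if include_eyeblocks:
        runs.append(Run("eyeblock-02", "eyeblock", "calibration", 0.0))

    online: list[list[Trial]] = [make_trials("movlook", trials_per_run)
                                 for _ in range(n_online_runs)]
    assign_errors([t for ts in online for t in ts])
    for i, trials in enumerate(online):
        alpha = 0.5 if i < n_online_runs // 2 else 1.0
        runs.append(Run(f"movlook-online-{i + 1:02d}", "movlook", "online",
                        alpha, trials))
    return TrialSchedule(runs=runs)


# ---------------------------------------------------------------------------
# synthesis configuration
# ---------------------------------------------------------------------------


@dataclass
class TemplateSpec:
    """A spatiotemporal bump: Gaussian in time, Gaussian on the scalp."""

    latency_s: float      # peak time relative to the locking event
    amplitude_uv: float
    center: str           # electrode label of the topography center
    temporal_sigma_s: float
    # volume conduction spatially low-passes scalp potentials: event-related
    # components are visible over much of the scalp, not a single electrode
    spatial_sigma_m: float = 0.06


@dataclass
class SynthConfig:
    fs: float = 200.0
    # background noise
    noise_scale_uv: float = 8.0
    noise_exponent: float = 1.0
    shared_noise_mix: float = 0.3
    # reaching-phase templates (saccade-locked)
    mrcp: TemplateSpec = field(default_factory=lambda: TemplateSpec(
        latency_s=-0.1, amplitude_uv=-6.0, center="Cz", temporal_sigma_s=0.30))
    # the saccade-locked visual (lambda-type) response is occipital and
    # focal enough not to displace the central negativity peak
    visual: TemplateSpec = field(default_factory=lambda: TemplateSpec(
        latency_s=0.0, amplitude_uv=4.0, center="Oz", temporal_sigma_s=0.15,
        spatial_sigma_m=0.05))
    # error-locked templates; single-trial amplitudes sit well above the
    # grand-average level, and the Pe (a P300-family component) gets an
    # extra-broad topography
    pe: TemplateSpec = field(default_factory=lambda: TemplateSpec(
        latency_s=0.44, amplitude_uv=10.0, center="CPz", temporal_sigma_s=0.08,
        spatial_sigma_m=0.08))
    ern: TemplateSpec = field(default_factory=lambda: TemplateSpec(
        latency_s=0.77, amplitude_uv=-8.0, center="FCz", temporal_sigma_s=0.08))
    # kinematic forward model
    kin_snr: float = 1.0
    kin_lag_gains: tuple[float, ...] = (1.0, 0.6, 0.3)
    kin_lag_step_s: float = 0.05
    kin_centers: tuple[str, ...] = ("C3", "C4", "CP1", "CP2", "Pz", "POz")
    kin_pattern_jitter: float = 0.2
    kin_pattern_seed: int = 12345
    # EOG
    eog_noise_uv: float = 3.0
    saccade_amplitude_uv: float = 150.0
    saccade_rise_s: float = 0.04
    blink_amplitude_uv: float = 400.0
    blink_sigma_s: float = 0.08
    eog_mix_scale: float = 0.4
    # trial timing
    baseline_s: float = 2.0
    saccade_window_s: tuple[float, float] = (2.0, 4.0)
    post_saccade_s: float = 1.0
    intertrial_gap_s: float = 2.0

    def __post_init__(self) -> None:
        for spec, lo, hi in ((self.pe, -0.5, 1.0), (self.ern, -0.5, 1.0)):
            if not lo <= spec.latency_s <= hi:
                raise ValueError("error-template latency outside the epoch range")
        if not -1.0 <= self.mrcp.latency_s <= 1.0:
            raise ValueError("movement-template latency outside the epoch range")
        for spec in (self.mrcp, self.visual, self.pe, self.ern):
            if not np.isfinite(spec.amplitude_uv):
                raise ValueError("template amplitudes must be finite")


def topography(montage: Montage, center: str, sigma_m: float) -> np.ndarray:
    d = np.linalg.norm(montage.positions - montage.positions[montage.index(center)],
                       axis=1)
    return np.exp(-0.5 * (d / sigma_m) ** 2)


def _bump(t: np.ndarray, peak_s: float, sigma_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - peak_s) / sigma_s) ** 2)


def add_template(eeg: np.ndarray, montage: Montage, spec: TemplateSpec,
                 event_sample: int, fs: float) -> None:
    """Add a spatiotemporal template in place, time-locked to ``event_sample``."""
    t = (np.arange(eeg.shape[1]) - event_sample) / fs
    course = spec.amplitude_uv * _bump(t, spec.latency_s, spec.temporal_sigma_s)
    eeg += topography(montage, spec.center, spec.spatial_sigma_m)[:, None] * course


# ---------------------------------------------------------------------------
# EOG / eye-artifact model
# ---------------------------------------------------------------------------

_SACCADE_DIRECTION = {
    # gaze shift from the start position towards screen center
    "left": (1.0, 0.0), "right": (-1.0, 0.0), "up": (0.0, -1.0), "down": (0.0, 1.0),
}


def _smooth_step(t: np.ndarray, onset_s: float, rise_s: float) -> np.ndarray:
    z = np.clip((t - onset_s) / (rise_s / 4.0), -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-z))


def eog_mixing_matrix(cfg: SynthConfig, montage: Montage) -> np.ndarray:
    """Ground-truth EOG -> EEG contamination (frontally weighted)."""
    centers = ("AF7", "AF8", "AFz", "AFz")
    scales = (1.0, 1.0, 1.2, 0.8)
    cols = [s * topography(montage, c, 0.05) for c, s in zip(centers, scales)]
    return cfg.eog_mix_scale * np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# forward kinematic model
# ---------------------------------------------------------------------------


def kinematic_patterns(cfg: SynthConfig, montage: Montage) -> np.ndarray:
    """(n_channels x 6) spatial patterns of the forward kinematic encoding."""
    rng = np.random.default_rng(cfg.kin_pattern_seed)
    cols = []
    for c in cfg.kin_centers:
        base = topography(montage, c, 0.04)
        jitter = cfg.kin_pattern_jitter * rng.standard_normal(montage.n_channels)
        cols.append(base + jitter * base.max() * 0.5)
    return np.stack(cols, axis=1)


def _encode_kinematics(cfg: SynthConfig, montage: Montage,
                       kin200: np.ndarray) -> np.ndarray:
    """Clean (noise-free, unscaled) EEG from the lagged forward model."""
    patterns = kinematic_patterns(cfg, montage)      # (ch, 6)
    lag = int(round(cfg.kin_lag_step_s * cfg.fs))
    kin200 = kin200.copy()
    # center the non-directional rows: cortex encodes deviations, and a
    # distance/speed mean would otherwise leave a DC offset on the scalp
    kin200[4:] -= kin200[4:].mean(axis=1, keepdims=True)
    clean = np.zeros((montage.n_channels, kin200.shape[1]))
    for i, g in enumerate(cfg.kin_lag_gains):
        shifted = np.roll(kin200, i * lag, axis=1)
        shifted[:, : i * lag] = kin200[:, [0]]
        clean += g * (patterns @ shifted)
    return clean


_SNAKE_BAND = (0.15, 0.45)


def _band_rms(x: np.ndarray, fs: float, band=_SNAKE_BAND) -> np.ndarray:
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1).std(axis=-1)


def _noise_band_rms(cfg: SynthConfig, n_samples: int) -> float:
    """Expected per-channel RMS of the background noise inside the snake band,
    from the synthesis spectrum and the band filter response (deterministic)."""
    if cfg.noise_scale_uv == 0:
        return 0.0
    f = np.fft.rfftfreq(n_samples, d=1.0 / cfg.fs)
    a2 = np.zeros_like(f)
    a2[1:] = f[1:] ** (-cfg.noise_exponent)
    sos = signal.butter(2, _SNAKE_BAND, btype="bandpass", fs=cfg.fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=f, fs=cfg.fs)
    frac = np.sqrt(np.sum(np.abs(h) ** 2 * a2) / np.sum(a2))
    mix = cfg.shared_noise_mix
    ch_scale = cfg.noise_scale_uv * np.sqrt((1 - mix) ** 2 + mix ** 2)
    return float(ch_scale * frac)


def _scaled_clean_tracking(cfg: SynthConfig, montage: Montage,
                           kin200: np.ndarray) -> np.ndarray:
    """Forward-encoded EEG scaled so band RMS on the encoding channels equals
    ``kin_snr`` times the expected noise band RMS."""
    clean = _encode_kinematics(cfg, montage, kin200)
    if cfg.kin_snr < np.inf and cfg.noise_scale_uv > 0:
        enc_rms = _band_rms(clean, cfg.fs)
        top = enc_rms > 0.1 * enc_rms.max()
        target = cfg.kin_snr * _noise_band_rms(cfg, kin200.shape[1])
        clean = clean * (target / max(np.median(enc_rms[top]), 1e-30))
    return clean


def _upsample_kinematics(snake: SnakeTrajectory, fs: float) -> np.ndarray:
    n = int(round(snake.n_samples / snake.fs * fs))
    t_src = np.arange(snake.n_samples) / snake.fs
    t_dst = np.arange(n) / fs
    return np.stack([np.interp(t_dst, t_src, row) for row in snake.kinematics()])


def simulate_tracking_eeg(cfg: SynthConfig, snake: SnakeTrajectory,
                          seed: int | np.random.Generator,
                          montage: Montage | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Low-frequency EEG linearly encoding the snake kinematics.

    Returns ``(eeg, kinematics)`` at the raw rate: the EEG is the lagged
    forward projection of (px, py, vx, vy, distance, speed) scaled to the
    configured signal-to-noise ratio in the snake band, plus pink noise.
    """
    montage = montage or default_montage()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kin200 = _upsample_kinematics(snake, cfg.fs)
    clean = _scaled_clean_tracking(cfg, montage, kin200)
    noise = _session_noise(cfg, rng, montage.n_channels, kin200.shape[1])
    return clean + noise, kin200


def _session_noise(cfg: SynthConfig, rng: np.random.Generator,
                   n_channels: int, n_samples: int) -> np.ndarray:
    if cfg.noise_scale_uv == 0:
        return np.zeros((n_channels, n_samples))
    own = pink_noise(rng, n_channels, n_samples, cfg.noise_exponent)
    shared = pink_noise(rng, 1, n_samples, cfg.noise_exponent)
    mix = cfg.shared_noise_mix
    return cfg.noise_scale_uv * ((1 - mix) * own + mix * shared)


# ---------------------------------------------------------------------------
# saccade detector
# ---------------------------------------------------------------------------


def detect_saccade(eog: np.ndarray, fs: float, threshold_mads: float = 20.0,
                   baseline: slice | None = None,
                   refractory_s: float = 0.5) -> np.ndarray:
    """Detect saccades by thresholding EOG derivatives.

    The detection statistic is the largest absolute channel derivative per
    sample; the threshold is ``threshold_mads`` times the MAD of the
    statistic over the baseline segment. Detections within the refractory
    period of a previous one are suppressed. Returns detection times (s).
    """
    if fs < 100:
        raise ValueError("EOG must be sampled at >= 100 Hz")
    eog = np.atleast_2d(eog)
    deriv = np.abs(np.diff(eog, axis=-1)) * fs
    stat = deriv.max(axis=0)
    if baseline is None:
        baseline = slice(0, int(fs))
    base = stat[baseline]
    mad = np.median(np.abs(base - np.median(base)))
    if mad <= 0:
        raise ValueError("flat EOG baseline (MAD is zero); cannot set threshold")
    above = np.flatnonzero(stat > threshold_mads * mad)
    detections = []
    refractory = int(round(refractory_s * fs))
    last = -np.inf
    for idx in above:
        if idx - last >= refractory:
            detections.append(idx + 1)  # diff shifts by one sample
            last = idx
    return np.asarray(detections) / fs


# ---------------------------------------------------------------------------
# run synthesis
# ---------------------------------------------------------------------------


def _reaching_segment(cfg: SynthConfig, montage: Montage, trial: Trial,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Clean EEG (templates only), EOG, saccade time and duration of one
    reaching phase."""
    t_sacc = float(rng.uniform(*cfg.saccade_window_s))
    dur = cfg.baseline_s + t_sacc + cfg.post_saccade_s
    n = int(round(dur * cfg.fs))
    t = np.arange(n) / cfg.fs
    sacc_s = cfg.baseline_s + t_sacc
    sacc_sample = int(round(sacc_s * cfg.fs))

    eog = np.zeros((4, n))
    dx, dy = _SACCADE_DIRECTION[trial.start_pos]
    step = cfg.saccade_amplitude_uv * _smooth_step(t, sacc_s, cfg.saccade_rise_s)
    eog[0] += dx * step        # EOGL
    eog[1] -= dx * step        # EOGR
    eog[2] += dy * step        # EOGU
    eog[3] -= dy * step        # EOGD

    eeg = np.zeros((montage.n_channels, n))
    add_template(eeg, montage, cfg.visual, sacc_sample, cfg.fs)
    if trial.condition == "movlook":
        add_template(eeg, montage, cfg.mrcp, sacc_sample, cfg.fs)
    return eeg, eog, sacc_s, dur


def simulate_run(cfg: SynthConfig, run: Run, seed: int | np.random.Generator,
                 montage: Montage | None = None) -> RawSession:
    """Synthesize one run as a continuous 200 Hz EEG/EOG recording."""
    montage = montage or default_montage()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if run.condition == "eyeblock":
        return _simulate_eyeblock(cfg, montage, rng, run.name)

    eeg_parts: list[np.ndarray] = []
    eog_parts: list[np.ndarray] = []
    events: list[tuple[float, float, str, float]] = []
    t_cursor = 0.0
    for ti, trial in enumerate(run.trials):
        eeg_r, eog_r, sacc_s, dur_r = _reaching_segment(cfg, montage, trial, rng)
        events.append((t_cursor, dur_r, "reaching_start", ti))
        events.append((t_cursor + sacc_s, 0.0, "saccade", ti))
        eeg_parts.append(eeg_r)
        eog_parts.append(eog_r)
        t_cursor += dur_r

        if trial.condition == "movlook" and trial.snake_seed is not None:
            snake = generate_snake(np.random.default_rng(trial.snake_seed))
            kin200 = _upsample_kinematics(snake, cfg.fs)
            eeg_t = _scaled_clean_tracking(cfg, montage, kin200)
            # pursuit EOG: small smooth tracking of the snake
            n_t = eeg_t.shape[1]
            gx = 20.0 * kin200[0]
            gy = 20.0 * kin200[1]
            eog_t = np.vstack([gx, -gx, gy, -gy])
            events.append((t_cursor, TRACKING_DURATION_S, "tracking_start", ti))
            if trial.error:
                err_sample = int(round(trial.error_onset_s * cfg.fs))
                add_template(eeg_t, montage, cfg.pe, err_sample, cfg.fs)
                add_template(eeg_t, montage, cfg.ern, err_sample, cfg.fs)
                events.append((t_cursor + trial.error_onset_s, 0.0, "error_onset", ti))
            eeg_parts.append(eeg_t)
            eog_parts.append(eog_t)
            t_cursor += n_t / cfg.fs

        n_gap = int(round(cfg.intertrial_gap_s * cfg.fs))
        eeg_parts.append(np.zeros((montage.n_channels, n_gap)))
        eog_parts.append(np.zeros((4, n_gap)))
        events.append((t_cursor, cfg.intertrial_gap_s, "gap", ti))
        t_cursor += cfg.intertrial_gap_s

    eeg = np.concatenate(eeg_parts, axis=1)
    eog = np.concatenate(eog_parts, axis=1)
    n = eeg.shape[1]
    eog += cfg.eog_noise_uv * pink_noise(rng, 4, n, cfg.noise_exponent)
    eeg += eog_mixing_matrix(cfg, montage) @ eog
    eeg += _session_noise(cfg, rng, montage.n_channels, n)
    ev = pd.DataFrame(events, columns=["onset", "duration", "trial_type", "value"])
    return RawSession(eeg=eeg, eog=eog, fs=cfg.fs, events=ev, montage=montage)


def _simulate_eyeblock(cfg: SynthConfig, montage: Montage,
                       rng: np.random.Generator, name: str) -> RawSession:
    """Eyeblock run: rest, horizontal/vertical saccade and blink segments."""
    fs = cfg.fs
    segs = [("rest", 30.0), ("eyemove_h", 20.0), ("eyemove_v", 20.0), ("blink", 20.0)]
    n = int(round(sum(d for _, d in segs) * fs))
    t = np.arange(n) / fs
    eog = np.zeros((4, n))
    events = []
    t0 = 0.0
    for label, dur in segs:
        events.append((t0, dur, label, 0.0))
        if label in ("eyemove_h", "eyemove_v"):
            sign = 1.0
            for onset in np.arange(t0 + 1.0, t0 + dur - 1.0, 2.0):
                step = cfg.saccade_amplitude_uv * sign * (
                    _smooth_step(t, onset, cfg.saccade_rise_s)
                    - _smooth_step(t, onset + 1.0, cfg.saccade_rise_s))
                if label == "eyemove_h":
                    eog[0] += step
                    eog[1] -= step
                else:
                    eog[2] += step
                    eog[3] -= step
                sign = -sign
        elif label == "blink":
            for onset in np.arange(t0 + 1.0, t0 + dur - 1.0, 2.0):
                bump = cfg.blink_amplitude_uv * _bump(t, onset, cfg.blink_sigma_s)
                eog[2] += bump
                eog[3] += 0.3 * bump
        t0 += dur
    eog += cfg.eog_noise_uv * pink_noise(rng, 4, n, cfg.noise_exponent)
    eeg = eog_mixing_matrix(cfg, montage) @ eog
    eeg += _session_noise(cfg, rng, montage.n_channels, n)
    ev = pd.DataFrame(events, columns=["onset", "duration", "trial_type", "value"])
    return RawSession(eeg=eeg, eog=eog, fs=fs, events=ev, montage=montage)


def simulate_session(cfg: SynthConfig, schedule: TrialSchedule, seed: int,
                     montage: Montage | None = None) -> dict[str, RawSession]:
    """Synthesize every run of the schedule; reproducible from the seed."""
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    return {run.name: simulate_run(cfg, run, rng, montage) for run in schedule.runs}


# thin phase-restricted wrappers -------------------------------------------------


def simulate_mrcp_epochs(cfg: SynthConfig, schedule: TrialSchedule,
                         seed: int, montage: Montage | None = None,
                         ) -> dict[str, RawSession]:
    """Continuous EEG/EOG for the reaching phases only (both conditions)."""
    reach_only = TrialSchedule(runs=[
        Run(r.name, "onlylook" if r.condition == "onlylook" else "movlook",
            r.phase, r.alpha,
            [Trial(t.condition, t.start_pos, snake_seed=None) for t in r.trials])
        for r in schedule.runs if r.condition in ("movlook", "onlylook")
    ])
    return simulate_session(cfg, reach_only, seed, montage)


def simulate_errp_epochs(cfg: SynthConfig, schedule: TrialSchedule, seed: int,
                         montage: Montage | None = None) -> dict[str, RawSession]:
    """Continuous EEG around (tracking + error) phases of movlook runs."""
    movlook = TrialSchedule(runs=[r for r in schedule.runs if r.condition == "movlook"])
    return simulate_session(cfg, movlook, seed, montage)
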