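"""Causal/zero-phase EEG preprocessing chains.

The common stage takes a raw 200 Hz recording through an anti-alias
low-pass (25 Hz, 2nd-order Butterworth), line-noise notches (50/100 Hz),
decimation to 100 Hz, bad-channel interpolation and EOG-regression eye
artifact attenuation. The movement branch adds a 0.18 Hz first-order
high-pass, common average reference, optional transient suppression and
a 3 Hz second-order low-pass before decimating to 10 Hz (intention
detection) and 20 Hz (trajectory decoding); the error-potential branch
band-passes the common 100 Hz stream at 1-10 Hz.

All chains run either causally (single forward pass, as online) or
zero-phase (forward-backward, for offline analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import Montage, RawSession, Stream

RAW_RATE_HZ = 200.0
COMMON_RATE_HZ = 100.0


@dataclass
class PreprocConfig:
    causal_mode: bool = True
    notch_hz: tuple[float, ...] = (50.0, 100.0)
    notch_q: float = 35.0
    mrcp_rate_hz: float = 10.0
    traj_rate_hz: float = 20.0
    errp_band_hz: tuple[float, float] = (1.0, 10.0)
    bad_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for rate in (self.mrcp_rate_hz, self.traj_rate_hz):
            if COMMON_RATE_HZ % rate:
                raise ValueError(f"branch rate {rate} Hz must divide {COMMON_RATE_HZ} Hz")


# ---------------------------------------------------------------------------
# filter designs (second-order sections)
# ---------------------------------------------------------------------------

def design_lowpass25(fs: float) -> np.ndarray:
    return signal.butter(2, 25.0, btype="low", fs=fs, output="sos")


def design_notch(freq: float, q: float, fs: float) -> np.ndarray:
    b, a = signal.iirnotch(freq, q, fs=fs)
    return signal.tf2sos(b, a)


def design_highpass018(fs: float) -> np.ndarray:
    return signal.butter(1, 0.18, btype="high", fs=fs, output="sos")


def design_lowpass3(fs: float) -> np.ndarray:
    return signal.butter(2, 3.0, btype="low", fs=fs, output="sos")


def design_errp_bandpass(band: tuple[float, float], fs: float) -> np.ndarray:
    # overall 4th order (2 poles per edge)
    return signal.butter(2, band, btype="bandpass", fs=fs, output="sos")


def apply_filter(sos: np.ndarray, x: np.ndarray, causal: bool) -> np.ndarray:
    if causal:
        return signal.sosfilt(sos, x, axis=-1)
    return signal.sosfiltfilt(sos, x, axis=-1)


def _decimate(x: np.ndarray, factor: int) -> np.ndarray:
    # anti-alias filtering happens upstream; plain sample picking keeps
    # the causal chains free of extra group delay
    return x[..., ::factor]


# ---------------------------------------------------------------------------
# EOG regression model
# ---------------------------------------------------------------------------

@dataclass
class EogModel:
    """Least-squares projection of EOG (and its derivative) out of the EEG."""

    coefficients: np.ndarray | None = None  # (n_eeg, 2 * n_eog)
    fs: float = COMMON_RATE_HZ

    @property
    def fitted(self) -> bool:
        return self.coefficients is not None

    def regressors(self, eog: np.ndarray) -> np.ndarray:
        """Stack raw EOG channels with their first temporal derivatives."""
        deriv = np.gradient(eog, axis=-1) * self.fs
        return np.vstack([eog, deriv])

    def apply(self, eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("EogModel must be fitted before application")
        return eeg - self.coefficients @ self.regressors(eog)


def fit_eog_model(eyeblock_eeg: np.ndarray, eyeblock_eog: np.ndarray,
                  fs: float = COMMON_RATE_HZ) -> EogModel:
    """Fit the per-channel EOG regression on eyeblock data.

    The eyeblock segments should contain rest, saccades and blinks so the
    regressors span the artifact subspace. Raises if the EOG carries
    (numerically) no variance, which makes the problem ill-posed.
    """
    model = EogModel(fs=fs)
    reg = model.regressors(np.asarray(eyeblock_eog, dtype=float))
    reg_c = reg - reg.mean(axis=1, keepdims=True)
    if np.any(reg_c.var(axis=1) < 1e-12):
        raise ValueError("EOG regressor variance ~0: ill-posed regression")
    eeg_c = eyeblock_eeg - np.mean(eyeblock_eeg, axis=1, keepdims=True)
    coef, *_ = np.linalg.lstsq(reg_c.T, eeg_c.T, rcond=None)
    model.coefficients = coef.T
    return model


# ---------------------------------------------------------------------------
# bad-channel interpolation and transient suppression
# ---------------------------------------------------------------------------

def interpolation_weights(montage: Montage, bad_idx: np.ndarray,
                          k: int = 4) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Inverse-distance weights of the k nearest good neighbors per bad channel."""
    bad_idx = np.asarray(bad_idx, dtype=int)
    good = np.setdiff1d(np.arange(montage.n_channels), bad_idx)
    if good.size < k:
        raise ValueError(f"need at least {k} good channels, have {good.size}")
    weights: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for b in bad_idx:
        nb = montage.nearest_neighbors(int(b), good, k=k)
        d = np.linalg.norm(montage.positions[nb] - montage.positions[b], axis=1)
        w = 1.0 / np.maximum(d, 1e-9)
        weights[int(b)] = (nb, w / w.sum())
    return weights


def interpolate_bad_channels(data: np.ndarray, montage: Montage,
                             bad_idx: np.ndarray | None = None) -> np.ndarray:
    """Replace bad channels by the weighted mean of their 4 nearest good neighbors."""
    if bad_idx is None:
        bad_idx = np.flatnonzero(montage.is_bad)
    bad_idx = np.asarray(bad_idx, dtype=int)
    if bad_idx.size == 0:
        return data
    out = data.copy()
    for b, (nb, w) in interpolation_weights(montage, bad_idx).items():
        out[b] = w @ data[nb]
    return out


@dataclass
class TransientStats:
    """Per-channel robust reference statistics from calibration rest data."""

    center: np.ndarray  # robust mean (median), µV
    scale: np.ndarray   # MAD-based sigma, µV


def estimate_transient_stats(data: np.ndarray) -> TransientStats:
    center = np.median(data, axis=1)
    mad = np.median(np.abs(data - center[:, None]), axis=1)
    return TransientStats(center=center, scale=np.maximum(1.4826 * mad, 1e-12))


def attenuate_transients(data: np.ndarray, stats: TransientStats, montage: Montage,
                         bound_mads: float = 5.0) -> np.ndarray:
    """Suppress electrode pops/drifts by probability-weighted neighbor interpolation.

    Samples whose robust z-score exceeds ``bound_mads`` are blended towards an
    inverse-distance interpolation of the 4 nearest channels, with blending
    weight ramping from 0 at the bound to 1 at twice the bound. Clean data
    passes through unchanged.
    """
    z = np.abs((data - stats.center[:, None]) / stats.scale[:, None])
    prob = np.clip(z / bound_mads - 1.0, 0.0, 1.0)
    if not prob.any():
        return data
    out = data.copy()
    all_idx = np.arange(montage.n_channels)
    for ch in np.flatnonzero(prob.any(axis=1)):
        nb = montage.nearest_neighbors(int(ch), np.setdiff1d(all_idx, [ch]), k=4)
        d = np.linalg.norm(montage.positions[nb] - montage.positions[ch], axis=1)
        w = 1.0 / np.maximum(d, 1e-9)
        w /= w.sum()
        est = w @ data[nb]
        p = prob[ch]
        out[ch] = (1.0 - p) * data[ch] + p * est
    return out


# ---------------------------------------------------------------------------
# processing chains
# ---------------------------------------------------------------------------

def common_filter(raw: RawSession, cfg: PreprocConfig) -> tuple[Stream, Stream]:
    """Filtering half of the common stage: anti-alias low-pass, notches,
    decimation to 100 Hz and bad-channel interpolation — everything that
    precedes the EOG regression, so the regression model itself can be
    fitted on data passed through this exact chain."""
    if raw.fs != RAW_RATE_HZ:
        raise ValueError(f"expected raw data at {RAW_RATE_HZ:g} Hz, got {raw.fs:g} Hz")
    causal = cfg.causal_mode
    eeg = apply_filter(design_lowpass25(raw.fs), raw.eeg, causal)
    eog = apply_filter(design_lowpass25(raw.fs), raw.eog, causal)
    for f0 in cfg.notch_hz:
        if f0 < raw.fs / 2:
            eeg = apply_filter(design_notch(f0, cfg.notch_q, raw.fs), eeg, causal)

    factor = int(round(raw.fs / COMMON_RATE_HZ))
    eeg = _decimate(eeg, factor)
    eog = _decimate(eog, factor)

    montage = raw.montage
    bad = montage.is_bad.copy()
    for lab in cfg.bad_channels:
        bad[montage.index(lab)] = True
    if bad.any():
        eeg = interpolate_bad_channels(eeg, montage, np.flatnonzero(bad))
    return (Stream(eeg, COMMON_RATE_HZ, montage.labels),
            Stream(eog, COMMON_RATE_HZ, ("EOGL", "EOGR", "EOGU", "EOGD")))


def preprocess_common(raw: RawSession, cfg: PreprocConfig, eog_model: EogModel,
                      keep_af: bool = False) -> tuple[Stream, Stream]:
    """Common stage: anti-alias + notch filters, 100 Hz decimation,
    bad-channel interpolation and eye-artifact attenuation.

    Returns the cleaned EEG stream (AF row dropped unless ``keep_af``) and
    the matching 100 Hz EOG stream. The EOG model must have been fitted on
    data passed through this same chain.
    """
    if not eog_model.fitted:
        raise RuntimeError("EogModel is not fitted; fit it on eyeblock data first")
    eeg_stream, eog_stream = common_filter(raw, cfg)
    eeg = eog_model.apply(eeg_stream.data, eog_stream.data)
    eog = eog_stream.data
    montage = raw.montage

    if not keep_af:
        keep = ~montage.is_af_row
        eeg = eeg[keep]
        labels = tuple(lab for lab, k in zip(montage.labels, keep) if k)
    else:
        labels = montage.labels
    return (Stream(eeg, COMMON_RATE_HZ, labels),
            Stream(eog, COMMON_RATE_HZ, ("EOGL", "EOGR", "EOGU", "EOGD")))


def preprocess_movement_branch(stream100: Stream, cfg: PreprocConfig,
                               montage: Montage | None = None,
                               transient_stats: TransientStats | None = None,
                               ) -> tuple[Stream, Stream]:
    """Movement branch: 0.18 Hz high-pass, CAR, transient suppression,
    3 Hz low-pass, then decimation to the 10 Hz and 20 Hz branch rates."""
    causal = cfg.causal_mode
    x = apply_filter(design_highpass018(stream100.fs), stream100.data, causal)
    x = x - x.mean(axis=0, keepdims=True)  # CAR
    if transient_stats is not None:
        if montage is None:
            raise ValueError("transient suppression needs the montage")
        x = attenuate_transients(x, transient_stats, montage)
    x = apply_filter(design_lowpass3(stream100.fs), x, causal)
    mrcp = _decimate(x, int(round(stream100.fs / cfg.mrcp_rate_hz)))
    traj = _decimate(x, int(round(stream100.fs / cfg.traj_rate_hz)))
    return (Stream(mrcp, cfg.mrcp_rate_hz, stream100.labels),
            Stream(traj, cfg.traj_rate_hz, stream100.labels))


def preprocess_errp_branch(stream100: Stream, cfg: PreprocConfig) -> Stream:
    """Error-potential branch: 1-10 Hz band-pass at the common 100 Hz rate."""
    x = apply_filter(design_errp_bandpass(cfg.errp_band_hz, stream100.fs),
                     stream100.data, cfg.causal_mode)
    return stream100.copy_with(x)
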