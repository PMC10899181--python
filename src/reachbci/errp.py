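"""Asynchronous error-potential (ErrP) detection.

Error potentials elicited by a sudden loss of cursor control show a
centro-parietal positivity (Pe) followed by a late frontocentral
negativity (ERN). A participant-specific discriminative window relative
to the error onset is chosen from the error-minus-correct difference
wave; channel x time amplitudes inside the window (at 100 Hz) feed a
PCA (99% retained variance) and a shrinkage LDA. Online, the classifier
slides sample-by-sample over the 1-10 Hz band-passed stream and an
error is called when the error posterior exceeds a threshold τ on three
consecutive samples; τ is tuned on calibration data by maximizing the
product of smoothed TPR and TNR over a 41-value grid.

Correct trials receive a *virtual* error onset drawn from the same
16-21 s distribution as the real ones, so both classes are scored on
identically-sized segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .mlcore import SldaModel, pca_reduce, train_slda
from .paradigm import ERROR_ONSET_RANGE_S

EPOCH_WINDOW_S = (-0.5, 1.0)      # epoching range around (virtual) onset
THRESHOLD_GRID = tuple(np.round(np.linspace(0.0, 1.0, 41), 3))
SMOOTH_SAMPLES = 7
POST_ONSET_TP_S = 1.0             # a TP needs a detection within 1 s of onset


def make_virtual_onsets(n_correct_trials: int, seed: int | np.random.Generator,
                        ) -> np.ndarray:
    """One virtual error onset per correct trial, uniform on [16, 21] s into
    the tracking phase (the same distribution as the real errors)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(*ERROR_ONSET_RANGE_S, size=n_correct_trials)


# ---------------------------------------------------------------------------
# discriminative-window selection
# ---------------------------------------------------------------------------


def select_window(error_epochs: np.ndarray, correct_epochs: np.ndarray,
                  reference_channel: int, fs: float = 100.0,
                  epoch_start_s: float = EPOCH_WINDOW_S[0],
                  search_range_s: tuple[float, float] = (0.2, 0.9),
                  duration_bounds_s: tuple[float, float] = (0.2, 0.6),
                  smooth_s: float = 0.05) -> tuple[float, float]:
    """Automated surrogate for the visual window choice.

    The error-minus-correct difference wave at the reference channel is
    smoothed and thresholded at 50% of its absolute maximum inside the
    search range; the window runs from the first suprathreshold local peak
    to the last suprathreshold sample, with the duration clipped to the
    given bounds. Returns ``(start_s, duration_s)`` relative to onset.
    """
    if len(error_epochs) < 5 or len(correct_epochs) < 5:
        raise ValueError("need at least 5 epochs per class")
    diff = (np.mean(error_epochs, axis=0) - np.mean(correct_epochs, axis=0)
            )[reference_channel]
    k = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(k) / k
    diff_s = np.convolve(np.abs(diff), kernel, mode="same")
    t = epoch_start_s + np.arange(diff.size) / fs
    in_range = (t >= search_range_s[0]) & (t <= search_range_s[1])
    peak = diff_s[in_range].max()
    if peak <= 1e-12:
        raise ValueError("flat difference wave; cannot select a window")
    above = in_range & (diff_s >= 0.5 * peak)
    idx = np.flatnonzero(above)
    start_idx = idx[0]
    for i in idx:
        if i + 1 >= diff_s.size or diff_s[i + 1] <= diff_s[i]:
            start_idx = i           # first suprathreshold local peak / plateau
            break
    end_idx = idx[-1]
    start = float(t[start_idx])
    duration = float(np.clip(t[end_idx] - start, *duration_bounds_s))
    start = min(start, EPOCH_WINDOW_S[1] - duration)
    return start, duration


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------


@dataclass
class ErrPDetector:
    """Sliding PCA + shrinkage-LDA classifier with a tuned threshold."""

    window_s: tuple[float, float]     # (start, duration) relative to onset
    pca: object                       # fitted sklearn PCA
    slda: SldaModel
    tau: float = 0.5
    consecutive: int = 3
    fs: float = 100.0
    epoch_start_s: float = EPOCH_WINDOW_S[0]
    curves: dict = field(default_factory=dict)

    @property
    def n_window_samples(self) -> int:
        return int(round(self.window_s[1] * self.fs))

    def _effective_weights(self) -> tuple[np.ndarray, float]:
        w = self.pca.components_.T @ self.slda.weights
        b = float(self.slda.bias - w @ self.pca.mean_)
        return w, b

    def window_features(self, epochs: np.ndarray) -> np.ndarray:
        """Flattened channel x time amplitudes of the discriminative window.

        ``epochs`` is trials x channels x samples on the epoching grid; the
        window is half-open, so 60 channels and 0.385 s at 100 Hz give
        60 x 38 = 2280 features.
        """
        s0 = int(round((self.window_s[0] - self.epoch_start_s) * self.fs))
        n = self.n_window_samples
        if s0 < 0 or s0 + n > epochs.shape[-1]:
            raise ValueError("discriminative window falls outside the epochs")
        return epochs[..., s0:s0 + n].reshape(epochs.shape[0], -1)

    def posterior_stream(self, stream: np.ndarray) -> np.ndarray:
        """Error posterior of the sliding window ending at each sample.

        Samples before the first complete window get posterior 0. Linear
        in the data, so the PCA projection and discriminant collapse into
        one correlation with an effective spatiotemporal weight pattern.
        """
        n = self.n_window_samples
        T = stream.shape[-1]
        p = np.zeros(T)
        if T < n:
            return p
        w, b = self._effective_weights()
        wins = sliding_window_view(stream, n, axis=-1)     # (ch, T-n+1, n)
        score = np.einsum("cpw,cw->p", wins,
                          w.reshape(stream.shape[0], n)) + b
        p[n - 1:] = 1.0 / (1.0 + np.exp(-np.clip(score, -500, 500)))
        return p


def fit_errp(epochs: np.ndarray, labels: np.ndarray,
             window_s: tuple[float, float], fs: float = 100.0,
             epoch_start_s: float = EPOCH_WINDOW_S[0],
             variance_target: float = 0.99) -> ErrPDetector:
    """Fit PCA (99% variance) + shrinkage LDA on window features.

    ``labels`` are truthy for error trials. The PCA basis is estimated on
    the given (training) epochs only; the threshold is left untuned.
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("need both error and correct epochs")
    det = ErrPDetector(window_s=window_s, pca=None, slda=None, fs=fs,
                       epoch_start_s=epoch_start_s)
    feats = det.window_features(np.asarray(epochs, dtype=float))
    pca, projected = pca_reduce(feats, variance_target)
    det.pca = pca
    det.slda = train_slda(projected, y.astype(int))
    return det


# ---------------------------------------------------------------------------
# asynchronous detection
# ---------------------------------------------------------------------------


def detections_from_posteriors(p: np.ndarray, tau: float,
                               consecutive: int = 3) -> np.ndarray:
    """Sample indices where the posterior has exceeded ``tau`` on the last
    ``consecutive`` samples (every such sample is reported)."""
    above = np.asarray(p) > tau
    mask = above.copy()
    for k in range(1, consecutive):
        mask[k:] &= above[:-k]
    mask[:consecutive - 1] = False
    return np.flatnonzero(mask)


def async_detect(detector: ErrPDetector, errp_stream: np.ndarray,
                 trial_bounds: list[tuple[float, float]] | None = None,
                 ) -> list[np.ndarray] | np.ndarray:
    """Slide the classifier one sample at a time over a 100 Hz stream.

    Returns detection times in seconds (stream clock). With
    ``trial_bounds`` (start, end) pairs, detection times are grouped per
    trial, with the posterior computed within each segment (as online,
    where buffers reset between trials).
    """
    if trial_bounds is None:
        p = detector.posterior_stream(errp_stream)
        return detections_from_posteriors(p, detector.tau,
                                          detector.consecutive) / detector.fs
    out = []
    for start_s, end_s in trial_bounds:
        s0 = int(round(start_s * detector.fs))
        s1 = int(round(end_s * detector.fs))
        p = detector.posterior_stream(errp_stream[..., s0:s1])
        ks = detections_from_posteriors(p, detector.tau, detector.consecutive)
        out.append(start_s + ks / detector.fs)
    return out


# ---------------------------------------------------------------------------
# threshold optimization and evaluation
# ---------------------------------------------------------------------------


def moving_average(y: np.ndarray, n: int = SMOOTH_SAMPLES) -> np.ndarray:
    """Centered moving average with edge-aware normalization (a constant
    input stays exactly constant)."""
    kernel = np.ones(n)
    return np.convolve(y, kernel, "same") / np.convolve(np.ones_like(y), kernel, "same")


def _trial_outcomes(p: np.ndarray, grid: np.ndarray, onset_idx: int,
                    fs: float, consecutive: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(any_pre, any_post, any_at_all) per threshold for one posterior stream."""
    above = p[None, :] > np.asarray(grid)[:, None]
    mask = above.copy()
    for k in range(1, consecutive):
        mask[:, k:] &= above[:, :-k]
    mask[:, :consecutive - 1] = False
    post_end = min(onset_idx + int(round(POST_ONSET_TP_S * fs)) + 1, mask.shape[1])
    any_pre = mask[:, :onset_idx].any(axis=1)
    any_post = mask[:, onset_idx:post_end].any(axis=1)
    return any_pre, any_post, mask.any(axis=1)


def _rates_for_trials(det: ErrPDetector, epochs: np.ndarray, labels: np.ndarray,
                      grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Asynchronous TPR and TNR per threshold over the given trials."""
    onset_idx = int(round(-det.epoch_start_s * det.fs))
    tp = np.zeros(len(grid))
    tn = np.zeros(len(grid))
    n_err = int(np.sum(labels))
    n_cor = len(labels) - n_err
    for ep, is_err in zip(epochs, labels):
        p = det.posterior_stream(ep)
        any_pre, any_post, any_all = _trial_outcomes(
            p, grid, onset_idx, det.fs, det.consecutive)
        if is_err:
            tp += (~any_pre) & any_post
        else:
            tn += ~any_all
    tpr = tp / n_err if n_err else np.zeros(len(grid))
    tnr = tn / n_cor if n_cor else np.zeros(len(grid))
    return tpr, tnr


def _select_tau(tpr: np.ndarray, tnr: np.ndarray, grid: np.ndarray,
                ) -> tuple[float, np.ndarray, np.ndarray]:
    tpr_s = moving_average(tpr)
    tnr_s = moving_average(tnr)
    product = tpr_s * tnr_s
    best = product.max()
    tau = float(grid[np.flatnonzero(product == best)[0]])  # smallest maximizer
    return tau, tpr_s, tnr_s


def optimize_threshold(epochs: np.ndarray, labels: np.ndarray,
                       window_s: tuple[float, float],
                       grid: tuple[float, ...] = THRESHOLD_GRID,
                       n_repetitions: int = 5, n_folds: int = 5,
                       fs: float = 100.0, seed: int = 0,
                       ) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-validated threshold tuning.

    Per repetition x fold the PCA+sLDA stage is refit on the training
    trials and the asynchronous detection is simulated on the held-out
    segments. TPR/TNR are averaged across folds per threshold, smoothed
    with a 7-sample moving average, and τ maximizes the smoothed
    TPR x TNR product (ties resolve to the smallest τ, favoring
    sensitivity).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    y = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(seed)
    tpr_sum = np.zeros(grid.size)
    tnr_sum = np.zeros(grid.size)
    n_evals = 0
    idx_err = np.flatnonzero(y)
    idx_cor = np.flatnonzero(~y)
    for _ in range(n_repetitions):
        err_folds = [np.sort(f) for f in np.array_split(rng.permutation(idx_err), n_folds)]
        cor_folds = [np.sort(f) for f in np.array_split(rng.permutation(idx_cor), n_folds)]
        for f in range(n_folds):
            test = np.r_[err_folds[f], cor_folds[f]]
            train = np.setdiff1d(np.arange(len(y)), test)
            det = fit_errp(epochs[train], y[train], window_s, fs=fs)
            tpr, tnr = _rates_for_trials(det, epochs[test], y[test], grid)
            tpr_sum += tpr
            tnr_sum += tnr
            n_evals += 1
    tpr_avg = tpr_sum / n_evals
    tnr_avg = tnr_sum / n_evals
    tau, tpr_s, tnr_s = _select_tau(tpr_avg, tnr_avg, grid)
    return tau, {"grid": grid, "tpr": tpr_avg, "tnr": tnr_avg,
                 "tpr_smooth": tpr_s, "tnr_smooth": tnr_s}


def calibrate_errp(epochs: np.ndarray, labels: np.ndarray,
                   reference_channel: int, fs: float = 100.0, seed: int = 0,
                   window_s: tuple[float, float] | None = None,
                   n_repetitions: int = 5, n_folds: int = 5) -> ErrPDetector:
    """Full calibration: window selection, PCA+sLDA fit on all trials,
    cross-validated threshold tuning."""
    y = np.asarray(labels).astype(bool)
    if window_s is None:
        window_s = select_window(epochs[y], epochs[~y], reference_channel, fs=fs)
    tau, curves = optimize_threshold(epochs, y, window_s, fs=fs, seed=seed,
                                     n_repetitions=n_repetitions, n_folds=n_folds)
    det = fit_errp(epochs, y, window_s, fs=fs)
    det.tau = tau
    det.curves = curves
    return det


@dataclass
class ErrPMetrics:
    tpr: float
    tnr: float
    latencies_s: list[float]      # first-detection latency after onset, TP trials


def evaluate_errp(det: ErrPDetector, epochs: np.ndarray, labels: np.ndarray,
                  ) -> ErrPMetrics:
    """Trial-level TPR/TNR of the tuned detector on epoched segments."""
    y = np.asarray(labels).astype(bool)
    grid = np.array([det.tau])
    tpr, tnr = _rates_for_trials(det, np.asarray(epochs, dtype=float), y, grid)
    onset_idx = int(round(-det.epoch_start_s * det.fs))
    latencies = []
    for ep, is_err in zip(epochs, y):
        if not is_err:
            continue
        p = det.posterior_stream(ep)
        ks = detections_from_posteriors(p, det.tau, det.consecutive)
        ks = ks[ks >= onset_idx]
        if ks.size:
            latencies.append(float((ks[0] - onset_idx) / det.fs))
    return ErrPMetrics(tpr=float(tpr[0]), tnr=float(tnr[0]), latencies_s=latencies)


# ---------------------------------------------------------------------------
# chance levels
# ---------------------------------------------------------------------------


def errp_chance(epochs: np.ndarray, labels: np.ndarray,
                window_s: tuple[float, float],
                grid: tuple[float, ...] = THRESHOLD_GRID,
                n_repetitions: int = 5, n_folds: int = 5, n_shuffles: int = 20,
                percentile: float = 95.0, fs: float = 100.0, seed: int = 0,
                ) -> dict[str, float | np.ndarray]:
    """Shuffle-based chance TPR/TNR for the full fit + tune + detect pipeline.

    Per repetition x fold x shuffle the trial labels are permuted, the
    classifier refit on part of the shuffled training portion, τ re-tuned
    on the held-out remainder of the training portion (tuning on the fit
    trials themselves would let the overfit classifier pick degenerate
    thresholds), and TPR/TNR scored on the test trials. Bounds are the
    requested upper percentile across all iterations.
    """
    epochs = np.asarray(epochs, dtype=float)
    y = np.asarray(labels).astype(bool)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    tpr_vals, tnr_vals = [], []
    idx_err = np.flatnonzero(y)
    idx_cor = np.flatnonzero(~y)
    for _ in range(n_repetitions):
        err_folds = [np.sort(f) for f in np.array_split(rng.permutation(idx_err), n_folds)]
        cor_folds = [np.sort(f) for f in np.array_split(rng.permutation(idx_cor), n_folds)]
        for f in range(n_folds):
            test = np.r_[err_folds[f], cor_folds[f]]
            train = np.setdiff1d(np.arange(len(y)), test)
            for _ in range(n_shuffles):
                y_sh = y[rng.permutation(len(y))]
                split = rng.permutation(train)
                n_fit = max(int(round(0.7 * len(split))), 2)
                fit_idx, tune_idx = split[:n_fit], split[n_fit:]
                if (y_sh[fit_idx].all() or not y_sh[fit_idx].any()
                        or not len(tune_idx)):
                    continue
                det = fit_errp(epochs[fit_idx], y_sh[fit_idx], window_s, fs=fs)
                tpr_tu, tnr_tu = _rates_for_trials(det, epochs[tune_idx],
                                                   y_sh[tune_idx], grid)
                det.tau, _, _ = _select_tau(tpr_tu, tnr_tu, grid)
                m = evaluate_errp(det, epochs[test], y_sh[test])
                tpr_vals.append(m.tpr)
                tnr_vals.append(m.tnr)
    tpr_vals = np.asarray(tpr_vals)
    tnr_vals = np.asarray(tnr_vals)
    return {"tpr_bound": float(np.percentile(tpr_vals, percentile)),
            "tnr_bound": float(np.percentile(tnr_vals, percentile)),
            "tpr_null": tpr_vals, "tnr_null": tnr_vals}
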