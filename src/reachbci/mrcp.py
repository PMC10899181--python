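"""Goal-directed movement-intention detection from MRCPs.

Two shrinkage-LDA classifiers operate on 1 s windows of the cleaned,
3 Hz low-passed, 10 Hz EEG: M1 separates attempted goal-directed
movement ("movlook") from rest, M2 separates it from gaze shifts alone
("onlylook"). Online, M1 posteriors stream into a 1 s buffer; once a
per-user fraction of the buffer (the *time-fraction*) exceeds 0.9, M2
is consulted, and a movement attempt is confirmed when the M2 posterior
exceeds 0.9 on two consecutive consulted samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .mlcore import ShuffleNullResult, SldaModel, shuffle_null, slda_accuracy_evaluator, train_slda
from .session import Stream

TIME_FRACTION_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))
TP_WINDOW_S = (-1.5, 1.0)   # detection window around saccade onset


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def extract_mrcp_features(stream: Stream, anchor_times_s: np.ndarray,
                          window_s: tuple[float, float] = (-0.5, 0.5),
                          ) -> tuple[np.ndarray, int]:
    """Flattened channel x sample amplitudes in ``[window_s)`` around anchors.

    The window is half-open at 10 Hz (1 s -> 10 samples per channel, so 55
    channels give 550 features). Epochs reaching outside the stream are
    skipped; the skip count is returned alongside the feature matrix.
    Feature order is channel-major: reshaping a row to (n_channels,
    n_window) recovers the epoch matrix.
    """
    fs = stream.fs
    n_win = int(round((window_s[1] - window_s[0]) * fs))
    rows, skipped = [], 0
    for t in np.atleast_1d(anchor_times_s):
        start = int(round((t + window_s[0]) * fs))
        if start < 0 or start + n_win > stream.n_samples:
            skipped += 1
            continue
        rows.append(stream.data[:, start:start + n_win].ravel())
    feats = np.asarray(rows) if rows else np.empty((0, stream.data.shape[0] * n_win))
    return feats, skipped


def extract_rest_features(stream: Stream, segments: list[tuple[float, float]],
                          epoch_s: float = 1.0) -> np.ndarray:
    """Non-overlapping ``epoch_s`` windows from rest/eye-movement segments."""
    n_win = int(round(epoch_s * stream.fs))
    rows = []
    for onset, duration in segments:
        start = int(round(onset * stream.fs))
        stop = min(int(round((onset + duration) * stream.fs)), stream.n_samples)
        for s in range(start, stop - n_win + 1, n_win):
            rows.append(stream.data[:, s:s + n_win].ravel())
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# hierarchical asynchronous detection
# ---------------------------------------------------------------------------


@dataclass
class DetectionEvent:
    time_s: float
    stage: str = "confirmed"    # m1-gate | confirmed
    trial: int | None = None


@dataclass
class HierarchicalMRCPDetector:
    m1: SldaModel
    m2: SldaModel
    time_fraction: float = 0.5
    prob_threshold: float = 0.9
    buffer_s: float = 1.0
    rate_hz: float = 10.0
    m2_consecutive: int = 2
    window_s: tuple[float, float] = (-0.5, 0.5)
    scores: dict = field(default_factory=dict)

    @property
    def buffer_len(self) -> int:
        return int(round(self.buffer_s * self.rate_hz))

    @property
    def detection_offset_s(self) -> float:
        """Lag between a stream sample and the center of its feature window."""
        n_win = int(round((self.window_s[1] - self.window_s[0]) * self.rate_hz))
        return (n_win - 1) / 2.0 / self.rate_hz

    def probability_streams(self, stream: Stream) -> tuple[np.ndarray, np.ndarray]:
        """Sliding M1/M2 posteriors: at sample k the classifiers see the last
        1 s of data; samples before the first full window get probability 0."""
        n_win = int(round((self.window_s[1] - self.window_s[0]) * self.rate_hz))
        T = stream.n_samples
        p1 = np.zeros(T)
        p2 = np.zeros(T)
        if T < n_win:
            return p1, p2
        wins = sliding_window_view(stream.data, n_win, axis=1)  # (ch, T-n+1, n)
        feats = wins.transpose(1, 0, 2).reshape(T - n_win + 1, -1)
        p1[n_win - 1:] = self.m1.predict_proba(feats)[:, 1]
        p2[n_win - 1:] = self.m2.predict_proba(feats)[:, 1]
        return p1, p2


def hierarchical_detect(p1: np.ndarray, p2: np.ndarray,
                        detector: HierarchicalMRCPDetector) -> np.ndarray:
    """Run the asynchronous hierarchical rule over aligned probability streams.

    At each sample, once the M1 buffer holds a full second, the M2 output is
    consulted whenever the fraction of buffered M1 posteriors above the
    threshold reaches the time-fraction; a detection fires at the
    ``m2_consecutive``-th consecutive consulted sample with M2 above the
    threshold. The buffer and the consecutive counter reset after each
    detection. Returns detection sample indices.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("probability streams must be aligned")
    L = detector.buffer_len
    thr = detector.prob_threshold
    tf = detector.time_fraction
    above = p1 > thr
    detections = []
    buffer_start = 0
    count = 0
    for k in range(p1.size):
        if k - buffer_start + 1 < L:
            continue
        frac = above[k - L + 1:k + 1].mean()
        if frac >= tf:                      # M1 gate open: consult M2
            count = count + 1 if p2[k] > thr else 0
            if count >= detector.m2_consecutive:
                detections.append(k)
                buffer_start = k + 1
                count = 0
    return np.asarray(detections, dtype=int)


def detect_on_stream(detector: HierarchicalMRCPDetector, stream: Stream,
                     trial: int | None = None) -> list[DetectionEvent]:
    """Sliding classification + hierarchical rule on a 10 Hz reaching stream.

    Detection timestamps are reported at the center of the feature window
    feeding the detection sample (the stream-time convention used for the
    TP/FP scoring windows).
    """
    p1, p2 = detector.probability_streams(stream)
    ks = hierarchical_detect(p1, p2, detector)
    off = detector.detection_offset_s
    return [DetectionEvent(time_s=k / detector.rate_hz - off, trial=trial) for k in ks]


# ---------------------------------------------------------------------------
# calibration data and time-fraction optimization
# ---------------------------------------------------------------------------


@dataclass
class MrcpTrial:
    """One reaching-phase trial: its 10 Hz stream and the saccade anchor."""

    stream: Stream
    saccade_time_s: float
    condition: str              # movlook | onlylook


@dataclass
class MrcpCalibration:
    trials: list[MrcpTrial]
    rest_features: np.ndarray
    window_s: tuple[float, float] = (-0.5, 0.5)

    def condition_features(self, condition: str) -> np.ndarray:
        rows = []
        for tr in self.trials:
            if tr.condition != condition:
                continue
            f, _ = extract_mrcp_features(tr.stream, np.array([tr.saccade_time_s]),
                                         self.window_s)
            if len(f):
                rows.append(f[0])
        return np.asarray(rows)


def _fit_m1_m2(movlook: np.ndarray, onlylook: np.ndarray, rest: np.ndarray,
               ) -> tuple[SldaModel, SldaModel]:
    X1 = np.vstack([rest, movlook])
    y1 = np.r_[np.zeros(len(rest)), np.ones(len(movlook))]
    X2 = np.vstack([onlylook, movlook])
    y2 = np.r_[np.zeros(len(onlylook)), np.ones(len(movlook))]
    return train_slda(X1, y1), train_slda(X2, y2)


def _trial_correct(detector: HierarchicalMRCPDetector, trial: MrcpTrial,
                   p1: np.ndarray, p2: np.ndarray) -> bool:
    ks = hierarchical_detect(p1, p2, detector)
    rel = ks / detector.rate_hz - detector.detection_offset_s - trial.saccade_time_s
    in_tp = (rel >= TP_WINDOW_S[0]) & (rel <= TP_WINDOW_S[1])
    in_fp = rel < TP_WINDOW_S[0]
    return bool(in_tp.any() and not in_fp.any())


def _group_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    return [np.sort(part) for part in np.array_split(rng.permutation(n), n_folds)]


def optimize_time_fraction(calib: MrcpCalibration,
                           grid: tuple[float, ...] = TIME_FRACTION_GRID,
                           n_repetitions: int = 5, n_folds: int = 5,
                           seed: int = 0, **detector_kwargs,
                           ) -> tuple[float, dict[float, float]]:
    """Cross-validated time-fraction selection.

    For every repetition x fold, M1/M2 are refit on the training split and
    the asynchronous hierarchical rule is simulated on the held-out movlook
    trials; a trial counts as correct when at least one detection falls in
    the TP window ([-1.5, 1] s around the saccade) and none earlier. The
    proportion correct is averaged per candidate value; ties resolve to the
    largest (most conservative) time-fraction.
    """
    if not len(grid):
        raise ValueError("empty time-fraction grid")
    rng = np.random.default_rng(seed)
    mov = [t for t in calib.trials if t.condition == "movlook"]
    onl = [t for t in calib.trials if t.condition == "onlylook"]
    rest = calib.rest_features

    def feats(trials: list[MrcpTrial]) -> np.ndarray:
        return np.asarray([
            extract_mrcp_features(t.stream, np.array([t.saccade_time_s]),
                                  calib.window_s)[0][0]
            for t in trials
        ])

    totals = {tf: 0.0 for tf in grid}
    n_evals = 0
    for _ in range(n_repetitions):
        mov_folds = _group_folds(len(mov), n_folds, rng)
        onl_folds = _group_folds(len(onl), n_folds, rng)
        rest_folds = _group_folds(len(rest), n_folds, rng)
        for f in range(n_folds):
            mov_tr = [mov[i] for i in np.setdiff1d(np.arange(len(mov)), mov_folds[f])]
            onl_tr = [onl[i] for i in np.setdiff1d(np.arange(len(onl)), onl_folds[f])]
            rest_tr = rest[np.setdiff1d(np.arange(len(rest)), rest_folds[f])]
            m1, m2 = _fit_m1_m2(feats(mov_tr), feats(onl_tr), rest_tr)
            probe = HierarchicalMRCPDetector(m1=m1, m2=m2, **detector_kwargs)
            test_trials = [mov[i] for i in mov_folds[f]]
            streams = [probe.probability_streams(t.stream) for t in test_trials]
            for tf in grid:
                probe.time_fraction = tf
                correct = sum(
                    _trial_correct(probe, t, p1, p2)
                    for t, (p1, p2) in zip(test_trials, streams)
                )
                totals[tf] += correct / max(len(test_trials), 1)
            n_evals += 1
    scores = {tf: totals[tf] / n_evals for tf in grid}
    best = max(scores.values())
    chosen = max(tf for tf, s in scores.items() if s == best)
    return chosen, scores


def calibrate_mrcp(calib: MrcpCalibration, grid: tuple[float, ...] = TIME_FRACTION_GRID,
                   n_repetitions: int = 5, n_folds: int = 5, seed: int = 0,
                   ) -> HierarchicalMRCPDetector:
    """Optimize the time-fraction, then refit M1/M2 on all calibration data."""
    tf, scores = optimize_time_fraction(calib, grid, n_repetitions, n_folds, seed)
    m1, m2 = _fit_m1_m2(calib.condition_features("movlook"),
                        calib.condition_features("onlylook"), calib.rest_features)
    det = HierarchicalMRCPDetector(m1=m1, m2=m2, time_fraction=tf,
                                   window_s=calib.window_s)
    det.scores = {"time_fraction_scores": scores}
    return det


# ---------------------------------------------------------------------------
# chance levels
# ---------------------------------------------------------------------------


def mrcp_chance(calib: MrcpCalibration, n_repetitions: int = 5, n_folds: int = 5,
                n_shuffles: int = 20, percentile: float = 95.0, seed: int = 0,
                ) -> dict[str, float | ShuffleNullResult]:
    """Shuffle-based chance accuracies for M1, M2 and the hierarchical stage.

    The hierarchical chance bound is the product of the M1 and M2 bounds
    (both classifiers must assent for a confirmed detection).
    """
    mov = calib.condition_features("movlook")
    onl = calib.condition_features("onlylook")
    rest = calib.rest_features
    X1 = np.vstack([rest, mov])
    y1 = np.r_[np.zeros(len(rest)), np.ones(len(mov))]
    X2 = np.vstack([onl, mov])
    y2 = np.r_[np.zeros(len(onl)), np.ones(len(mov))]
    kw = dict(n_repetitions=n_repetitions, n_folds=n_folds,
              n_shuffles=n_shuffles, percentile=percentile)
    null1 = shuffle_null(y1, slda_accuracy_evaluator(X1), seed=seed, **kw)
    null2 = shuffle_null(y2, slda_accuracy_evaluator(X2), seed=seed + 1, **kw)
    b1 = null1.bounds["metric"]
    b2 = null2.bounds["metric"]
    return {"m1_bound": b1, "m2_bound": b2, "hierarchical_bound": b1 * b2,
            "m1_null": null1, "m2_null": null2}
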