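"""Closed-loop feedback simulation.

Replays a scheduled online session against the three calibrated
decoders: the hierarchical intention detector launches (or times out)
the reaching phase, the trajectory decoder drives the cursor during
tracking mixed with a delayed copy of the snake (α = 0.5 or 1.0 EEG
control), and on error trials the cursor deviates 90° off the snake
until the asynchronous ErrP detector calls the error (cursor rejoins)
or 1.5 s elapse (cursor disappears).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errp import ErrPDetector, detections_from_posteriors
from .mrcp import TP_WINDOW_S, HierarchicalMRCPDetector, hierarchical_detect
from .paradigm import (ERROR_ONSET_RANGE_S, TRACKING_DURATION_S, SnakeTrajectory,
                       TrialSchedule, generate_snake)
from .pipeline import ProcessedRun, process_run, saccade_anchor
from .preprocess import EogModel, PreprocConfig, TransientStats
from .session import RawSession, Stream
from .trajectory import PLSUKFModel, build_lag_matrix, ukf_decode

REACH_TIMEOUT_S = 5.0
ERROR_ACTION_WINDOW_S = 1.5      # cursor disappears this long after the onset
DEFAULT_SNAKE_DELAY_S = 0.14     # replayed-cursor delay mimicking pipeline latency


def inject_error(snake: SnakeTrajectory, onset_s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Cursor path deviating 90° from the snake at the error onset.

    From the onset the cursor velocity is the snake velocity rotated by a
    randomly-signed right angle (speed preserved) for up to 1.5 s; the
    path before the onset is the snake itself. Returns a 2 x T position
    array on the snake clock.
    """
    if not ERROR_ONSET_RANGE_S[0] <= onset_s <= ERROR_ONSET_RANGE_S[1]:
        raise ValueError(
            f"error onset {onset_s:g} s outside {ERROR_ONSET_RANGE_S} s")
    k0 = int(round(onset_s * snake.fs))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    rot = np.array([[0.0, -sign], [sign, 0.0]])
    v = np.vstack([snake.vx, snake.vy])
    pos = np.vstack([snake.px, snake.py]).copy()
    k1 = min(k0 + int(round(ERROR_ACTION_WINDOW_S * snake.fs)), pos.shape[1])
    v_rot = rot @ v[:, k0:k1]
    pos[:, k0:k1] = pos[:, [k0]] + np.cumsum(v_rot, axis=1) / snake.fs
    if k1 < pos.shape[1]:
        pos[:, k1:] = pos[:, [k1 - 1]]
    return pos


def delayed_snake(snake: SnakeTrajectory, delay_s: float) -> np.ndarray:
    """Snake positions shifted later by the processing-latency delay."""
    shift = int(round(delay_s * snake.fs))
    pos = np.vstack([snake.px, snake.py])
    if shift == 0:
        return pos
    out = np.empty_like(pos)
    out[:, shift:] = pos[:, :-shift or None]
    out[:, :shift] = pos[:, [0]]
    return out


@dataclass
class TrialLog:
    run: str
    trial: int
    alpha: float
    detected: bool                 # intention detection before timeout
    detection_time_s: float | None
    timeout: bool
    intention_correct: bool        # detection inside the TP window, none before
    error_trial: bool = False
    errp_detected: bool | None = None
    errp_latency_s: float | None = None
    cursor: np.ndarray | None = None       # 2 x T positions, 20 Hz
    cursor_present: np.ndarray | None = None


@dataclass
class SessionLog:
    trials: list[TrialLog] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{k: v for k, v in t.__dict__.items()
                              if k not in ("cursor", "cursor_present")}
                             for t in self.trials])


def _reaching_outcome(detector: HierarchicalMRCPDetector, stream: Stream,
                      saccade_s: float) -> tuple[bool, float | None, bool]:
    p1, p2 = detector.probability_streams(stream)
    ks = hierarchical_detect(p1, p2, detector)
    rel = ks / detector.rate_hz - detector.detection_offset_s - saccade_s
    in_tp = (rel >= TP_WINDOW_S[0]) & (rel <= TP_WINDOW_S[1])
    correct = bool(in_tp.any() and not (rel < TP_WINDOW_S[0]).any())
    det_time = float(ks[0] / detector.rate_hz) if ks.size else None
    detected = det_time is not None and det_time <= REACH_TIMEOUT_S + saccade_s
    return detected, det_time, correct


def run_session(runs: dict[str, RawSession], schedule: TrialSchedule,
                mrcp_detector: HierarchicalMRCPDetector, plsukf: PLSUKFModel,
                errp_detector: ErrPDetector, cfg: PreprocConfig,
                eog_model: EogModel, seed: int = 0,
                transient_stats: TransientStats | None = None,
                snake_delay_s: float = DEFAULT_SNAKE_DELAY_S) -> SessionLog:
    """Simulate the closed loop over the online runs of a session.

    All three models must be calibrated; per trial the log records the
    intention-detection outcome, the mixed cursor trajectory and the
    error-handling outcome. Deterministic given the session and seed.
    """
    for name, model in (("intention detector", mrcp_detector),
                        ("trajectory model", plsukf),
                        ("error detector", errp_detector)):
        if model is None:
            raise ValueError(f"{name} is not calibrated")
    rng = np.random.default_rng(seed)
    log = SessionLog()
    decoded_all, target_all = [], []

    for run in schedule.runs_of("movlook", phase="online"):
        proc: ProcessedRun = process_run(runs[run.name], cfg, eog_model,
                                         transient_stats)
        reaches = proc.raw.events_of("reaching_start")
        tracking = proc.raw.events_of("tracking_start")
        for _, ev in reaches.iterrows():
            ti = int(ev.value)
            trial = run.trials[ti]
            anchor = saccade_anchor(proc.eog, ev.onset, ev.duration)
            if anchor is None:
                anchor = ev.onset + ev.duration - 1.0
            fs_m = proc.mrcp.fs
            s0 = int(round(ev.onset * fs_m))
            s1 = min(int(round((ev.onset + ev.duration + 1.5) * fs_m)),
                     proc.mrcp.n_samples)
            reach_stream = Stream(proc.mrcp.data[:, s0:s1], fs_m, proc.mrcp.labels)
            detected, det_time, correct = _reaching_outcome(
                mrcp_detector, reach_stream, anchor - ev.onset)

            entry = TrialLog(run=run.name, trial=ti, alpha=run.alpha,
                             detected=detected, detection_time_s=det_time,
                             timeout=not detected, intention_correct=correct,
                             error_trial=trial.error)

            track = tracking[tracking["value"] == ti]
            if len(track):
                t_on = float(track.iloc[0]["onset"])
                fs_t = proc.traj.fs
                k0 = int(round(t_on * fs_t))
                n_t = int(round(TRACKING_DURATION_S * fs_t))
                seg = proc.traj.data[:, k0:k0 + n_t]
                X = build_lag_matrix(seg)
                dec = ukf_decode(plsukf, X)
                snake = generate_snake(np.random.default_rng(trial.snake_seed))
                n_lag_off = seg.shape[1] - X.shape[1]
                delayed = delayed_snake(snake, snake_delay_s)
                mix_target = delayed[:, n_lag_off:]
                cursor = (run.alpha * dec[:2]
                          + (1.0 - run.alpha) * mix_target[:, :dec.shape[1]])
                present = np.ones(cursor.shape[1], dtype=bool)

                if trial.error:
                    deviated = inject_error(snake, trial.error_onset_s, rng)
                    e_rel = trial.error_onset_s
                    fs_e = errp_detector.fs
                    seg_e = proc.errp.data[
                        :, int(round(t_on * fs_e)):int(round((t_on
                            + TRACKING_DURATION_S) * fs_e))]
                    p = errp_detector.posterior_stream(seg_e)
                    ks = detections_from_posteriors(
                        p, errp_detector.tau, errp_detector.consecutive)
                    rel = ks / fs_e - e_rel
                    hits = rel[(rel > 0) & (rel <= ERROR_ACTION_WINDOW_S)]
                    entry.errp_detected = bool(hits.size)
                    k_dev = max(int(round(e_rel * fs_t)) - n_lag_off, 0)
                    if hits.size:
                        entry.errp_latency_s = float(hits[0])
                        k_rejoin = max(
                            int(round((e_rel + hits[0]) * fs_t)) - n_lag_off, 0)
                        # system-imposed deviation until the detected ErrP
                        # snaps the cursor back onto the snake
                        cursor[:, k_dev:k_rejoin] = deviated[
                            :, k_dev + n_lag_off:k_rejoin + n_lag_off]
                        cursor[:, k_rejoin:] = mix_target[
                            :, k_rejoin:cursor.shape[1]]
                    else:
                        k_gone = max(int(round((e_rel + ERROR_ACTION_WINDOW_S)
                                               * fs_t)) - n_lag_off, 0)
                        cursor[:, k_dev:k_gone] = deviated[
                            :, k_dev + n_lag_off:k_gone + n_lag_off]
                        present[k_gone:] = False
                else:
                    decoded_all.append(dec[:2])
                    target_all.append(snake.kinematics()[:2, n_lag_off:])
                entry.cursor = cursor
                entry.cursor_present = present
            log.trials.append(entry)

    frame = log.frame()
    metrics: dict = {}
    if len(frame):
        metrics["detection_rate"] = float(frame["intention_correct"].mean())
        metrics["timeout_rate"] = float(frame["timeout"].mean())
        err = frame[frame["error_trial"]]
        if len(err):
            metrics["online_tpr"] = float(err["errp_detected"].mean())
    if decoded_all:
        dec = np.concatenate(decoded_all, axis=1)
        tar = np.concatenate(target_all, axis=1)
        metrics["r_x"] = float(np.corrcoef(dec[0], tar[0])[0, 1])
        metrics["r_y"] = float(np.corrcoef(dec[1], tar[1])[0, 1])
    log.metrics = metrics
    return log
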