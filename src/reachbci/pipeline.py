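"""End-to-end calibration assembly: runs -> decoder-ready data structures.

Glues the processing chains to the paradigm: fits the EOG regression on
the eyeblock run, pushes every run through the common and branch chains,
anchors reaching-phase trials on EOG-detected saccades, cuts tracking
segments into lag-feature/kinematic-target pairs (with artifact-based
trial rejection), and epochs the error-potential stream around real and
virtual error onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import errp as errp_mod
from .mrcp import MrcpCalibration, MrcpTrial, extract_rest_features
from .paradigm import (TRACKING_DURATION_S, TrialSchedule, detect_saccade,
                       generate_snake)
from .preprocess import (EogModel, PreprocConfig, Stream, TransientStats,
                         apply_filter, design_highpass018, common_filter,
                         estimate_transient_stats, fit_eog_model,
                         preprocess_common, preprocess_errp_branch,
                         preprocess_movement_branch)
from .session import RawSession
from .trajectory import build_lag_matrix, reject_trials


@dataclass
class ProcessedRun:
    """All branch streams of one run, on the common clocks."""

    mrcp: Stream       # 10 Hz, 55 channels
    traj: Stream       # 20 Hz, 55 channels
    errp: Stream       # 100 Hz, 60 channels
    eog: Stream        # 100 Hz
    raw: RawSession


@dataclass
class CalibrationData:
    mrcp: MrcpCalibration
    traj_X: list[np.ndarray]          # 385 x T lag matrices, kept trials
    traj_Y: list[np.ndarray]          # 6 x T kinematic targets
    traj_rejected: list[int]
    errp_epochs: np.ndarray           # trials x 60 x 150
    errp_labels: np.ndarray           # bool, True = error trial
    errp_reference_channel: int
    eog_model: EogModel = None
    transient_stats: TransientStats | None = None


def fit_artifact_models(eyeblock: RawSession, cfg: PreprocConfig,
                        ) -> tuple[EogModel, TransientStats]:
    """Fit the EOG regression and the transient reference statistics on an
    eyeblock run (rest + saccades + blinks)."""
    eeg100, eog100 = common_filter(eyeblock, cfg)
    eog_model = fit_eog_model(eeg100.data, eog100.data, fs=eeg100.fs)

    clean = eog_model.apply(eeg100.data, eog100.data)
    keep = ~eyeblock.montage.is_af_row
    hp = apply_filter(design_highpass018(eeg100.fs), clean[keep], cfg.causal_mode)
    hp -= hp.mean(axis=0, keepdims=True)
    rest = eyeblock.events_of("rest")
    if len(rest):
        s0 = int(round(rest.loc[0, "onset"] * eeg100.fs)) + int(eeg100.fs)
        s1 = int(round((rest.loc[0, "onset"] + rest.loc[0, "duration"]) * eeg100.fs))
        hp = hp[:, s0:s1]
    return eog_model, estimate_transient_stats(hp)


def process_run(raw: RawSession, cfg: PreprocConfig, eog_model: EogModel,
                transient_stats: TransientStats | None = None) -> ProcessedRun:
    """Push one run through the common stage and all three branches."""
    eeg60, eog100 = preprocess_common(raw, cfg, eog_model, keep_af=True)
    keep = ~raw.montage.is_af_row
    eeg55 = Stream(eeg60.data[keep], eeg60.fs,
                   tuple(l for l, k in zip(eeg60.labels, keep) if k))
    montage55 = raw.montage.subset(keep)
    mrcp, traj = preprocess_movement_branch(eeg55, cfg, montage55, transient_stats)
    errp = preprocess_errp_branch(eeg60, cfg)
    return ProcessedRun(mrcp=mrcp, traj=traj, errp=errp, eog=eog100, raw=raw)


# ---------------------------------------------------------------------------
# reaching-phase anchoring
# ---------------------------------------------------------------------------


def saccade_anchor(eog: Stream, reach_onset_s: float, reach_duration_s: float,
                   threshold_mads: float = 20.0) -> float | None:
    """EOG-derivative saccade time within one reaching phase (run clock)."""
    s0 = int(round(reach_onset_s * eog.fs))
    s1 = int(round((reach_onset_s + reach_duration_s) * eog.fs))
    seg = eog.data[:, s0:s1]
    try:
        times = detect_saccade(seg, eog.fs, threshold_mads=threshold_mads,
                               baseline=slice(0, int(eog.fs)))
    except ValueError:
        return None
    return reach_onset_s + float(times[0]) if times.size else None


def _mrcp_trials_from_run(proc: ProcessedRun, condition: str,
                          post_margin_s: float = 1.5) -> list[MrcpTrial]:
    trials = []
    reaches = proc.raw.events_of("reaching_start")
    fs = proc.mrcp.fs
    for _, ev in reaches.iterrows():
        anchor = saccade_anchor(proc.eog, ev.onset, ev.duration)
        if anchor is None:
            sacc = proc.raw.events_of("saccade")
            match = sacc[sacc["value"] == ev.value]
            if not len(match):
                continue
            anchor = float(match.iloc[0]["onset"])
        s0 = int(round(ev.onset * fs))
        s1 = min(int(round((ev.onset + ev.duration + post_margin_s) * fs)),
                 proc.mrcp.n_samples)
        trials.append(MrcpTrial(
            stream=Stream(proc.mrcp.data[:, s0:s1], fs, proc.mrcp.labels),
            saccade_time_s=anchor - ev.onset,
            condition=condition,
        ))
    return trials


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------


def assemble_calibration(runs: dict[str, RawSession], schedule: TrialSchedule,
                         cfg: PreprocConfig | None = None, seed: int = 0,
                         ) -> CalibrationData:
    """Process a calibration session into decoder-ready containers.

    Fits the artifact models on the first eyeblock run, extracts
    saccade-anchored reaching trials for the intention detector, rejects
    and cuts tracking segments for the trajectory decoder, and epochs the
    ErrP stream around error (or virtual) onsets.
    """
    cfg = cfg or PreprocConfig()
    eyeblock_runs = [r for r in schedule.runs if r.condition == "eyeblock"]
    if not eyeblock_runs:
        raise ValueError("schedule contains no eyeblock run to fit artifact models")
    eog_model, tstats = fit_artifact_models(runs[eyeblock_runs[0].name], cfg)

    mrcp_trials: list[MrcpTrial] = []
    traj_epochs: list[np.ndarray] = []
    traj_targets: list[np.ndarray] = []
    errp_epoch_list: list[np.ndarray] = []
    errp_labels: list[bool] = []
    rest_features = None
    errp_rng = np.random.default_rng(seed)

    for run in schedule.runs:
        if run.phase != "calibration":
            continue
        raw = runs[run.name]
        if run.condition == "eyeblock":
            proc = process_run(raw, cfg, eog_model, tstats)
            segs = [(ev.onset, ev.duration)
                    for lab in ("rest", "eyemove_h", "eyemove_v")
                    for ev in raw.events_of(lab).itertuples()]
            feats = extract_rest_features(proc.mrcp, segs)
            rest_features = feats if rest_features is None else np.vstack(
                [rest_features, feats])
            continue

        proc = process_run(raw, cfg, eog_model, tstats)
        mrcp_trials.extend(_mrcp_trials_from_run(proc, run.condition))

        if run.condition != "movlook":
            continue
        tracking = proc.raw.events_of("tracking_start")
        errors = proc.raw.events_of("error_onset")
        for _, ev in tracking.iterrows():
            trial = run.trials[int(ev.value)]
            t20 = int(round(ev.onset * proc.traj.fs))
            n20 = int(round(TRACKING_DURATION_S * proc.traj.fs))
            if not trial.error:
                seg = proc.traj.data[:, t20:t20 + n20]
                snake = generate_snake(np.random.default_rng(trial.snake_seed))
                traj_epochs.append(seg)
                traj_targets.append(snake.kinematics())
            # error epoching on the 100 Hz branch
            if trial.error:
                match = errors[errors["value"] == ev.value]
                onset_s = float(match.iloc[0]["onset"]) if len(match) else (
                    ev.onset + trial.error_onset_s)
                label = True
            else:
                onset_s = ev.onset + float(
                    errp_mod.make_virtual_onsets(1, errp_rng)[0])
                label = False
            e0 = int(round((onset_s + errp_mod.EPOCH_WINDOW_S[0]) * proc.errp.fs))
            n_e = int(round((errp_mod.EPOCH_WINDOW_S[1]
                             - errp_mod.EPOCH_WINDOW_S[0]) * proc.errp.fs))
            if e0 >= 0 and e0 + n_e <= proc.errp.n_samples:
                errp_epoch_list.append(proc.errp.data[:, e0:e0 + n_e])
                errp_labels.append(label)

    # balance the M1 problem: keep about as many rest epochs as movlook trials
    n_mov = sum(t.condition == "movlook" for t in mrcp_trials)
    if rest_features is not None and len(rest_features) > n_mov:
        pick = np.random.default_rng(seed + 1).choice(
            len(rest_features), size=n_mov, replace=False)
        rest_features = rest_features[np.sort(pick)]

    kept, rejected, _ = reject_trials(traj_epochs)
    traj_X, traj_Y = [], []
    for i in kept:
        X = build_lag_matrix(traj_epochs[i])
        traj_X.append(X)
        traj_Y.append(traj_targets[i][:, traj_epochs[i].shape[1] - X.shape[1]:])

    any_run = runs[next(iter(runs))]
    calib = CalibrationData(
        mrcp=MrcpCalibration(trials=mrcp_trials, rest_features=rest_features),
        traj_X=traj_X, traj_Y=traj_Y, traj_rejected=list(rejected),
        errp_epochs=np.asarray(errp_epoch_list),
        errp_labels=np.asarray(errp_labels, dtype=bool),
        errp_reference_channel=any_run.montage.index("FCz"),
        eog_model=eog_model, transient_stats=tstats,
    )
    return calib
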