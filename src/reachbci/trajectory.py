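"""Distance/speed-informed trajectory decoding (PLS + Unscented Kalman Filter).

Six movement parameters — horizontal/vertical position and velocity plus
the non-directional distance (‖p‖) and speed (‖v‖) — are predicted from
385 lagged EEG features (7 lags x 55 channels at 20 Hz) by partial least
squares regression. The six PLS outputs act as measurements for an
Unscented Kalman Filter over the state [px, py, vx, vy] with a
constant-velocity transition; the nonlinear observation maps the state
to all six parameters, letting the amplitude information in distance
and speed constrain the directional estimates.

Activation patterns A = Cov(X) · W · Cov(Y) turn the backward decoding
weights into forward (interpretable) patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

N_LAGS = 7
N_CHANNELS = 55
PARAM_NAMES = ("px", "py", "vx", "vy", "distance", "speed")
DT_S = 0.05


# ---------------------------------------------------------------------------
# lag features and PLS
# ---------------------------------------------------------------------------


def build_lag_matrix(traj_data: np.ndarray, n_lags: int = N_LAGS,
                     n_channels: int = N_CHANNELS) -> np.ndarray:
    """Stack the current and previous ``n_lags - 1`` samples channel-major.

    Column ``k`` of the output holds samples t_{k-6} ... t_k (oldest lag
    first, the current sample in the last channel block); the first
    ``n_lags - 1`` time points are dropped rather than zero-padded. A
    55-channel stream yields 385 rows.
    """
    x = np.asarray(traj_data, dtype=float)
    if x.shape[0] != n_channels:
        raise ValueError(f"expected {n_channels} channels, got {x.shape[0]}")
    if x.shape[1] < n_lags:
        raise ValueError(f"need at least {n_lags} samples")
    wins = sliding_window_view(x, n_lags, axis=1)       # (ch, T-n_lags+1, n_lags)
    return wins.transpose(2, 0, 1).reshape(n_lags * n_channels, -1)


def lag_block(X: np.ndarray, lag: int, n_channels: int = N_CHANNELS) -> np.ndarray:
    """Channel rows of lag ``lag`` (0 = current sample, 6 = oldest)."""
    n_lags = X.shape[0] // n_channels
    i = n_lags - 1 - lag
    return X[i * n_channels:(i + 1) * n_channels]


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int = 10,
            ) -> tuple[np.ndarray, np.ndarray]:
    """PLS coefficients ``W`` (features x targets) and intercepts.

    ``X`` is features x T, ``Y`` targets x T. Deterministic given the
    inputs; sample order does not matter (PLS depends on cross-products
    only).
    """
    Xs = np.asarray(X, dtype=float).T
    Ys = np.asarray(Y, dtype=float).T
    if Xs.shape[0] <= n_components:
        raise ValueError("n_components must be smaller than the sample count")
    max_rank = min(Xs.shape)
    if max_rank <= 2000:
        rank = np.linalg.matrix_rank(Xs - Xs.mean(axis=0))
        if n_components > rank:
            raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, Ys)
    coef = np.asarray(pls.coef_)
    if coef.shape == (Ys.shape[1], Xs.shape[1]):
        coef = coef.T
    intercept = np.asarray(pls.intercept_).ravel()
    return coef, intercept


def pls_predict(W: np.ndarray, intercept: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predicted targets (targets x T) for a lag-feature matrix."""
    return W.T @ X + intercept[:, None]


def compute_activation_patterns(X: np.ndarray, Y: np.ndarray,
                                W: np.ndarray) -> np.ndarray:
    """Forward activation patterns A = Cov(X) · W · Cov(Y)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if W.shape != (X.shape[0], Y.shape[0]):
        raise ValueError(
            f"W must be {(X.shape[0], Y.shape[0])} for these data, got {W.shape}")
    return np.cov(X) @ W @ np.cov(Y)


# ---------------------------------------------------------------------------
# Unscented Kalman Filter
# ---------------------------------------------------------------------------


@dataclass
class UkfConfig:
    dt: float = DT_S
    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0
    divergence_bound: float = 1e6
    jitter: float = 1e-9


def _observation(states: np.ndarray) -> np.ndarray:
    """h([px, py, vx, vy]) -> the six movement parameters; vectorized over
    sigma points (states is n_sigma x 4)."""
    px, py, vx, vy = states.T
    return np.column_stack([px, py, vx, vy, np.hypot(px, py), np.hypot(vx, vy)])


class UnscentedKalmanFilter:
    """Merwe scaled sigma-point filter for the constant-velocity state."""

    def __init__(self, Q: np.ndarray, R: np.ndarray, x0: np.ndarray,
                 P0: np.ndarray, cfg: UkfConfig | None = None,
                 obs_idx: np.ndarray | None = None):
        self.cfg = cfg or UkfConfig()
        dt = self.cfg.dt
        self.F = np.eye(4)
        self.F[0, 2] = self.F[1, 3] = dt
        self.Q = np.asarray(Q, dtype=float)
        self.R = np.asarray(R, dtype=float)
        self.x = np.asarray(x0, dtype=float).copy()
        self.P = np.asarray(P0, dtype=float).copy()
        self.obs_idx = (np.arange(self.R.shape[0]) if obs_idx is None
                        else np.asarray(obs_idx, dtype=int))
        n = 4
        lam = self.cfg.alpha ** 2 * (n + self.cfg.kappa) - n
        self._lam = lam
        self.Wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
        self.Wc = self.Wm.copy()
        self.Wm[0] = lam / (n + lam)
        self.Wc[0] = lam / (n + lam) + (1 - self.cfg.alpha ** 2 + self.cfg.beta)

    def _sigma_points(self) -> np.ndarray:
        n = 4
        try:
            L = np.linalg.cholesky((n + self._lam) * self.P)
        except np.linalg.LinAlgError:
            warnings.warn("state covariance lost positive definiteness; "
                          "regularizing with jitter")
            self.P = self.P + self.cfg.jitter * np.eye(n)
            L = np.linalg.cholesky((n + self._lam) * self.P)
        return np.vstack([self.x, self.x + L.T, self.x - L.T])

    def step(self, z: np.ndarray) -> np.ndarray:
        # predict (linear transition)
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        # update through sigma points
        sig = self._sigma_points()
        Z = _observation(sig)[:, self.obs_idx]
        z_mean = self.Wm @ Z
        dZ = Z - z_mean
        dX = sig - self.Wm @ sig
        S = (dZ.T * self.Wc) @ dZ + self.R[np.ix_(self.obs_idx, self.obs_idx)]
        C = (dX.T * self.Wc) @ dZ
        K = np.linalg.solve(S.T, C.T).T
        self.x = self.x + K @ (np.asarray(z)[self.obs_idx] - z_mean)
        self.P = self.P - K @ S @ K.T
        if np.linalg.norm(self.x) > self.cfg.divergence_bound:
            raise RuntimeError("UKF diverged (state norm exceeded bound)")
        return self.x


# ---------------------------------------------------------------------------
# the fused model
# ---------------------------------------------------------------------------


@dataclass
class PLSUKFModel:
    W: np.ndarray                  # (385, 6)
    intercept: np.ndarray          # (6,)
    n_components: int
    activation_patterns: np.ndarray  # (385, 6)
    Q: np.ndarray                  # (4, 4)
    R: np.ndarray                  # (6, 6)
    x0: np.ndarray                 # (4,)
    P0: np.ndarray                 # (4, 4)
    ukf: UkfConfig = field(default_factory=UkfConfig)
    training_stats: dict = field(default_factory=dict)


def fit_plsukf(trials_X: list[np.ndarray], trials_Y: list[np.ndarray],
               n_components: int = 10, ukf: UkfConfig | None = None,
               ) -> PLSUKFModel:
    """Fit PLS on concatenated trials, then derive the filter covariances.

    The measurement noise R is the training residual covariance of the PLS
    predictions; the process noise Q follows a white-acceleration model
    with the acceleration variance estimated from the training velocity
    increments.
    """
    ukf = ukf or UkfConfig()
    X = np.concatenate(trials_X, axis=1)
    Y = np.concatenate(trials_Y, axis=1)
    W, intercept = fit_pls(X, Y, n_components)
    resid = Y - pls_predict(W, intercept, X)
    R = np.cov(resid) + 1e-9 * np.eye(Y.shape[0])
    A = compute_activation_patterns(X, Y, W)

    dt = ukf.dt
    var_acc = []
    for Yt in trials_Y:
        acc = np.diff(Yt[2:4], axis=1) / dt
        var_acc.append(acc.var(axis=1))
    sa2 = np.mean(var_acc, axis=0)          # per-axis acceleration variance
    Q = np.zeros((4, 4))
    for axis, s2 in enumerate(sa2):
        p, v = axis, axis + 2
        Q[p, p] = 0.25 * dt ** 4 * s2
        Q[p, v] = Q[v, p] = 0.5 * dt ** 3 * s2
        Q[v, v] = dt ** 2 * s2
    P0 = np.diag(Y[:4].var(axis=1))
    return PLSUKFModel(W=W, intercept=intercept, n_components=n_components,
                       activation_patterns=A, Q=Q, R=R,
                       x0=np.zeros(4), P0=P0, ukf=ukf,
                       training_stats={"n_samples": X.shape[1],
                                       "n_trials": len(trials_X)})


def ukf_decode(model: PLSUKFModel, X: np.ndarray,
               obs_idx: np.ndarray | None = None) -> np.ndarray:
    """Decode a lag-feature matrix to the state trajectory (4 x T).

    Per time step the PLS models supply the six measurements which the UKF
    fuses into [px, py, vx, vy]; strictly causal.
    """
    Z = pls_predict(model.W, model.intercept, X)
    ukf = UnscentedKalmanFilter(model.Q, model.R, model.x0, model.P0,
                                model.ukf, obs_idx=obs_idx)
    out = np.empty((4, Z.shape[1]))
    for k in range(Z.shape[1]):
        out[:, k] = ukf.step(Z[:, k])
    return out


def decoded_kinematics(states: np.ndarray) -> np.ndarray:
    """Expand a 4 x T state trajectory with distance and speed rows."""
    return np.vstack([states, np.hypot(states[0], states[1]),
                      np.hypot(states[2], states[3])])


# ---------------------------------------------------------------------------
# trial rejection
# ---------------------------------------------------------------------------


def reject_trials(tracking_epochs: list[np.ndarray], amplitude_uv: float = 100.0,
                  z_bound: float = 4.0) -> tuple[list[int], list[int], dict[int, str]]:
    """Flag tracking trials with abnormal amplitude, variance or kurtosis.

    A trial is flagged when any sample exceeds ±``amplitude_uv``, or when
    its log-variance or kurtosis lies more than ``z_bound`` SDs above the
    across-trial mean. Returns (kept, flagged, reasons); in batch use the
    flags are auto-confirmed.
    """
    n = len(tracking_epochs)
    logvar = np.array([np.log(np.maximum(ep.var(axis=1), 1e-30)).mean()
                       for ep in tracking_epochs])
    with warnings.catch_warnings():
        # constant epochs trip a precision warning inside the moment
        # calculation; their kurtosis value is irrelevant to the outlier rule
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = np.array([np.mean(stats.kurtosis(ep, axis=1))
                         for ep in tracking_epochs])
    reasons: dict[int, str] = {}
    for i, ep in enumerate(tracking_epochs):
        if np.abs(ep).max() > amplitude_uv:
            reasons[i] = "amplitude"
    for name, vals in (("variance", logvar), ("kurtosis", kurt)):
        mu, sd = vals.mean(), vals.std()
        if sd > 0:
            for i in np.flatnonzero(vals > mu + z_bound * sd):
                reasons.setdefault(int(i), name)
    flagged = sorted(reasons)
    kept = [i for i in range(n) if i not in reasons]
    return kept, flagged, reasons


# ---------------------------------------------------------------------------
# evaluation and chance levels
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryMetrics:
    r: dict[str, float]            # per parameter
    r_axis: dict[str, float]       # x / y: mean of position and velocity r
    aratio: dict[str, float]       # sigma(decoded) / sigma(target)
    rms: dict[str, float]

    def to_frame(self):
        """One row per movement parameter (r, Aratio, rms) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {"parameter": list(PARAM_NAMES),
             "r": [self.r[p] for p in PARAM_NAMES],
             "aratio": [self.aratio[p] for p in PARAM_NAMES],
             "rms": [self.rms[p] for p in PARAM_NAMES]})


def evaluate_trajectories(decoded: np.ndarray, target: np.ndarray,
                          ) -> TrajectoryMetrics:
    """Pearson r, amplitude ratio and RMS error per movement parameter.

    ``decoded`` may be the 4-row state or the expanded 6-row kinematics;
    ``target`` is the 6-row reference. Per-axis r is the mean of the
    position and velocity correlations of that axis.
    """
    dec = np.asarray(decoded, dtype=float)
    if dec.shape[0] == 4:
        dec = decoded_kinematics(dec)
    tar = np.asarray(target, dtype=float)
    if dec.shape != tar.shape:
        raise ValueError("decoded and target must align")
    r, aratio, rms = {}, {}, {}
    for i, name in enumerate(PARAM_NAMES):
        sd_d, sd_t = dec[i].std(), tar[i].std()
        if sd_d == 0 or sd_t == 0:
            raise ValueError(f"zero-variance signal for {name}: r undefined")
        r[name] = float(np.corrcoef(dec[i], tar[i])[0, 1])
        aratio[name] = float(sd_d / sd_t)
        rms[name] = float(np.sqrt(np.mean((dec[i] - tar[i]) ** 2)))
    r_axis = {"x": 0.5 * (r["px"] + r["vx"]), "y": 0.5 * (r["py"] + r["vy"])}
    return TrajectoryMetrics(r=r, r_axis=r_axis, aratio=aratio, rms=rms)


def _split_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    return [np.sort(p) for p in np.array_split(rng.permutation(n), n_folds)]


def evaluate_plsukf(trials_X: list[np.ndarray], trials_Y: list[np.ndarray],
                    n_components: int = 10, scheme: str = "loto",
                    n_folds: int = 5, seed: int = 0) -> TrajectoryMetrics:
    """Held-out decoding performance over concatenated test predictions.

    ``scheme='loto'`` leaves one trial out per fit (the calibration-phase
    convention); ``scheme='kfold'`` splits trials into ``n_folds`` groups,
    trading a little optimism for a large fit-count reduction.
    """
    n = len(trials_X)
    if scheme == "loto":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold":
        folds = _split_folds(n, min(n_folds, n), np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    dec_parts, tar_parts = [], []
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        model = fit_plsukf([trials_X[i] for i in train],
                           [trials_Y[i] for i in train], n_components)
        for i in test:
            dec_parts.append(decoded_kinematics(ukf_decode(model, trials_X[i])))
            tar_parts.append(trials_Y[i])
    return evaluate_trajectories(np.concatenate(dec_parts, axis=1),
                                 np.concatenate(tar_parts, axis=1))


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    if n < 2:
        raise ValueError("need at least 2 trials")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def trajectory_chance(trials_X: list[np.ndarray], trials_Y: list[np.ndarray],
                      n_shuffles: int = 100, percentile: float = 97.5,
                      n_components: int = 10, seed: int = 0,
                      test_fraction: float = 0.2,
                      ) -> dict[str, dict[str, float] | np.ndarray]:
    """Chance bounds by breaking the trial-trajectory correspondence.

    Per shuffle the trajectory assignment is deranged (no trial keeps its
    own snake), a fresh PLS+UKF model is fitted on the training portion and
    scored on held-out trials; the requested upper percentile of each metric
    distribution across shuffles gives r_chance, rms_chance and
    Aratio_chance.
    """
    n = len(trials_X)
    rng = np.random.default_rng(seed)
    r_axis_vals = {"x": [], "y": []}
    r_vals = {p: [] for p in PARAM_NAMES}
    rms_vals = {p: [] for p in PARAM_NAMES}
    aratio_vals = {p: [] for p in PARAM_NAMES}
    n_test = max(int(round(test_fraction * n)), 1)
    for _ in range(n_shuffles):
        perm = _derangement(n, rng)
        order = rng.permutation(n)
        test, train = order[:n_test], order[n_test:]
        model = fit_plsukf([trials_X[i] for i in train],
                           [trials_Y[perm[i]] for i in train], n_components)
        dec = np.concatenate(
            [decoded_kinematics(ukf_decode(model, trials_X[i])) for i in test], axis=1)
        tar = np.concatenate([trials_Y[perm[i]] for i in test], axis=1)
        m = evaluate_trajectories(dec, tar)
        for k in ("x", "y"):
            r_axis_vals[k].append(abs(m.r_axis[k]))
        for p in PARAM_NAMES:
            r_vals[p].append(abs(m.r[p]))
            rms_vals[p].append(m.rms[p])
            aratio_vals[p].append(m.aratio[p])
    pct = lambda d: {k: float(np.percentile(v, percentile)) for k, v in d.items()}
    return {"r_chance_axis": pct(r_axis_vals), "r_chance": pct(r_vals),
            "rms_chance": pct(rms_vals), "aratio_chance": pct(aratio_vals),
            "n_shuffles": n_shuffles}
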