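"""Synthetic study generator with known ground truth.

Emulates the data structure of a repeated-measures ECT study: per-session
postictal EEG whose alpha/delta balance recovers sigmoidally from near -1,
ictal spike-wave segments terminating in suppression, and reorientation
times generated from a linear mixed model on (true) EEG features and
clinical covariates, observed on a 5-minute question grid.

Signal model
------------
Each channel is the sum of two independent band-limited noise processes
(delta 0.5-4 Hz, alpha 8-13 Hz; FFT brick-wall filtered, unit variance)
with time-varying gains g_d(t), g_a(t) chosen so that the instantaneous
band-power balance equals the programmed recovery curve f(t):

    g_a(t)^2 = P (1 + f(t)) / 2,   g_d(t)^2 = P (1 - f(t)) / 2,

with P the total band power (µV²). Then (Pa - Pd)/(Pa + Pd) = f(t) exactly
in expectation. Channels share the gain laws with independent noise, so the
channel-median PSD equals the single-channel expectation.

All defaults mirror the study conditions: 32 subjects, ~8.5 sessions each
(272 sessions), seizure duration 58.5 ± 29.9 s, charge 349.3 ± 162.4 mC,
midazolam in 37% of sessions, bilateral placement in ~66%, age 54.2 ± 13.9 y,
56% female, recovery-curve parameters centred on the reported group values
(A = 0.33 ± 0.27, lag = 6.3 ± 3.1 min, T_max = 29.4 ± 8.6 min).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecording, SeizureMarkers
from .recovery import sigmoid_eval

__all__ = [
    "SimConfig",
    "GroundTruth",
    "StudyData",
    "COVARIATES",
    "CONTINUOUS_COVARIATES",
    "BETA_TRUTH",
    "INTERCEPT_TRUTH",
    "DOMAIN_QUESTIONS",
    "simulate_postictal_eeg",
    "simulate_ictal_segment",
    "simulate_rot",
    "simulate_study",
    "write_study",
]

#: fixed-effect design order used by both the generator and the mixed models
COVARIATES = [
    "t_max", "amplitude", "tau", "charge", "seizure_duration",
    "midazolam", "placement", "session_number", "sex", "age",
]
CONTINUOUS_COVARIATES = [
    "t_max", "amplitude", "tau", "charge", "seizure_duration",
    "session_number", "age",
]

#: per-domain fixed-effect truths (minutes per standardized unit for
#: continuous predictors, minutes per level for binary ones); effects the
#: study reported as non-significant without a printed estimate are 0.
BETA_TRUTH: dict[str, dict[str, float]] = {
    "person": {"t_max": 1.5, "amplitude": -1.2, "tau": 0.7,
               "seizure_duration": 2.5, "midazolam": 4.4},
    "place": {"t_max": 3.3, "amplitude": -1.2, "tau": -0.7, "charge": 2.6,
              "seizure_duration": 3.1, "midazolam": 8.3, "placement": 5.2},
    "time": {"t_max": 2.4, "amplitude": -2.8, "tau": -0.3,
             "seizure_duration": 3.3, "midazolam": 5.6, "age": 4.0},
}
INTERCEPT_TRUTH = {"person": 24.0, "place": 28.6, "time": 33.0}

DOMAIN_QUESTIONS = {
    "person": ("name", "birthday"),
    "place": ("hospital",),
    "time": ("age", "weekday"),
}

MONTAGE_12 = ["Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
              "O1", "O2", "T3", "T4"]


@dataclass
class SimConfig:
    """Study-level simulation configuration (defaults = study conditions)."""

    n_subjects: int = 32
    sessions_per_subject: float = 8.5
    fs: float = 128.0
    postictal_duration: float = 60.0  # minutes
    n_channels: int = 12
    seizure_duration_dist: tuple[float, float] = (58.5, 29.9)  # s
    charge_dist: tuple[float, float] = (349.3, 162.4)  # mC
    age_dist: tuple[float, float] = (54.2, 13.9)  # years
    # recovery-curve truths: (mean, sd) for A, lag, tau, lower asymptote
    amplitude_dist: tuple[float, float] = (0.33, 0.27)
    lag_dist: tuple[float, float] = (6.3, 3.1)
    # tau's dispersion is a free choice (group tau stats are not reported);
    # 4.0 keeps corr(T_max, tau) ~ 0.79 so the design satisfies the VIF < 5
    # screen the analysis asserts (see docs/methods.md)
    tau_dist: tuple[float, float] = (23.1, 4.0)  # T_max mean 29.4 = lag + tau
    lower_asymptote_dist: tuple[float, float] = (-0.95, 0.04)
    beta_truth: dict = field(default_factory=lambda: {
        d: dict(v) for d, v in BETA_TRUTH.items()})
    intercept_truth: dict = field(
        default_factory=lambda: dict(INTERCEPT_TRUTH))
    random_effect_sds: tuple[float, float] = (5.0, 2.0)  # intercept, t_max slope
    resid_sd: float = 8.0  # minutes, session-domain residual
    question_sd: float = 2.0  # minutes, per-question scatter within a domain
    question_interval: float = 5.0  # minutes
    first_assessment: float = 5.0  # minutes after seizure offset
    # reorientation is assessed until the patient reorients, beyond the 1-h
    # EEG window; questions still unanswered at rot_window are censored
    rot_window: float = 120.0  # minutes
    baseline_disoriented_prob: float = 0.02
    midazolam_prob: float = 0.37
    placement_prob_BL: float = 0.658
    sex_male_prob: float = 0.44
    total_band_power: float = 900.0  # µV², delta + alpha
    artifact_rate_per_min: float = 2.0
    artifact_amp: float = 500.0  # µV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 128:
            raise ValueError(f"fs must be >= 128 Hz, got {self.fs}")
        if self.postictal_duration < 40:
            raise ValueError("postictal_duration must be >= 40 min")
        if self.question_interval <= 0:
            raise ValueError("question_interval must be positive")
        for name, sd in [("resid_sd", self.resid_sd),
                         ("question_sd", self.question_sd),
                         *zip(("intercept_sd", "slope_sd"),
                              self.random_effect_sds)]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0, got {sd}")

    def sessions_for_subject(self, i: int) -> int:
        """Deterministic per-subject session count whose mean is
        ``sessions_per_subject`` (first subjects get the extra sessions)."""
        base = int(np.floor(self.sessions_per_subject))
        n_extra = round((self.sessions_per_subject - base) * self.n_subjects)
        return base + (1 if i < n_extra else 0)


@dataclass
class GroundTruth:
    """Truth bookkeeping for recovery tests."""

    sessions: pd.DataFrame  # per-session true A, lam, tau, U, t_max
    rot_latent: pd.DataFrame  # per session x domain noise-free latent ROT
    subject_effects: pd.DataFrame  # random intercept and t_max slope
    beta: dict
    intercept: dict


@dataclass
class StudyData:
    """One simulated study, ready for the analysis pipeline."""

    sessions: pd.DataFrame  # covariates + EEG features (true or fitted)
    rot_log: pd.DataFrame  # question-level reorientation log
    truth: GroundTruth
    config: SimConfig
    fits: pd.DataFrame | None = None  # full path only: per-session fit table


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Normal draws re-drawn into [lo, hi] (resampling, not clipping)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    # bounded number of redraw rounds; clip any stragglers
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def _band_noise(rng, n, fs, lo, hi):
    """Unit-variance band-limited Gaussian noise via FFT brick wall."""
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1 / fs)
    X[(f < lo) | (f > hi)] = 0
    y = np.fft.irfft(X, n)
    return y / y.std()


def simulate_postictal_eeg(
    truth,
    duration: float = 60.0,
    fs: float = 128.0,
    n_channels: int = 12,
    rng=None,
    total_power: float = 900.0,
    artifact_rate_per_min: float = 0.0,
    artifact_amp: float = 500.0,
) -> EEGRecording:
    """Synthesize a postictal EEG whose windowed ADR tracks the programmed
    recovery curve.

    Parameters
    ----------
    truth : tuple (A, lam, tau, U) or mapping with those keys
        Recovery-curve truth; time origin of the recording is seizure offset.
    duration : float
        Postictal duration in minutes (>= 40).
    artifact_rate_per_min : float
        Expected count of injected 1-s high-amplitude transients per minute,
        each on one random channel; injected artifacts are listed in the
        recording's ``artifact_times`` metadata.
    """
    if duration < 40:
        raise ValueError(f"duration must be >= 40 min, got {duration}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(truth, dict):
        A, lam, tau, U = (truth[k] for k in ("A", "lam", "tau", "U"))
    else:
        A, lam, tau, U = truth

    n = int(round(duration * 60 * fs))
    t_min = np.arange(n) / fs / 60.0
    f_t = sigmoid_eval(t_min, A, lam, tau, U)
    f_t = np.clip(f_t, -1.0, 1.0)
    g_alpha = np.sqrt(total_power * (1 + f_t) / 2)
    g_delta = np.sqrt(total_power * (1 - f_t) / 2)

    # generator bands are inset from the nominal analysis bands by the Hann
    # main-lobe half-width of a 5-s window (0.4 Hz) so that the programmed
    # band power falls entirely inside the analysis band integral
    delta_band = (0.5 + 0.4, 4.0 - 0.4)
    alpha_band = (8.0 + 0.4, 13.0 - 0.4)

    if n_channels <= len(MONTAGE_12):
        labels = MONTAGE_12[:n_channels]
    else:
        labels = MONTAGE_12 + [f"EEG{i}" for i in range(len(MONTAGE_12),
                                                        n_channels)]
    samples = np.empty((n_channels, n))
    for c in range(n_channels):
        delta = _band_noise(rng, n, fs, *delta_band)
        alpha = _band_noise(rng, n, fs, *alpha_band)
        samples[c] = g_delta * delta + g_alpha * alpha

    artifact_times: list[tuple[float, int]] = []
    n_art = rng.poisson(artifact_rate_per_min * duration)
    for _ in range(n_art):
        t_a = rng.uniform(0, duration * 60 - 1.0)
        ch = int(rng.integers(n_channels))
        a = int(t_a * fs)
        b = min(a + int(fs), n)
        samples[ch, a:b] += artifact_amp * np.sign(
            rng.standard_normal(b - a))
        artifact_times.append((t_a, ch))

    return EEGRecording(
        samples=samples, fs=fs, channel_labels=labels,
        markers=SeizureMarkers(onset_s=0.0, offset_s=0.0),
        artifact_times=artifact_times,
    )


def simulate_ictal_segment(
    seizure_duration: float,
    fs: float = 128.0,
    rng=None,
    suppression_s: float = 5.0,
    n_channels: int = 12,
) -> EEGRecording:
    """Spike-wave-like rhythmic segment followed by a suppressed tail.

    The ictal part is a 3 Hz spike-wave surrogate (harmonic stack, ~150 µV)
    lasting ``seizure_duration`` seconds; the tail is < 10 µV noise lasting
    ``suppression_s`` (>= 2) seconds. Markers carry the programmed
    onset (0) and offset (= seizure_duration).
    """
    if seizure_duration <= 0:
        raise ValueError("seizure_duration must be positive")
    if suppression_s < 2:
        raise ValueError("suppression tail must be >= 2 s")
    if rng is None:
        rng = np.random.default_rng()
    n_ict = int(round(seizure_duration * fs))
    n_sup = int(round(suppression_s * fs))
    t = np.arange(n_ict) / fs
    spike_wave = (120 * np.sin(2 * np.pi * 3 * t)
                  + 60 * np.sin(2 * np.pi * 6 * t)
                  + 30 * np.sin(2 * np.pi * 9 * t))
    labels = MONTAGE_12[:n_channels] if n_channels <= 12 else [
        f"ch{i}" for i in range(n_channels)]
    samples = np.empty((n_channels, n_ict + n_sup))
    for c in range(n_channels):
        samples[c, :n_ict] = spike_wave + 10 * rng.standard_normal(n_ict)
        samples[c, n_ict:] = 2.0 * rng.standard_normal(n_sup)
    return EEGRecording(
        samples=samples, fs=fs, channel_labels=labels,
        markers=SeizureMarkers(onset_s=0.0, offset_s=seizure_duration),
    )


def _grid_ceil(latent: np.ndarray, first: float, interval: float) -> np.ndarray:
    """Smallest question-grid time >= latent; grid = first + k*interval,
    latent times floored at the first assessment."""
    shifted = np.maximum(latent - first, 0.0)
    return first + interval * np.ceil(shifted / interval - 1e-9)


def simulate_rot(
    features: pd.DataFrame,
    config: SimConfig,
    rng,
    subject_effects: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate question-level reorientation times from the mixed model.

    ``features`` needs one row per session with ``session_id``,
    ``subject_id`` and all :data:`COVARIATES`. Latent domain ROT =
    intercept + beta . z(covariates) + subject intercept + subject slope *
    z(t_max) + Gaussian residual; each question adds independent
    N(0, question_sd) scatter, is floored at the first assessment and
    observed as the smallest question-grid time >= its latent time.
    Questions still unanswered at the end of the observation window are
    censored (missing). Baseline disorientation invalidates the domain.

    Returns (rot_log, latent_truth, subject_effects).
    """
    if config.resid_sd < 0:
        raise ValueError("resid_sd must be >= 0")
    df = features.reset_index(drop=True)
    z = df[COVARIATES].astype(float).copy()
    for c in CONTINUOUS_COVARIATES:
        sd = z[c].std(ddof=1)
        z[c] = (z[c] - z[c].mean()) / (sd if sd > 0 else 1.0)

    subjects = df["subject_id"].unique()
    if subject_effects is None:
        b0_sd, b1_sd = config.random_effect_sds
        subject_effects = pd.DataFrame({
            "subject_id": subjects,
            "b0": rng.normal(0, b0_sd, len(subjects)) if b0_sd > 0
            else np.zeros(len(subjects)),
            "b1": rng.normal(0, b1_sd, len(subjects)) if b1_sd > 0
            else np.zeros(len(subjects)),
        })
    eff = subject_effects.set_index("subject_id")
    b0 = eff.loc[df["subject_id"], "b0"].to_numpy()
    b1 = eff.loc[df["subject_id"], "b1"].to_numpy()

    log_rows, latent_rows = [], []
    window_end = config.rot_window
    for domain, questions in DOMAIN_QUESTIONS.items():
        beta = config.beta_truth.get(domain, {})
        lin = np.full(len(df), float(config.intercept_truth[domain]))
        for cov, b in beta.items():
            lin = lin + b * z[cov].to_numpy()
        eps = (rng.normal(0, config.resid_sd, len(df))
               if config.resid_sd > 0 else np.zeros(len(df)))
        latent = lin + b0 + b1 * z["t_max"].to_numpy() + eps
        oriented = rng.random(len(df)) >= config.baseline_disoriented_prob
        for i, row in enumerate(df.itertuples()):
            latent_rows.append({
                "session_id": row.session_id, "domain": domain,
                "latent_rot": latent[i], "baseline_oriented": bool(oriented[i]),
            })
            for q in questions:
                lq = latent[i] + (rng.normal(0, config.question_sd)
                                  if config.question_sd > 0 else 0.0)
                obs = float(_grid_ceil(np.array([lq]), config.first_assessment,
                                       config.question_interval)[0])
                log_rows.append({
                    "session_id": row.session_id,
                    "question_id": q,
                    "domain": domain,
                    "minutes_to_correct": obs if obs <= window_end else np.nan,
                    "baseline_oriented": bool(oriented[i]),
                })
    rot_log = pd.DataFrame(log_rows)
    latent_truth = pd.DataFrame(latent_rows)
    return rot_log, latent_truth, subject_effects.reset_index(drop=True)


def _simulate_sessions(config: SimConfig, rng) -> pd.DataFrame:
    """Covariates and true recovery-curve parameters, one row per session."""
    rows = []
    for i in range(config.n_subjects):
        subj = f"S{i + 1:02d}"
        age = float(_truncnorm(rng, *config.age_dist, 18, 95, 1)[0])
        sex = int(rng.random() < config.sex_male_prob)
        n_sess = config.sessions_for_subject(i)
        for k in range(n_sess):
            lam = float(_truncnorm(rng, *config.lag_dist, 0.5, 20, 1)[0])
            tau = float(_truncnorm(rng, *config.tau_dist, 2, 50, 1)[0])
            A = float(_truncnorm(rng, *config.amplitude_dist, 0.05, 1.5, 1)[0])
            low = float(_truncnorm(
                rng, *config.lower_asymptote_dist, -1.0, -0.8, 1)[0])
            U = min(low + A, 1.0)
            rows.append({
                "session_id": f"{subj}_E{k + 1:02d}",
                "subject_id": subj,
                "session_number": k + 1,
                "age": age,
                "sex": sex,
                "charge": float(_truncnorm(rng, *config.charge_dist,
                                           25, 1200, 1)[0]),
                "seizure_duration": float(_truncnorm(
                    rng, *config.seizure_duration_dist, 10, 240, 1)[0]),
                "midazolam": int(rng.random() < config.midazolam_prob),
                "placement": int(rng.random() < config.placement_prob_BL),
                "true_A": A, "true_lam": lam, "true_tau": tau, "true_U": U,
                "true_t_max": lam + tau,
            })
    return pd.DataFrame(rows)


def simulate_study(
    config: SimConfig | None = None,
    mode: str = "features",
    feature_noise_sd: float = 0.0,
) -> StudyData:
    """Simulate a full study, reproducibly from ``config.seed``.

    ``mode="features"`` (fast path) uses the true recovery-curve parameters
    as the session's EEG features, optionally perturbed by independent
    Gaussian noise of SD ``feature_noise_sd`` (in each feature's units).
    ``mode="full"`` synthesizes raw postictal EEG per session and runs it
    through the entire pipeline (filter -> epochs -> artifact screen ->
    Welch/ADR -> sigmoid fit); QC-failed sessions are dropped, as in the
    analysis contract.
    """
    if config is None:
        config = SimConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_clin, rng_eeg = (np.random.default_rng(s) for s in ss.spawn(2))

    sessions = _simulate_sessions(config, rng_clin)
    true_feats = sessions.rename(columns={
        "true_t_max": "t_max", "true_A": "amplitude", "true_tau": "tau"})
    feat_cols = ["session_id", "subject_id"] + COVARIATES

    # clinical outcomes are driven by the true physiology
    rot_log, latent_truth, subject_effects = simulate_rot(
        true_feats[feat_cols], config, rng_clin)

    fits_df = None
    if mode == "features":
        feats = true_feats[feat_cols].copy()
        if feature_noise_sd > 0:
            for c in ("t_max", "amplitude", "tau"):
                feats[c] += rng_clin.normal(0, feature_noise_sd, len(feats))
    elif mode == "full":
        from .pipeline import process_postictal_recording

        fit_rows = []
        child_seeds = ss.spawn(len(sessions))
        for row, child in zip(sessions.itertuples(), child_seeds):
            rec = simulate_postictal_eeg(
                (row.true_A, row.true_lam, row.true_tau, row.true_U),
                duration=config.postictal_duration,
                fs=config.fs,
                n_channels=config.n_channels,
                rng=np.random.default_rng(child),
                total_power=config.total_band_power,
                artifact_rate_per_min=config.artifact_rate_per_min,
                artifact_amp=config.artifact_amp,
            )
            _, fit = process_postictal_recording(
                rec, duration_min=int(config.postictal_duration))
            fit_rows.append({
                "session_id": row.session_id, "A": fit.A, "lam": fit.lam,
                "tau": fit.tau, "U": fit.U, "r2": fit.r_squared,
                "t_max": fit.t_max, "converged": fit.converged,
                "qc_pass": fit.qc_pass,
            })
        fits_df = pd.DataFrame(fit_rows)
        fitted = fits_df[fits_df["qc_pass"]].rename(columns={
            "t_max": "t_max", "A": "amplitude", "tau": "tau"})
        feats = true_feats[feat_cols].drop(
            columns=["t_max", "amplitude", "tau"]).merge(
            fitted[["session_id", "t_max", "amplitude", "tau"]],
            on="session_id", how="inner")
        feats = feats[feat_cols]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    truth = GroundTruth(
        sessions=sessions[["session_id", "subject_id", "true_A", "true_lam",
                           "true_tau", "true_U", "true_t_max"]].copy(),
        rot_latent=latent_truth,
        subject_effects=subject_effects,
        beta={d: dict(v) for d, v in config.beta_truth.items()},
        intercept=dict(config.intercept_truth),
    )
    return StudyData(sessions=feats, rot_log=rot_log, truth=truth,
                     config=config, fits=fits_df)


def write_study(study: StudyData, outdir, write_edf_files: bool = False) -> None:
    """Write a simulated study to disk: ``sessions.csv``, ``rot_log.csv``,
    ``truth.json`` and (optionally) one EDF per session plus ``markers.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.sessions.to_csv(outdir / "sessions.csv", index=False)
    study.rot_log.to_csv(outdir / "rot_log.csv", index=False)
    truth = {
        "sessions": study.truth.sessions.to_dict(orient="records"),
        "rot_latent": study.truth.rot_latent.to_dict(orient="records"),
        "subject_effects": study.truth.subject_effects.to_dict(orient="records"),
        "beta": study.truth.beta,
        "intercept": study.truth.intercept,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(study.config).items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    if write_edf_files:
        from .edf import write_edf

        cfg = study.config
        ss = np.random.SeedSequence(cfg.seed + 1)
        markers = []
        for row, child in zip(study.truth.sessions.itertuples(),
                              ss.spawn(len(study.truth.sessions))):
            rec = simulate_postictal_eeg(
                (row.true_A, row.true_lam, row.true_tau, row.true_U),
                duration=cfg.postictal_duration, fs=cfg.fs,
                n_channels=cfg.n_channels,
                rng=np.random.default_rng(child),
                total_power=cfg.total_band_power,
                artifact_rate_per_min=cfg.artifact_rate_per_min,
                artifact_amp=cfg.artifact_amp,
            )
            write_edf(outdir / f"{row.session_id}.edf", rec)
            markers.append({"session_id": row.session_id,
                            "seizure_onset_s": 0.0, "seizure_offset_s": 0.0})
        pd.DataFrame(markers).to_csv(outdir / "markers.csv", index=False)
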