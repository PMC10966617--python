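"""End-to-end orchestration: EEG signal path, clinical scoring, and the
per-domain mixed models, with per-session error bookkeeping.

Failures in one session (all-artifact EEG, too-short series, failed fit) are
recorded in an exclusion table and never abort the run, mirroring the
first-class exclusion bookkeeping a clinical-EEG pipeline needs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import EEGRecording, bandpass_filter, flag_artifacts, segment_epochs
from .recovery import InsufficientDataError, SigmoidFit, fit_sigmoid
from .reorientation import score_rot_log
from .association import build_session_table, fit_domain_lmm, midazolam_sensitivity
from .simulate import SimConfig, StudyData, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "process_postictal_recording",
    "analyze_study",
    "run_simulated_study",
    "write_results",
    "plot_fit",
]


def process_postictal_recording(
    rec: EEGRecording,
    duration_min: int | None = None,
    low: float = 0.5,
    high: float = 30.0,
    epoch_length: float = 5.0,
    amp_thresh: float = 200.0,
    flat_thresh: float = 0.1,
    window: float = 5.0,
    overlap: float = 0.5,
    adr_mode: str = "per_window",
) -> tuple[pd.DataFrame, SigmoidFit]:
    """Signal path for one postictal recording (time origin = seizure offset):
    band-pass filter -> 5-s epochs -> artifact screen -> windowed Welch PSD ->
    channel-median -> band powers -> ADR per minute -> sigmoid fit.

    Returns (adr_series, fit).
    """
    from .spectral import compute_adr_series

    filtered = bandpass_filter(rec, low=low, high=high)
    epochs = segment_epochs(filtered, t0=0.0, epoch_length=epoch_length)
    epochs = flag_artifacts(filtered, epochs, amp_thresh=amp_thresh,
                            flat_thresh=flat_thresh)
    series = compute_adr_series(filtered, epochs, window=window,
                                overlap=overlap, duration_min=duration_min,
                                mode=adr_mode)
    fit = fit_sigmoid(series)
    return series, fit


def analyze_study(study: StudyData) -> dict:
    """Clinical-side analysis of a (simulated or assembled) study: scores the
    question log, joins the session table, and fits the three domain models
    plus the midazolam-free sensitivity refits."""
    rot = score_rot_log(study.rot_log)
    table = build_session_table(study.sessions, rots=rot)
    errors = []
    lmm = {}
    for domain in ("person", "place", "time"):
        try:
            lmm[domain] = fit_domain_lmm(table, domain)
        except Exception as exc:  # surfaced, never silent
            errors.append({"session_id": "*", "stage": f"lmm_{domain}",
                           "status": "failed", "reason": str(exc)})
    sensitivity = midazolam_sensitivity(table)
    return {"rot": rot, "table": table, "lmm": lmm,
            "sensitivity": sensitivity, "errors": pd.DataFrame(errors)}


def run_simulated_study(config: SimConfig, mode: str = "features") -> dict:
    """Simulate a study and run the full analysis on it."""
    study = simulate_study(config, mode=mode)
    out = analyze_study(study)
    out["study"] = study
    return out


def _lmm_to_json(result) -> dict:
    return {
        "domain": result.domain,
        "coefficients": {
            name: {"beta": row["beta"], "se": row["se"],
                   "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                   "p": row["p"]}
            for name, row in result.coef.iterrows()
        },
        "random_sds": result.random_sds,
        "method": result.method,
        "n_obs": result.n_obs,
        "n_subjects": result.n_subjects,
        "vif": result.vif.to_dict(),
        "converged": result.converged,
        "singular": result.singular,
        "fallback": result.fallback,
        "diagnostics": result.diagnostics,
    }


def write_results(results: dict, outdir, config: SimConfig | None = None,
                  seed: int | None = None) -> None:
    """Write rot.csv, lmm_<domain>.json, results_summary.csv and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["rot"].to_csv(outdir / "rot.csv", index=False)
    results["table"].to_csv(outdir / "session_table.csv", index=False)
    summary_rows = []
    for domain, res in results["lmm"].items():
        (outdir / f"lmm_{domain}.json").write_text(
            json.dumps(_lmm_to_json(res), indent=1))
        for name, row in res.coef.iterrows():
            summary_rows.append({
                "domain": domain, "effect": name, "beta": row["beta"],
                "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                "p": row["p"],
            })
    pd.DataFrame(summary_rows).to_csv(outdir / "results_summary.csv",
                                      index=False)
    if len(results.get("errors", [])):
        results["errors"].to_csv(outdir / "errors.csv", index=False)

    manifest = {"package_version": __version__, "seed": seed}
    if config is not None:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in dataclasses.asdict(config).items()}
        manifest["config"] = cfg
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    import numpy, scipy, statsmodels  # noqa: PLC0415

    manifest["versions"] = {"numpy": numpy.__version__,
                            "scipy": scipy.__version__,
                            "statsmodels": statsmodels.__version__}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def plot_fit(series: pd.DataFrame, fit: SigmoidFit, path) -> None:
    """Two-panel fit figure: ADR per minute with the fitted curve, and the
    fitted derivative with T_max marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .recovery import sigmoid_deriv, sigmoid_eval

    t = np.linspace(0, series["minute"].max(), 500)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.plot(series["minute"], series["adr"], "o", ms=4, label="ADR / min")
    ax1.plot(t, sigmoid_eval(t, fit.A, fit.lam, fit.tau, fit.U), "r-",
             label=f"sigmoid fit (R²={fit.r_squared:.2f})")
    ax1.set_ylabel("normalized alpha–delta ratio")
    ax1.legend()
    ax2.plot(t, sigmoid_deriv(t, fit.A, fit.lam, fit.tau, fit.U), "g-")
    ax2.axvline(fit.t_max, ls="--", c="k",
                label=f"T_max = {fit.t_max:.1f} min")
    ax2.set_xlabel("minutes since seizure offset")
    ax2.set_ylabel("df/dt (ADR/min)")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
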