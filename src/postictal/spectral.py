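"""Normalized alpha-delta ratio (ADR) from preprocessed EEG.

ADR = (Pa - Pd) / (Pa + Pd), with Pa the power in the alpha band (8-13 Hz)
and Pd the power in the delta band (0.5-4 Hz), both integrated from a Welch
power spectral density. ADR ranges from -1 (pure delta, deep postictal
slowing) to +1 (pure alpha, restored awake rhythm).

Pipeline order, per window: channel-median PSD -> band powers -> ADR; window
ADRs are then averaged per minute. Windows are the Welch segments themselves:
5-s Hann-tapered periodograms advancing by 50% overlap. An alternative
"power-first" mode (average band powers per minute, then one ADR) is exposed
via ``minute_series(..., mode="power_first")``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EEGRecording, EpochSet

logger = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 13.0)
DELTA_BAND = (0.5, 4.0)

__all__ = [
    "ALPHA_BAND",
    "DELTA_BAND",
    "WindowPSD",
    "window_psd",
    "median_over_channels",
    "band_power",
    "adr",
    "minute_series",
    "compute_adr_series",
]


@dataclass
class WindowPSD:
    """Per-window, per-channel power spectral densities.

    ``psd[w, c]`` is the density (µV²/Hz) for window w on channel c; NaN
    where the channel was excluded (artifact-flagged epoch overlap or
    wholesale rejection). ``starts`` are window start times in seconds on the
    recording's time axis.
    """

    freqs: np.ndarray  # (n_freqs,)
    psd: np.ndarray  # (n_windows, n_channels, n_freqs)
    starts: np.ndarray  # (n_windows,) seconds
    window: float

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def window_psd(
    rec: EEGRecording,
    epochs: EpochSet,
    window: float = 5.0,
    overlap: float = 0.5,
    t0: float = 0.0,
) -> WindowPSD:
    """Hann-tapered periodogram per overlapping window (Welch segments).

    Windows of ``window`` seconds advance by ``window * (1 - overlap)``
    starting at ``t0``. A window is excluded for a channel when it overlaps
    any artifact-flagged epoch on that channel, or when the channel is
    rejected wholesale.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    advance = window * (1 - overlap)
    nper = int(round(window * rec.fs))
    n_win = int(np.floor((rec.duration - t0 - window) / advance)) + 1
    if n_win <= 0:
        warnings.warn("no complete PSD window in recording", stacklevel=2)
        return WindowPSD(
            freqs=np.fft.rfftfreq(nper, 1 / rec.fs),
            psd=np.empty((0, rec.n_channels, nper // 2 + 1)),
            starts=np.empty(0),
            window=window,
        )
    starts = t0 + advance * np.arange(n_win)
    idx0 = np.round(starts * rec.fs).astype(int)
    keep = idx0 + nper <= rec.n_samples  # guard against float rounding
    starts, idx0, n_win = starts[keep], idx0[keep], int(keep.sum())

    segs = np.stack(
        [rec.samples[:, a : a + nper] for a in idx0], axis=0
    )  # (n_win, n_ch, nper)
    freqs, psd = signal.periodogram(
        segs, fs=rec.fs, window="hann", scaling="density", axis=-1
    )

    # exclusion mask from the epoch grid
    ep_starts = epochs.starts
    ep_len = epochs.epoch_length
    excl = np.zeros((n_win, rec.n_channels), dtype=bool)
    for w, s in enumerate(starts):
        # epochs overlapping [s, s + window)
        overl = (ep_starts < s + window) & (ep_starts + ep_len > s)
        if overl.any():
            excl[w] = epochs.channel_flags[overl].any(axis=0)
        else:
            excl[w] = True  # window outside the artifact-screened span
    excl |= epochs.channel_rejected[None, :]
    psd[excl] = np.nan
    return WindowPSD(freqs=freqs, psd=psd, starts=starts, window=window)


def median_over_channels(wpsd: WindowPSD) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-wise median PSD across available (non-excluded) channels.

    Returns
    -------
    med : ndarray, shape (n_windows, n_freqs)
        Median PSD; all-NaN rows where no channel was available.
    n_used : ndarray, shape (n_windows,)
        Channels contributing per window.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(wpsd.psd, axis=1)
    n_used = (~np.isnan(wpsd.psd).all(axis=2)).sum(axis=1)
    med[n_used == 0] = np.nan
    return med, n_used


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of the PSD over [lo, hi] on the native frequency
    grid (no interpolation). Works on a single PSD or a stack (last axis =
    frequency); returns µV²."""
    if lo >= hi:
        raise ValueError(f"band [{lo}, {hi}] is degenerate")
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise ValueError(
            f"band [{lo}, {hi}] outside PSD support [{freqs[0]}, {freqs[-1]}]"
        )
    m = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return np.trapezoid(np.asarray(psd)[..., m], freqs[m], axis=-1)


def adr(p_alpha, p_delta):
    """Normalized alpha-delta ratio (Pa - Pd)/(Pa + Pd), clipped to [-1, 1].

    Vectorized; windows where both powers are zero (or NaN) yield NaN
    (missing), never -1 or 0.
    """
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_delta = np.asarray(p_delta, dtype=float)
    denom = p_alpha + p_delta
    bad = ~(denom > 0)
    if np.any(bad & ~np.isnan(denom)):
        logger.warning("ADR undefined for %d window(s) with zero total power",
                       int(np.sum(bad & ~np.isnan(denom))))
    # zero/negative total power is mapped to missing below, so the division
    # itself needs no epsilon guard (which would break the exact identities)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (p_alpha - p_delta) / denom
    out = np.where(bad, np.nan, out)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def minute_series(
    window_starts: np.ndarray,
    window_adrs: np.ndarray = None,
    duration_min: int | None = None,
    nominal_per_minute: int | None = None,
    *,
    band_powers: tuple[np.ndarray, np.ndarray] | None = None,
    mode: str = "per_window",
) -> pd.DataFrame:
    """Average window ADRs into minute bins [k, k+1) since seizure offset.

    A bin is missing when fewer than 50% of its nominal windows are valid.
    ``mode="power_first"`` averages alpha/delta band powers over the minute
    and takes a single ADR instead (requires ``band_powers``).

    Returns a DataFrame with columns minute, adr, n_windows.
    """
    starts_min = np.asarray(window_starts) / 60.0
    if mode == "power_first":
        if band_powers is None:
            raise ValueError("power_first mode requires band_powers")
        pa, pd_ = band_powers
        valid = ~np.isnan(pa) & ~np.isnan(pd_)
    elif mode == "per_window":
        window_adrs = np.asarray(window_adrs, dtype=float)
        valid = ~np.isnan(window_adrs)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if duration_min is None:
        duration_min = int(np.floor(starts_min.max())) + 1 if len(starts_min) else 0
    if nominal_per_minute is None:
        # nominal count from the observed advance (default 2.5 s -> 24/min)
        adv = np.median(np.diff(window_starts)) if len(window_starts) > 1 else 2.5
        nominal_per_minute = int(round(60.0 / adv))

    rows = []
    for k in range(duration_min):
        in_bin = (starts_min >= k) & (starts_min < k + 1)
        ok = in_bin & valid
        n = int(ok.sum())
        if n < 0.5 * nominal_per_minute:
            val = np.nan
        elif mode == "per_window":
            val = float(np.mean(window_adrs[ok]))
        else:
            val = adr(float(np.mean(pa[ok])), float(np.mean(pd_[ok])))
        rows.append((k, val, n))
    return pd.DataFrame(rows, columns=["minute", "adr", "n_windows"])


def compute_adr_series(
    rec: EEGRecording,
    epochs: EpochSet,
    window: float = 5.0,
    overlap: float = 0.5,
    duration_min: int | None = None,
    mode: str = "per_window",
) -> pd.DataFrame:
    """Full spectral path: windowed PSDs -> channel median -> band powers ->
    ADR -> per-minute series. The recording's time origin must be seizure
    offset (crop first)."""
    wpsd = window_psd(rec, epochs, window=window, overlap=overlap)
    med, _ = median_over_channels(wpsd)
    pa = band_power(wpsd.freqs, med, *ALPHA_BAND)
    pd_ = band_power(wpsd.freqs, med, *DELTA_BAND)
    if mode == "power_first":
        return minute_series(
            wpsd.starts, duration_min=duration_min,
            band_powers=(pa, pd_), mode="power_first",
        )
    window_adrs = adr(pa, pd_)
    return minute_series(wpsd.starts, window_adrs, duration_min=duration_min)
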