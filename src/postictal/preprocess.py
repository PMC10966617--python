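"""Raw EEG preprocessing: band-pass filtering, epoching, artifact screening,
and seizure/suppression marker utilities.

All signals are in microvolts. Postictal time is expressed in minutes relative
to seizure offset (offset itself = 0.0); intervals are half-open [start, end).
Seizure markers are accepted from annotations when available; automated
suppression detection only *proposes* an offset and never silently overrides
an annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "SeizureMarkers",
    "EpochSet",
    "bandpass_filter",
    "segment_epochs",
    "flag_artifacts",
    "detect_suppression",
    "propose_seizure_offset",
    "seizure_duration",
]


@dataclass
class SeizureMarkers:
    """Seizure onset/offset in seconds on the recording's time axis."""

    onset_s: float
    offset_s: float


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling frequency in Hz.
    channel_labels : list of str
        Unique 10-20 electrode names.
    start_time : float
        Start of the recording in seconds relative to the recording origin.
    markers : SeizureMarkers, optional
        Annotated seizure onset/offset in seconds.
    artifact_times : list of (float, int)
        Metadata for injected artifacts: (time in s, channel index).
        Populated by the simulator; empty for real recordings.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0
    markers: SeizureMarkers | None = None
    artifact_times: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def crop(self, t0: float, t1: float | None = None) -> "EEGRecording":
        """Return the sub-recording on [t0, t1) seconds of the time axis."""
        i0 = int(round(t0 * self.fs))
        i1 = self.n_samples if t1 is None else int(round(t1 * self.fs))
        i0 = max(i0, 0)
        return replace(
            self,
            samples=self.samples[:, i0:i1].copy(),
            start_time=self.start_time + i0 / self.fs,
            artifact_times=[
                (t - i0 / self.fs, ch)
                for (t, ch) in self.artifact_times
                if i0 / self.fs <= t < i1 / self.fs
            ],
        )


@dataclass
class EpochSet:
    """Contiguous 5-s epoch grid with per-channel artifact flags.

    ``channel_flags[i, c]`` is True when epoch i on channel c contains an
    artifact; ``channel_rejected[c]`` marks channels flagged in more than half
    of all epochs (rejected wholesale, emulating noisy/detached electrodes).
    """

    starts: np.ndarray  # epoch start times, seconds on the recording axis
    epoch_length: float
    channel_flags: np.ndarray  # (n_epochs, n_channels) bool
    channel_rejected: np.ndarray  # (n_channels,) bool

    @property
    def n_epochs(self) -> int:
        return len(self.starts)

    def epoch_valid(self) -> np.ndarray:
        """Per-epoch flag: at least one unrejected, unflagged channel."""
        usable = ~self.channel_flags & ~self.channel_rejected[None, :]
        return usable.any(axis=1)


def bandpass_filter(
    rec: EEGRecording, low: float = 0.5, high: float = 30.0
) -> EEGRecording:
    """First-order Butterworth band-pass, applied forward-backward (zero phase).

    Raises
    ------
    ValueError
        If the sampling rate does not satisfy fs > 2*high.
    """
    if rec.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for band edge {high} Hz"
        )
    sos = signal.butter(1, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def segment_epochs(
    rec: EEGRecording, t0: float = 0.0, epoch_length: float = 5.0
) -> EpochSet:
    """Segment the recording into contiguous epochs starting at ``t0`` seconds.

    The trailing partial epoch is discarded. Artifact flags start all-clear;
    run :func:`flag_artifacts` to populate them.
    """
    available = rec.duration - t0
    n = int(np.floor(available / epoch_length)) if available > 0 else 0
    if n <= 0:
        warnings.warn("recording too short for a single epoch", stacklevel=2)
        n = 0
    starts = t0 + epoch_length * np.arange(n)
    return EpochSet(
        starts=starts,
        epoch_length=epoch_length,
        channel_flags=np.zeros((n, rec.n_channels), dtype=bool),
        channel_rejected=np.zeros(rec.n_channels, dtype=bool),
    )


def flag_artifacts(
    rec: EEGRecording,
    epochs: EpochSet,
    amp_thresh: float = 200.0,
    flat_thresh: float = 0.1,
) -> EpochSet:
    """Screen channel-epochs for artifacts.

    A channel-epoch is flagged when its peak absolute amplitude exceeds
    ``amp_thresh`` µV (movement/electrode pop) or its peak-to-peak range is
    below ``flat_thresh`` µV (detached/flat electrode). Channels flagged in
    more than 50% of epochs are rejected wholesale. Thresholds are automated
    surrogates for visual inspection and are configurable.
    """
    n_ep = epochs.n_epochs
    flags = np.zeros((n_ep, rec.n_channels), dtype=bool)
    for i, s in enumerate(epochs.starts):
        a = int(round(s * rec.fs))
        b = a + int(round(epochs.epoch_length * rec.fs))
        seg = rec.samples[:, a:b]
        peak = np.abs(seg).max(axis=1)
        ptp = seg.max(axis=1) - seg.min(axis=1)
        flags[i] = (peak > amp_thresh) | (ptp < flat_thresh)
    rejected = (
        flags.mean(axis=0) > 0.5 if n_ep else np.zeros(rec.n_channels, bool)
    )
    for c in np.flatnonzero(rejected):
        logger.info(
            "channel %s rejected (%.0f%% flagged epochs)",
            rec.channel_labels[c],
            100 * flags[:, c].mean(),
        )
    return EpochSet(
        starts=epochs.starts,
        epoch_length=epochs.epoch_length,
        channel_flags=flags,
        channel_rejected=rejected,
    )


def _amplitude_envelope(rec: EEGRecording, window: float = 0.5) -> np.ndarray:
    """Cross-channel amplitude envelope: RMS in sliding windows of ``window``
    seconds per channel, then median across channels ("generalized"
    suppression means most channels, robust to one bad electrode)."""
    w = max(int(round(window * rec.fs)), 1)
    kernel = np.ones(w) / w
    sq = rec.samples**2
    # moving-average of squared signal, same length (centered)
    ms = np.apply_along_axis(
        lambda x: np.convolve(x, kernel, mode="same"), 1, sq
    )
    rms = np.sqrt(ms)
    return np.median(rms, axis=0)


def detect_suppression(
    rec: EEGRecording,
    amp: float = 10.0,
    min_dur: float = 2.0,
    window: float = 0.5,
) -> list[tuple[float, float]]:
    """Find maximal intervals of generalized EEG suppression.

    Returns sorted, disjoint half-open intervals [start, end) in seconds where
    the cross-channel amplitude envelope stays below ``amp`` µV for at least
    ``min_dur`` seconds. An empty list means no suppression.
    """
    env = _amplitude_envelope(rec, window=window)
    below = env < amp
    if not below.any():
        return []
    # edges of runs of True
    d = np.diff(below.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(below)]
    out = []
    for a, b in zip(starts, ends):
        t0, t1 = a / rec.fs, b / rec.fs
        if t1 - t0 >= min_dur:
            out.append((t0, t1))
    return out


def propose_seizure_offset(
    rec: EEGRecording, onset_s: float = 0.0, **kwargs
) -> float | None:
    """Propose a seizure offset: start of the first suppression interval after
    ``onset_s``. Returns None if no qualifying interval exists. This is a
    fallback for missing annotations, never an override."""
    for t0, _ in detect_suppression(rec, **kwargs):
        if t0 >= onset_s:
            return t0
    return None


def seizure_duration(onset_s: float, offset_s: float) -> float:
    """Seizure duration in seconds (offset − onset).

    Raises
    ------
    ValueError
        If offset is not strictly after onset.
    """
    if offset_s <= onset_s:
        raise ValueError(
            f"seizure offset ({offset_s}) must be after onset ({onset_s})"
        )
    return offset_s - onset_s
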