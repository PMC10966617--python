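"""EDF input/output for EEG recordings.

Reading goes through MNE's EDF reader. Writing uses a minimal EDF writer
(16-bit samples, physical units µV, 1-second data records), sufficient for
round-tripping the recordings this package produces.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from pathlib import Path

import numpy as np

from .preprocess import EEGRecording

__all__ = ["read_edf", "write_edf"]

#: 10-20 electrode names recognized when normalizing channel labels
_1020 = {
    s.upper(): s for s in [
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz", "C4",
        "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2", "A1", "A2", "T7",
        "T8", "P7", "P8", "Fpz", "Oz",
    ]
}


def _normalize_label(label: str) -> str:
    """Map raw EDF labels like 'EEG Fp1-Cz' onto bare 10-20 names."""
    s = label.strip()
    for prefix in ("EEG ", "eeg "):
        if s.startswith(prefix):
            s = s[len(prefix):]
    s = s.split("-")[0].strip()
    return _1020.get(s.upper(), s)


def _fixed(s: str, width: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: EEGRecording) -> None:
    """Write a recording as 16-bit EDF (one 1-s data record per second).

    The sampling rate must be a whole number of samples per second; a
    trailing partial second is dropped.
    """
    path = Path(path)
    spr = int(round(rec.fs))
    if abs(spr - rec.fs) > 1e-9:
        raise ValueError(f"EDF writer requires integer fs, got {rec.fs}")
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels
    data = rec.samples[:, : n_rec * spr]

    # symmetric physical range per channel, header-representable in 8 chars
    pmaxs = []
    for c in range(ns):
        m = float(np.max(np.abs(data[c]))) or 1.0
        pm = float(f"{m * 1.001 + 1e-6:.6g}")
        while pm < m:  # guard against downward rounding
            pm = float(f"{pm * 1.01:.6g}")
        pmaxs.append(pm)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _fixed("0", 8),
        _fixed("X X X X", 80),
        _fixed("Startdate X X X X", 80),
        _fixed(now.strftime("%d.%m.%y"), 8),
        _fixed(now.strftime("%H.%M.%S"), 8),
        _fixed(str(256 * (ns + 1)), 8),
        _fixed("", 44),
        _fixed(str(n_rec), 8),
        _fixed("1", 8),
        _fixed(str(ns), 4),
    ])
    fields = [
        [_fixed(lab, 16) for lab in rec.channel_labels],
        [_fixed("AgAgCl electrode", 80)] * ns,
        [_fixed("uV", 8)] * ns,
        [_fixed(f"{-pm:.6g}"[:8], 8) for pm in pmaxs],
        [_fixed(f"{pm:.6g}"[:8], 8) for pm in pmaxs],
        [_fixed("-32768", 8)] * ns,
        [_fixed("32767", 8)] * ns,
        [_fixed("", 80)] * ns,
        [_fixed(str(spr), 8)] * ns,
        [_fixed("", 32)] * ns,
    ]
    header += b"".join(b"".join(f) for f in fields)

    # EDF linear map: phys = cal * dig + off, cal = (pmax-pmin)/(dmax-dmin)
    pm = np.array(pmaxs)[:, None]
    cal = 2 * pm / 65535.0
    off = pm - cal * 32767.0
    digital = np.clip(np.round((data - off) / cal), -32768, 32767).astype("<i2")
    # interleave: per record, all samples of ch0, then ch1, ...
    recs = digital.reshape(ns, n_rec, spr).transpose(1, 0, 2)
    path.write_bytes(header + recs.tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (µV).

    Channel labels are normalized to bare 10-20 names; non-EEG channels are
    dropped with a warning. Data recorded in other voltage units are rescaled
    to µV (MNE converts all voltages to volts internally).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # corrupt header etc.
        raise ValueError(f"cannot read EDF {path}: {exc}") from exc
    picks = [i for i, t in enumerate(raw.get_channel_types())
             if t in ("eeg", "misc")]
    dropped = [raw.ch_names[i] for i in range(len(raw.ch_names))
               if i not in picks]
    if dropped:
        warnings.warn(f"dropping non-EEG channels: {dropped}", stacklevel=2)
    samples_uv = raw.get_data(picks=picks) * 1e6
    labels = [_normalize_label(raw.ch_names[i]) for i in picks]
    return EEGRecording(samples=samples_uv, fs=float(raw.info["sfreq"]),
                        channel_labels=labels)
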