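"""Reading, validation and preprocessing of multi-channel resting-state EEG.

The pipeline assumes scalp EEG in microvolts on a 10-20 montage (default
20 electrodes, 500 Hz). Preprocessing follows common clinical practice:
bad-channel interpolation from montage neighbours, average re-referencing,
and a zero-phase FIR band-pass (default 0.5-45 Hz).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Recording",
    "Montage",
    "EpochedRecording",
    "Consciousness",
    "Side",
    "DEFAULT_MONTAGE",
    "read_recording",
    "read_clinical_labels",
    "doc_binary",
    "preprocess",
    "detect_bad_channels",
    "epoch",
    "drop_artifact_epochs",
    "concatenate_epochs",
]


# ---------------------------------------------------------------------------
# Montage geometry

# Adjacency of the 20-electrode 10-20 montage, as an undirected edge list.
_EDGES_1020 = [
    ("Fp1", "Fp2"), ("Fp1", "F7"), ("Fp1", "F3"), ("Fp1", "Fz"),
    ("Fp2", "F4"), ("Fp2", "F8"), ("Fp2", "Fz"),
    ("F7", "F3"), ("F7", "T3"),
    ("F3", "Fz"), ("F3", "C3"),
    ("Fz", "F4"), ("Fz", "Cz"),
    ("F4", "F8"), ("F4", "C4"),
    ("F8", "T4"),
    ("T3", "C3"), ("T3", "T5"),
    ("C3", "Cz"), ("C3", "P3"),
    ("Cz", "C4"), ("Cz", "Pz"),
    ("C4", "T4"), ("C4", "P4"),
    ("T4", "T6"),
    ("T5", "P3"), ("T5", "O1"),
    ("P3", "Pz"), ("P3", "O1"),
    ("Pz", "P4"), ("Pz", "Oz"),
    ("P4", "T6"), ("P4", "O2"),
    ("T6", "O2"),
    ("O1", "Oz"), ("Oz", "O2"),
]

_LABELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "Oz", "O2",
]

# Case-insensitive aliases seen in clinical exports (old vs new temporal names).
_CANONICAL_ALIASES = {
    "t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6",
    **{lab.lower(): lab for lab in _LABELS_1020},
}


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus a symmetric neighbour relation."""

    labels: tuple[str, ...]
    neighbors: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                if a not in self.neighbors.get(b, ()):
                    raise ValueError(f"neighbor relation not symmetric: {a}-{b}")


def _build_default_montage() -> Montage:
    nbrs: dict[str, list[str]] = {lab: [] for lab in _LABELS_1020}
    for a, b in _EDGES_1020:
        nbrs[a].append(b)
        nbrs[b].append(a)
    return Montage(tuple(_LABELS_1020), {k: tuple(v) for k, v in nbrs.items()})


DEFAULT_MONTAGE = _build_default_montage()


def canonical_label(name: str) -> str:
    """Map a raw channel name to its canonical 10-20 form where possible.

    Unknown labels are preserved verbatim.
    """
    key = name.strip().replace("EEG ", "").replace("-REF", "").strip().lower()
    return _CANONICAL_ALIASES.get(key, name.strip())


# ---------------------------------------------------------------------------
# Core containers


@dataclass
class Recording:
    """Channels-by-samples EEG matrix in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique, montage-ordered channel names.
    subject_id : str
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochedRecording:
    """Stack of equal-length epochs cut from one recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    epoch_length_s: float
    overlap_fraction: float
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


class Consciousness(str, Enum):
    awake = "awake"
    somnolence = "somnolence"
    stupor = "stupor"
    light_coma = "light_coma"
    middle_coma = "middle_coma"
    deep_coma = "deep_coma"


class Side(str, Enum):
    """Laterality code: bilateral, left, right or not affected."""

    B = "B"
    L = "L"
    R = "R"
    none = "none"


def read_clinical_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-subject clinical label table.

    Expects CSV columns ``subject_id, consciousness, motor_side, stroke_side``;
    enum values are validated against the closed vocabularies.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "consciousness", "motor_side", "stroke_side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    for col, enum in (
        ("consciousness", Consciousness),
        ("motor_side", Side),
        ("stroke_side", Side),
    ):
        bad = set(df[col]) - {e.value for e in enum}
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    return df


def doc_binary(consciousness: str | Consciousness) -> int:
    """Binary disorders-of-consciousness label: awake -> 0, any other state -> 1."""
    value = Consciousness(consciousness).value
    return 0 if value == Consciousness.awake.value else 1


# ---------------------------------------------------------------------------
# Readers


def read_recording(
    path: str | os.PathLike,
    fmt: str | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read an EEG recording from EDF/EDF+ or a delimited numeric matrix.

    Parameters
    ----------
    path : path to the file.
    fmt : "edf" or "delimited"; inferred from the extension when None.
    fs : sampling rate, required for delimited files without one (default 500).
    subject_id : defaults to the file stem.

    Returns
    -------
    Recording with channel labels mapped to canonical 10-20 names where
    recognised; unrecognised labels are kept verbatim.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.lower().endswith((".edf", ".bdf")) else "delimited"
    sid = subject_id or os.path.splitext(os.path.basename(path))[0]

    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        labels = [canonical_label(name) for name in raw.ch_names]
        return Recording(data, float(raw.info["sfreq"]), labels, sid)

    if fmt == "delimited":
        sep = "\t" if path.lower().endswith((".tsv", ".txt")) else ","
        with open(path) as fh:
            first = fh.readline()
        tokens = [t.strip() for t in first.strip().split(sep)]

        def _is_number(tok: str) -> bool:
            try:
                float(tok)
                return True
            except ValueError:
                return False

        has_header = not all(_is_number(t) for t in tokens if t)
        if has_header:
            labels = [canonical_label(t) for t in tokens if t]
            data = np.loadtxt(path, delimiter=sep, skiprows=1, ndmin=2)
            # header lists one name per channel row
            if data.shape[0] != len(labels) and data.shape[1] == len(labels):
                data = data.T
        else:
            data = np.loadtxt(path, delimiter=sep, ndmin=2)
            labels = [f"ch{i}" for i in range(data.shape[0])]
        if data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        return Recording(data, float(fs or 500.0), labels, sid)

    raise ValueError(f"unknown format: {fmt!r}")


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording as a delimited matrix, one row per channel."""
    header = ",".join(rec.channel_labels)
    np.savetxt(path, rec.data, delimiter=",", header=header, comments="")


# ---------------------------------------------------------------------------
# Preprocessing


def detect_bad_channels(
    rec: Recording,
    z_thresh: float = 5.0,
    montage: Montage = DEFAULT_MONTAGE,
) -> list[str]:
    """Flag channels whose log-variance deviates robustly from their neighbours.

    For each channel the deviation of its log-variance from the median
    log-variance of its montage neighbours is computed; deviations are then
    converted to robust z-scores (median / scaled MAD across channels) and
    channels with ``|z| > z_thresh`` are returned. Channels absent from the
    montage are compared against all other channels.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    if rec.n_channels < 3:
        raise ValueError("need at least 3 channels to judge outliers")
    var = rec.data.var(axis=1)
    logvar = np.log(np.maximum(var, np.finfo(float).tiny))
    idx = {lab: i for i, lab in enumerate(rec.channel_labels)}
    dev = np.empty(rec.n_channels)
    for i, lab in enumerate(rec.channel_labels):
        nbr_idx = [idx[n] for n in montage.neighbors.get(lab, ()) if n in idx]
        if not nbr_idx:
            nbr_idx = [j for j in range(rec.n_channels) if j != i]
        dev[i] = logvar[i] - np.median(logvar[nbr_idx])
    mad = np.median(np.abs(dev - np.median(dev)))
    if mad == 0:
        # no dispersion: only flag channels that differ at all, scaled by an
        # absolute floor so identical channels yield an empty list
        scale = 1e-12
    else:
        scale = 1.4826 * mad
    z = (dev - np.median(dev)) / scale
    return [rec.channel_labels[i] for i in np.flatnonzero(np.abs(z) > z_thresh)]


def _interpolate_bad(
    data: np.ndarray,
    labels: list[str],
    bad: list[str],
    montage: Montage,
) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(labels)}
    out = data.copy()
    bad_set = set(bad)
    for lab in bad:
        if lab not in idx:
            raise ValueError(f"unknown bad channel {lab!r}")
        good_nbrs = [
            idx[n]
            for n in montage.neighbors.get(lab, ())
            if n in idx and n not in bad_set
        ]
        if not good_nbrs:
            raise ValueError(f"bad channel {lab!r} has no good neighbours")
        out[idx[lab]] = data[good_nbrs].mean(axis=0)
    return out


def _fir_bandpass(fs: float, hp_hz: float, lp_hz: float,
                  transition_hz: float = 0.5) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase band-pass taps."""
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return sps.firwin(
        numtaps, [hp_hz, lp_hz], pass_zero=False, fs=fs, window="hamming"
    )


def preprocess(
    rec: Recording,
    hp_hz: float = 0.5,
    lp_hz: float = 45.0,
    bad_channels: list[str] | None = None,
    montage: Montage = DEFAULT_MONTAGE,
) -> Recording:
    """Interpolate bad channels, average-reference, and band-pass filter.

    Steps, in order:

    1. each listed bad channel is replaced by the mean of its good montage
       neighbours;
    2. the instantaneous mean across channels is subtracted (average
       reference), making the per-sample channel mean exactly zero;
    3. zero-phase band-pass: windowed-sinc FIR (Hamming, 0.5 Hz transition)
       applied forward and backward.
    """
    if not (0 < hp_hz < lp_hz < rec.fs / 2):
        raise ValueError("require 0 < hp_hz < lp_hz < fs/2")
    data = rec.data
    if bad_channels:
        data = _interpolate_bad(data, rec.channel_labels, bad_channels, montage)
    data = data - data.mean(axis=0, keepdims=True)
    taps = _fir_bandpass(rec.fs, hp_hz, lp_hz)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    data = sps.filtfilt(taps, [1.0], data, axis=1, padlen=padlen)
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(data, rec.fs, list(rec.channel_labels), rec.subject_id)


# ---------------------------------------------------------------------------
# Epoching


def epoch(rec: Recording, length_s: float = 2.0,
          overlap: float = 0.0) -> EpochedRecording:
    """Cut a recording into maximal full epochs; trailing samples are dropped.

    Epochs are half-open sample intervals ``[start, start + length)`` with
    stride ``round(length * fs * (1 - overlap))``.
    """
    n_len = int(round(length_s * rec.fs))
    if n_len < 2:
        raise ValueError("epoch length must cover at least 2 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if rec.n_samples < n_len:
        raise ValueError("recording shorter than one epoch")
    stride = max(1, int(round(n_len * (1 - overlap))))
    starts = range(0, rec.n_samples - n_len + 1, stride)
    blocks = np.stack([rec.data[:, s:s + n_len] for s in starts])
    return EpochedRecording(
        blocks, length_s, overlap, rec.fs,
        list(rec.channel_labels), rec.subject_id,
    )


def drop_artifact_epochs(ep: EpochedRecording,
                         threshold_uv: float = 150.0) -> EpochedRecording:
    """Drop epochs whose peak absolute amplitude exceeds ``threshold_uv``.

    Epoch-level surrogate for continuous artifact rejection: preserves the
    shapes downstream stages expect while removing high-amplitude segments.
    """
    peak = np.abs(ep.epochs).max(axis=(1, 2))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError("all epochs exceed the artifact threshold")
    return EpochedRecording(
        ep.epochs[keep], ep.epoch_length_s, ep.overlap_fraction, ep.fs,
        list(ep.channel_labels), ep.subject_id,
    )


def concatenate_epochs(ep: EpochedRecording) -> Recording:
    """Stitch non-overlapping epochs back into a continuous recording."""
    if ep.overlap_fraction != 0:
        raise ValueError("only non-overlapping epochs can be concatenated")
    data = np.concatenate(list(ep.epochs), axis=1)
    labels = ep.channel_labels or [f"ch{i}" for i in range(ep.n_channels)]
    return Recording(data, ep.fs, labels, ep.subject_id)
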