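"""EEG microstate segmentation and statistical parameters.

Microstates are brief quasi-stable scalp topographies. Segmentation uses
the polarity-invariant modified k-means: maps at local maxima of global
field power (GFP) are clustered by squared spatial correlation, prototypes
are the first principal eigenvectors of their assigned maps, and every
sample is then backfitted to the best-matching prototype. Per-state
statistics (mean GFP, duration, occurrence, coverage, global explained
variance) form the classifier feature vector: 5k features for k states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import FeatureVector
from .eeg_io import Recording

__all__ = [
    "GFPSeries",
    "MicrostatePrototypes",
    "MicrostateSegmentation",
    "MicrostateParameters",
    "compute_gfp",
    "gfp_peaks",
    "modified_kmeans",
    "backfit",
    "microstate_parameters",
    "microstate_features",
]

PARAMETER_NAMES = ("mean_gfp", "duration_ms", "occurrence_per_s", "coverage", "gev")


@dataclass
class GFPSeries:
    """Global field power per sample (µV), nonnegative."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP must be nonnegative")


@dataclass
class MicrostatePrototypes:
    """k unit-norm topographic maps, defined up to sign."""

    maps: np.ndarray  # (k, n_channels)
    training_gev: float = np.nan

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("prototype maps must be unit-norm")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateSegmentation:
    """Per-sample state labels in 0..k-1."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


@dataclass
class MicrostateParameters:
    """Per-state statistics; arrays indexed by state 0..k-1."""

    mean_gfp: np.ndarray        # µV
    duration_ms: np.ndarray     # mean stable-run length
    occurrence_per_s: np.ndarray
    coverage: np.ndarray        # fraction of samples, sums to 1
    gev: np.ndarray             # per-state global explained variance


def _average_reference(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=0, keepdims=True)


def compute_gfp(rec: Recording) -> GFPSeries:
    """GFP_t: root mean square of the average-referenced values at sample t.

    Equals the spatial standard deviation across channels. Input that is
    not average-referenced is re-referenced automatically with a warning.
    """
    data = rec.data
    if np.abs(data.mean(axis=0)).max() > 1e-6 * max(np.abs(data).max(), 1e-30):
        warnings.warn("input not average-referenced; re-referencing for GFP")
        data = _average_reference(data)
    return GFPSeries(np.sqrt(np.mean(data**2, axis=0)), rec.fs)


def gfp_peaks(rec: Recording) -> np.ndarray:
    """Sample indices of local GFP maxima (strictly above both neighbours)."""
    data = _average_reference(rec.data)
    g = np.sqrt(np.mean(data**2, axis=0))
    core = (g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:])
    return np.flatnonzero(core) + 1


def _normalize_maps(data: np.ndarray) -> np.ndarray:
    """Average-reference and unit-normalize column maps; drops zero maps."""
    maps = _average_reference(data)
    norms = np.linalg.norm(maps, axis=0)
    keep = norms > 0
    return (maps[:, keep] / norms[keep]).T  # (n_maps, n_channels)


def _gev(maps: np.ndarray, gfp: np.ndarray, protos: np.ndarray,
         labels: np.ndarray) -> float:
    """GFP-weighted explained variance of maps by their assigned prototypes.

    maps: (n_maps, n_ch) unit-norm; gfp: per-map GFP; protos: (k, n_ch).
    """
    corr = np.einsum("mc,mc->m", maps, protos[labels])
    denom = np.sum(gfp**2)
    if denom == 0:
        return 0.0
    return float(np.sum((gfp * corr) ** 2) / denom)


def modified_kmeans(
    maps_at_peaks: np.ndarray,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MicrostatePrototypes:
    """Polarity-invariant k-means on topographic maps.

    Parameters
    ----------
    maps_at_peaks : (n_maps, n_channels) maps sampled at GFP peaks
        (rows need not be normalized; they are average-referenced and
        unit-normalized internally, their norms kept as GFP weights).
    k : number of prototypes, 2 <= k <= n_maps (k=1 accepted for testing).
    restarts : independent seeded initializations; the best-GEV run wins.

    Assignment maximizes the squared spatial correlation (sign-free); the
    prototype update is the first principal eigenvector of the assigned
    maps' scatter matrix. Iteration stops when the relative GEV change
    falls below ``tol``. An emptied cluster is re-seeded from the currently
    worst-explained map.
    """
    raw = np.asarray(maps_at_peaks, dtype=float)
    if raw.ndim != 2:
        raise ValueError("maps_at_peaks must be (n_maps, n_channels)")
    if not 1 <= k <= raw.shape[0]:
        raise ValueError("need 1 <= k <= number of maps")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    centered = _average_reference(raw.T).T
    gfp = np.linalg.norm(centered, axis=1) / np.sqrt(raw.shape[1])
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    maps = centered[ok] / norms[ok, None]
    gfp = gfp[ok]
    n_maps = maps.shape[0]
    rng = np.random.default_rng(seed)

    best_protos, best_gev = None, -np.inf
    for _ in range(restarts):
        protos = maps[rng.choice(n_maps, size=k, replace=False)].copy()
        prev_gev = -np.inf
        for _ in range(max_iter):
            corr = maps @ protos.T  # (n_maps, k)
            labels = np.argmax(corr**2, axis=1)
            for state in range(k):
                sel = labels == state
                if not sel.any():
                    worst = np.argmin(np.max(corr**2, axis=1))
                    protos[state] = maps[worst]
                    labels[worst] = state
                    sel = labels == state
                # first principal eigenvector of the assigned maps' scatter
                scatter = maps[sel].T @ maps[sel]
                _, v = np.linalg.eigh(scatter)
                protos[state] = v[:, -1]
            cur = _gev(maps, gfp, protos, labels)
            if prev_gev > -np.inf and abs(cur - prev_gev) <= tol * max(abs(prev_gev), 1e-12):
                break
            prev_gev = cur
        if cur > best_gev:
            best_gev, best_protos = cur, protos.copy()
    return MicrostatePrototypes(best_protos, best_gev)


def backfit(
    rec: Recording,
    protos: MicrostatePrototypes,
    min_duration_ms: float = 0.0,
) -> MicrostateSegmentation:
    """Label every sample with the prototype of maximal absolute correlation.

    Zero-GFP samples inherit the previous label (state 0 at the start).
    With ``min_duration_ms > 0``, runs shorter than the minimum are merged
    into the neighbouring state with the higher boundary correlation.
    """
    if rec.n_channels != protos.maps.shape[1]:
        raise ValueError("channel count mismatch between data and prototypes")
    maps = _average_reference(rec.data)
    norms = np.linalg.norm(maps, axis=0)
    corr = np.zeros((protos.k, rec.n_samples))
    nz = norms > 0
    corr[:, nz] = (protos.maps @ maps[:, nz]) / norms[nz]
    labels = np.argmax(np.abs(corr), axis=0)
    # zero-GFP samples inherit the previous label
    prev = 0
    for t in range(rec.n_samples):
        if not nz[t]:
            labels[t] = prev
        prev = labels[t]
    if min_duration_ms > 0:
        labels = _smooth_short_runs(labels, rec.fs, min_duration_ms, corr)
    return MicrostateSegmentation(labels, rec.fs)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encoding: list of (state, start, length)."""
    out = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out.append((int(labels[start]), start, t - start))
            start = t
    return out


def _smooth_short_runs(labels: np.ndarray, fs: float, min_ms: float,
                       corr: np.ndarray) -> np.ndarray:
    min_len = int(np.ceil(min_ms * fs / 1000.0))
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        for state, start, length in _runs(labels):
            if length >= min_len or length == len(labels):
                continue
            left = labels[start - 1] if start > 0 else None
            right = labels[start + length] if start + length < len(labels) else None
            if left is None and right is None:
                continue
            if left is None:
                tgt = right
            elif right is None:
                tgt = left
            else:
                mid = slice(start, start + length)
                tgt = left if np.abs(corr[left, mid]).sum() >= np.abs(
                    corr[right, mid]).sum() else right
            labels[start:start + length] = tgt
            changed = True
            break
    return labels


def microstate_parameters(
    seg: MicrostateSegmentation,
    rec: Recording,
    protos: MicrostatePrototypes,
) -> MicrostateParameters:
    """Per-state mean GFP, duration, occurrence, coverage and GEV.

    duration: mean length of the state's stable runs (ms); occurrence:
    runs per second; coverage: fraction of samples; GEV_k: GFP-weighted
    squared correlation of the state's samples with its prototype,
    normalized by the total squared GFP. A state that never occurs gets
    zeros and a warning.
    """
    labels = seg.labels
    if len(labels) != rec.n_samples:
        raise ValueError("segmentation and recording lengths differ")
    k = protos.k
    data = _average_reference(rec.data)
    gfp = np.sqrt(np.mean(data**2, axis=0))
    norms = np.linalg.norm(data, axis=0)
    corr = np.zeros((k, rec.n_samples))
    nz = norms > 0
    corr[:, nz] = (protos.maps @ data[:, nz]) / norms[nz]

    total_s = rec.n_samples / rec.fs
    total_gfp_sq = np.sum(gfp**2)
    runs = _runs(labels)
    mean_gfp = np.zeros(k)
    duration = np.zeros(k)
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    gev = np.zeros(k)
    for state in range(k):
        sel = labels == state
        state_runs = [r for r in runs if r[0] == state]
        if not sel.any():
            warnings.warn(f"microstate {state} never occurs; parameters set to 0")
            continue
        mean_gfp[state] = gfp[sel].mean()
        lengths = np.array([r[2] for r in state_runs], dtype=float)
        duration[state] = lengths.mean() / rec.fs * 1000.0
        occurrence[state] = len(state_runs) / total_s
        coverage[state] = sel.mean()
        if total_gfp_sq > 0:
            gev[state] = np.sum((gfp[sel] * corr[state, sel]) ** 2) / total_gfp_sq
    return MicrostateParameters(mean_gfp, duration, occurrence, coverage, gev)


def microstate_features(
    rec: Recording,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    min_duration_ms: float = 0.0,
    protos: MicrostatePrototypes | None = None,
) -> FeatureVector:
    """Segment a recording into k microstates and return the 5k features.

    Prototypes are fitted on the recording's own GFP-peak maps unless
    pre-fitted (e.g. group-level, training subjects only) prototypes are
    supplied. States are ordered by descending coverage so feature vectors
    are comparable across subjects; each state contributes
    (mean_gfp, duration_ms, occurrence_per_s, coverage, gev).
    """
    if not 2 <= k <= 30:
        raise ValueError("k must lie in 2..30")
    if protos is None:
        peaks = gfp_peaks(rec)
        if len(peaks) < k:
            raise ValueError("fewer GFP peaks than clusters")
        protos = modified_kmeans(rec.data[:, peaks].T, k, restarts, seed, tol)
    seg = backfit(rec, protos, min_duration_ms)
    params = microstate_parameters(seg, rec, protos)
    order = np.argsort(-params.coverage, kind="stable")
    values = []
    names = []
    for rank, state in enumerate(order):
        for pname, arr in zip(
            PARAMETER_NAMES,
            (params.mean_gfp, params.duration_ms, params.occurrence_per_s,
             params.coverage, params.gev),
        ):
            values.append(arr[state])
            names.append(f"ms{rank}_{pname}")
    return FeatureVector(np.array(values), names, f"microstate_k{k}",
                         rec.subject_id)
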