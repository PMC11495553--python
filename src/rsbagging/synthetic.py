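"""Synthetic EEG and cohort generators with known ground truth.

Every analysis stage has a matching generator so the full pipeline is
testable without clinical recordings:

* coupled oscillators with von Mises phase jitter (phase measures),
* stable MVAR systems with planted directed influence (GC/DTF/PDC),
* piecewise-stable scalp topographies (microstates),
* imbalanced feature cohorts, including a preset reproducing the study
  cohort composition (241 stroke patients, 97 with a disorder of
  consciousness) for the classifier protocol.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .connectivity import MVARModel
from .eeg_io import Recording
from .ensemble import Dataset

__all__ = [
    "OscillatorSpec",
    "MVARSpec",
    "MicrostateSpec",
    "CohortSpec",
    "gen_oscillators",
    "gen_mvar",
    "gen_microstate_eeg",
    "gen_cohort",
    "gen_imbalanced_gaussians",
    "vonmises_resultant",
    "kappa_for_strength",
    "random_templates",
    "table1_labels",
    "spec_from_yaml",
]


# ---------------------------------------------------------------------------
# von Mises helpers


def vonmises_resultant(kappa: float) -> float:
    """Population mean resultant length I1(kappa)/I0(kappa) of a von Mises."""
    if kappa <= 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_for_strength(strength: float) -> float:
    """Concentration kappa whose mean resultant equals ``strength``.

    strength is the target population phase locking in [0, 1); returns 0
    for strength 0 and infinity for strength >= 1 - 1e-9.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    if strength == 0:
        return 0.0
    if strength >= 1 - 1e-9:
        return np.inf
    return float(optimize.brentq(
        lambda k: vonmises_resultant(k) - strength, 1e-9, 1e4
    ))


# ---------------------------------------------------------------------------
# Coupled oscillators


@dataclass
class OscillatorSpec:
    """Sinusoidal channels with controllable pairwise phase coupling.

    ``coupling`` entries are (chan_a, chan_b, phase_lag_rad, strength):
    within each segment channel b's phase offset from channel a is the lag
    plus von Mises jitter whose concentration is solved so that the
    population phase locking equals ``strength``. Phases are redrawn every
    ``segment_length_s`` (one downstream spectral observation per segment).
    """

    n_channels: int = 2
    tone_freq: float = 10.0
    coupling: list[tuple[int, int, float, float]] = field(default_factory=list)
    noise_sd: float = 0.1
    fs: float = 250.0
    duration_s: float = 60.0
    seed: int = 0
    segment_length_s: float = 2.0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.tone_freq:
            raise ValueError("fs must exceed twice the tone frequency")
        for a, b, _, s in self.coupling:
            if not 0 <= s <= 1:
                raise ValueError("coupling strength must lie in [0, 1]")
            if not (0 <= a < self.n_channels and 0 <= b < self.n_channels):
                raise ValueError("coupling channel index out of range")


def gen_oscillators(spec: OscillatorSpec) -> Recording:
    """Simulate the coupled-oscillator recording described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n_seg_len = int(round(spec.segment_length_s * spec.fs))
    n_seg = int(spec.duration_s * spec.fs) // n_seg_len
    if n_seg < 1:
        raise ValueError("duration shorter than one segment")
    t = np.arange(n_seg_len) / spec.fs
    kappas = {(a, b): (lag, kappa_for_strength(s))
              for a, b, lag, s in spec.coupling}
    targets = {b: (a, lag, kappa) for (a, b), (lag, kappa) in kappas.items()}
    data = np.empty((spec.n_channels, n_seg * n_seg_len))
    for s in range(n_seg):
        phases = {}
        for c in range(spec.n_channels):
            if c not in targets:
                phases[c] = rng.uniform(0, 2 * np.pi)
        for c in range(spec.n_channels):
            if c in targets:
                a, lag, kappa = targets[c]
                base = phases.get(a)
                if base is None:  # chained coupling: resolve source first
                    raise ValueError("coupling chains are not supported")
                if np.isinf(kappa):
                    jitter = 0.0
                else:
                    jitter = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(
                        -np.pi, np.pi)
                phases[c] = base + lag + jitter
        seg = slice(s * n_seg_len, (s + 1) * n_seg_len)
        for c in range(spec.n_channels):
            data[c, seg] = np.cos(2 * np.pi * spec.tone_freq * t + phases[c])
    data += spec.noise_sd * rng.standard_normal(data.shape)
    labels = [f"osc{i}" for i in range(spec.n_channels)]
    return Recording(data, spec.fs, labels, f"osc_seed{spec.seed}")


# ---------------------------------------------------------------------------
# MVAR systems


@dataclass
class MVARSpec:
    """A stable MVAR generating system with known directed influence."""

    coeffs: np.ndarray           # (p, n_ch, n_ch)
    noise_cov: np.ndarray | None = None
    fs: float = 250.0
    duration_s: float = 60.0
    seed: int = 0
    burn_in: int = 500


def gen_mvar(spec: MVARSpec) -> Recording:
    """Exact simulation of the MVAR system with burn-in discarded.

    Raises if the coefficient matrices define an unstable system.
    """
    coeffs = np.asarray(spec.coeffs, dtype=float)
    p, n_ch, _ = coeffs.shape
    cov = np.eye(n_ch) if spec.noise_cov is None else np.asarray(spec.noise_cov)
    model = MVARModel(coeffs, cov, spec.fs)  # validates stability/symmetry
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s * spec.fs)
    chol = np.linalg.cholesky(cov)
    total = n + spec.burn_in + p
    eps = rng.standard_normal((total, n_ch)) @ chol.T
    y = np.zeros((total, n_ch))
    for t in range(p, total):
        acc = eps[t].copy()
        for k in range(p):
            acc += coeffs[k] @ y[t - 1 - k]
        y[t] = acc
    data = y[spec.burn_in + p:].T
    labels = [f"ch{i}" for i in range(n_ch)]
    del model
    return Recording(data, spec.fs, labels, f"mvar_seed{spec.seed}")


# ---------------------------------------------------------------------------
# Microstate EEG


def random_templates(k: int, n_channels: int, seed: int = 0) -> np.ndarray:
    """k orthonormal average-referenced topographic maps (k, n_channels)."""
    if k >= n_channels:
        raise ValueError("need k < n_channels for average-referenced maps")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, k))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    q -= q.mean(axis=0, keepdims=True)
    q /= np.linalg.norm(q, axis=0, keepdims=True)
    return q.T


@dataclass
class MicrostateSpec:
    """Piecewise-stable topography sequence with jittered run lengths.

    Run lengths follow a shifted geometric law: minimum run
    ``(1 - duration_jitter) * mean`` plus a geometric tail, giving the
    requested mean duration. The topography amplitude is modulated by a
    rectified 10 Hz oscillation (floored so the map never vanishes), which
    creates the GFP peaks that segmentation clusters. Defaults follow the
    40-150 ms range reported for scalp microstates (mean 80 ms).
    """

    templates: np.ndarray                 # (k, n_channels) unit-norm
    mean_duration_ms: float = 80.0
    duration_jitter: float = 0.5
    gfp_scale: float = 10.0               # µV
    noise_sd: float = 1.0                 # µV per channel
    fs: float = 250.0
    duration_s: float = 60.0
    seed: int = 0
    modulation_hz: float = 10.0
    random_polarity: bool = True

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        norms = np.linalg.norm(self.templates, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("templates must be unit-norm")
        if self.mean_duration_ms <= 0:
            raise ValueError("mean_duration_ms must be positive")
        if not 0 <= self.duration_jitter <= 1:
            raise ValueError("duration_jitter must lie in [0, 1]")


def gen_microstate_eeg(spec: MicrostateSpec) -> tuple[Recording, np.ndarray]:
    """Simulate microstate EEG; returns the recording and true labels."""
    k, n_ch = spec.templates.shape
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s * spec.fs)
    mean_len = spec.mean_duration_ms * spec.fs / 1000.0
    min_len = max(1, int(round(mean_len * (1 - spec.duration_jitter))))
    tail_mean = max(mean_len - min_len, 0.0)
    p_geom = 1.0 / (1.0 + tail_mean)

    labels = np.empty(n, dtype=int)
    signs = np.empty(n)
    t0 = 0
    state = int(rng.integers(k))
    while t0 < n:
        run = min_len + rng.geometric(p_geom) - 1
        run = min(run, n - t0)
        labels[t0:t0 + run] = state
        signs[t0:t0 + run] = rng.choice([-1.0, 1.0]) if spec.random_polarity else 1.0
        t0 += run
        if k > 1:
            nxt = int(rng.integers(k - 1))
            state = nxt if nxt < state else nxt + 1

    t = np.arange(n) / spec.fs
    amp = spec.gfp_scale * (0.3 + 0.7 * np.abs(
        np.sin(2 * np.pi * spec.modulation_hz * t)))
    data = spec.templates[labels].T * (amp * signs) * np.sqrt(n_ch)
    data = data + spec.noise_sd * rng.standard_normal(data.shape)
    ch = [f"ch{i}" for i in range(n_ch)]
    return Recording(data, spec.fs, ch, f"ms_seed{spec.seed}"), labels


# ---------------------------------------------------------------------------
# Cohorts

# Study cohort composition: per consciousness state, (female, male),
# stroke-location (B, L, R) counts and motor-disturbance (B, L, R) counts;
# remainders within a state have side "none".
_TABLE1 = {
    "awake": ((37, 107), (36, 52, 47), (23, 37, 46)),
    "somnolence": ((18, 34), (9, 29, 11), (15, 10, 20)),
    "stupor": ((13, 12), (8, 10, 6), (9, 5, 9)),
    "light_coma": ((3, 12), (6, 4, 4), (8, 4, 2)),
    "middle_coma": ((0, 2), (1, 1, 0), (1, 0, 1)),
    "deep_coma": ((1, 2), (0, 0, 0), (0, 0, 1)),
}


def table1_labels(seed: int = 0) -> pd.DataFrame:
    """Clinical label table with the study cohort's exact composition.

    241 subjects; per consciousness state the female/male, stroke-location
    and motor-disturbance side counts are reproduced exactly, with the
    within-state pairing of attributes randomized by ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for state, ((nf, nm), loc, motor) in _TABLE1.items():
        n = nf + nm
        sexes = ["F"] * nf + ["M"] * nm
        locs = (["B"] * loc[0] + ["L"] * loc[1] + ["R"] * loc[2]
                + ["none"] * (n - sum(loc)))
        motors = (["B"] * motor[0] + ["L"] * motor[1] + ["R"] * motor[2]
                  + ["none"] * (n - sum(motor)))
        rng.shuffle(sexes)
        rng.shuffle(locs)
        rng.shuffle(motors)
        for i in range(n):
            rows.append({
                "subject_id": f"S{sid:03d}",
                "consciousness": state,
                "motor_side": motors[i],
                "stroke_side": locs[i],
                "sex": sexes[i],
            })
            sid += 1
    return pd.DataFrame(rows)


@dataclass
class CohortSpec:
    """Feature cohort layout.

    ``preset="table1"`` reproduces the study composition; otherwise
    ``class_counts`` gives explicit per-consciousness-state counts. Each
    clinical attribute shifts its own block of ``n_informative`` features
    by ``effect_size / sqrt(n_informative)`` per feature, so the
    between-class Mahalanobis separation per attribute is ~2x
    ``effect_size`` for lateralized contrasts.
    """

    preset: str | None = "table1"
    class_counts: dict[str, int] | None = None
    n_features: int = 190
    n_informative: int = 20
    effect_size: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset is None and not self.class_counts:
            raise ValueError("give a preset or explicit class counts")
        if 5 * self.n_informative > self.n_features:
            raise ValueError("need n_features >= 5 * n_informative")


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (features, labels) tables for a synthetic cohort.

    Features are standard normal with additive block shifts per clinical
    attribute (consciousness, motor side, stroke side), making every
    classification task learnable at the configured effect size.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.preset == "table1":
        labels = table1_labels(spec.seed)
    elif spec.preset is None:
        rows = []
        sid = 0
        for state, n in spec.class_counts.items():
            if n < 1:
                raise ValueError("class counts must be >= 1")
            for _ in range(n):
                rows.append({"subject_id": f"S{sid:03d}",
                             "consciousness": state,
                             "motor_side": "none", "stroke_side": "none",
                             "sex": "F"})
                sid += 1
        labels = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown preset {spec.preset!r}")

    n_subj = len(labels)
    X = rng.standard_normal((n_subj, spec.n_features))
    d = spec.effect_size / np.sqrt(spec.n_informative)
    blocks = [slice(b * spec.n_informative, (b + 1) * spec.n_informative)
              for b in range(5)]
    doc = labels["consciousness"].ne("awake").to_numpy()
    X[doc, blocks[0]] += d
    for col, lr_block, b_block in (("motor_side", 1, 2), ("stroke_side", 3, 4)):
        side = labels[col].to_numpy()
        X[side == "L", blocks[lr_block]] += d
        X[side == "R", blocks[lr_block]] -= d
        X[side == "B", blocks[b_block]] += d
    feat_cols = [f"f{i:03d}" for i in range(spec.n_features)]
    features = pd.DataFrame(X, columns=feat_cols)
    features.insert(0, "subject_id", labels["subject_id"].to_numpy())
    return features, labels


def gen_imbalanced_gaussians(
    n_minority: int,
    n_majority: int,
    n_features: int = 10,
    separation: float = 2.0,
    seed: int = 0,
) -> Dataset:
    """Two isotropic Gaussians at the given Mahalanobis separation.

    The minority class (label 1) mean sits ``separation`` away from the
    majority mean along a random unit direction.
    """
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    X_maj = rng.standard_normal((n_majority, n_features))
    X_min = rng.standard_normal((n_minority, n_features)) + separation * direction
    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(n_majority, int), np.ones(n_minority, int)])
    perm = rng.permutation(len(y))
    return Dataset(X[perm], y[perm])


# ---------------------------------------------------------------------------
# YAML spec loading

_SPEC_KINDS = {
    "oscillators": OscillatorSpec,
    "mvar": MVARSpec,
    "microstates": MicrostateSpec,
    "cohort": CohortSpec,
}


def spec_from_yaml(path: str):
    """Load a generator spec from YAML; the ``kind`` key selects the type."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kind = payload.pop("kind", None)
    if kind not in _SPEC_KINDS:
        raise ValueError(f"unknown or missing spec kind {kind!r}")
    for key in ("coeffs", "noise_cov", "templates"):
        if key in payload and payload[key] is not None:
            payload[key] = np.asarray(payload[key], dtype=float)
    if "coupling" in payload and payload["coupling"] is not None:
        payload["coupling"] = [tuple(c) for c in payload["coupling"]]
    return _SPEC_KINDS[kind](**payload)
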