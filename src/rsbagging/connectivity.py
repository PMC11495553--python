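"""Functional and effective EEG connectivity measures.

Eleven pairwise measures over a 1-45 Hz grid, all derived from one of two
substrates:

* per-epoch Hann-tapered Fourier coefficients (cross-spectral observations)
  for the nonparametric measures — coherence (COH), phase-locking value
  (PLV), phase lag index family (PLI, wPLI, debiased wPLI), pairwise phase
  consistency (PPC, weighted PPC), cross-spectral density magnitude (CSD)
  and orthogonalized power-envelope correlation (POWCORR);
* a multivariate autoregressive (MVAR) model for the directed measures —
  spectral Granger causality (GC), directed transfer function (DTF) and
  partial directed coherence (PDC).

Per-frequency matrices are averaged over the band and vectorized to the
upper triangle, giving 190 features for a 20-channel montage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .eeg_io import EpochedRecording

__all__ = [
    "SpectralObservations",
    "MVARModel",
    "ConnectivityStack",
    "FeatureVector",
    "PHASE_MEASURES",
    "AMPLITUDE_MEASURES",
    "DIRECTED_MEASURES",
    "ALL_MEASURES",
    "MEASURE_RANGES",
    "compute_spectra",
    "phase_measure",
    "amplitude_measure",
    "fit_mvar",
    "directed_measure",
    "band_average_and_vectorize",
    "connectivity_features",
]

PHASE_MEASURES = ("COH", "PLV", "PLI", "wPLI", "wPLI_de", "PPC", "wPPC")
AMPLITUDE_MEASURES = ("CSD", "POWCORR")
DIRECTED_MEASURES = ("GC", "DTF", "PDC")
ALL_MEASURES = PHASE_MEASURES + AMPLITUDE_MEASURES + DIRECTED_MEASURES

#: documented value range per measure (GC is unbounded above)
MEASURE_RANGES: dict[str, tuple[float, float]] = {
    "COH": (0.0, 1.0), "PLV": (0.0, 1.0), "PLI": (0.0, 1.0),
    "wPLI": (0.0, 1.0), "wPLI_de": (-1.0, 1.0), "PPC": (-1.0, 1.0),
    "wPPC": (-1.0, 1.0), "POWCORR": (-1.0, 1.0), "DTF": (0.0, 1.0),
    "PDC": (0.0, 1.0), "GC": (0.0, np.inf), "CSD": (0.0, np.inf),
}


# ---------------------------------------------------------------------------
# Spectral substrate


@dataclass
class SpectralObservations:
    """Per-observation spectral coefficients on a fixed frequency grid.

    ``coeffs[k, f, c]`` is the tapered Fourier coefficient of channel ``c``
    in observation (epoch) ``k`` at ``freqs[f]``. The cross-spectral tensor
    ``obs[k, f, i, j] = X_i X_j*`` is derived on demand; for pairwise work
    use :meth:`cross_spectrum`, which avoids materializing it.
    """

    coeffs: np.ndarray  # complex (n_obs, n_freq, n_channels)
    freqs: np.ndarray
    taper_info: str = "hann"
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (n_obs, n_freq, n_channels)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    @property
    def obs(self) -> np.ndarray:
        """Full cross-spectral tensor (n_obs, n_freq, n_ch, n_ch); Hermitian
        slices with real nonnegative diagonal. Memory scales with n_ch**2."""
        return np.einsum("kfi,kfj->kfij", self.coeffs, self.coeffs.conj())

    def cross_spectrum(self, i: int, j: int) -> np.ndarray:
        """Per-observation cross-spectrum S_ij (n_obs, n_freq), complex."""
        return self.coeffs[:, :, i] * self.coeffs[:, :, j].conj()


def compute_spectra(
    ep: EpochedRecording,
    f_lo: float = 1.0,
    f_hi: float = 45.0,
    taper: str = "hann",
) -> SpectralObservations:
    """Per-epoch tapered Fourier coefficients on an integer-Hz grid.

    Each epoch yields one cross-spectral observation. The grid covers the
    integer frequencies in ``[f_lo, f_hi]`` that the epoch length resolves
    (2 s epochs give 0.5 Hz native resolution; the 1 Hz grid subsamples it).
    """
    if ep.n_epochs < 2:
        raise ValueError("need at least 2 epochs for spectral observations")
    n = ep.epochs.shape[2]
    if f_lo < 1.0 / ep.epoch_length_s:
        raise ValueError("f_lo below the epoch frequency resolution")
    if f_hi >= ep.fs / 2:
        raise ValueError("f_hi must be below the Nyquist frequency")
    if taper == "hann":
        win = np.hanning(n)
    elif taper in ("boxcar", "none"):
        win = np.ones(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    grid = np.arange(int(np.ceil(f_lo)), int(np.floor(f_hi)) + 1, dtype=float)
    native = np.fft.rfftfreq(n, d=1.0 / ep.fs)
    bin_idx = np.array([int(round(f * n / ep.fs)) for f in grid])
    if not np.allclose(native[bin_idx], grid, atol=1e-9):
        raise ValueError("integer-Hz grid not resolvable at this epoch length")
    fft = np.fft.rfft(ep.epochs * win[None, None, :], axis=2)
    scale = np.sqrt(2.0 / (ep.fs * np.sum(win**2)))
    coeffs = np.transpose(fft[:, :, bin_idx], (0, 2, 1)) * scale
    return SpectralObservations(
        coeffs, grid, taper, list(ep.channel_labels), ep.subject_id
    )


# ---------------------------------------------------------------------------
# Connectivity containers


@dataclass
class ConnectivityStack:
    """Per-frequency connectivity matrices for one measure.

    ``values[f, i, j]``: for undirected measures a symmetric matrix; for
    directed measures the influence of source channel ``j`` on target
    channel ``i``.
    """

    measure: str
    values: np.ndarray  # (n_freq, n_ch, n_ch) real
    freqs: np.ndarray
    directed: bool
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (n_freq, n_ch, n_ch)")


@dataclass
class FeatureVector:
    """Vectorized connectivity (or microstate) features with provenance."""

    values: np.ndarray
    feature_names: list[str]
    measure: str
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names must align")


# ---------------------------------------------------------------------------
# Nonparametric measures

_EPS = np.finfo(float).tiny


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with the 0/0 -> 0 convention."""
    out = np.zeros(np.broadcast_shapes(np.shape(num), np.shape(den)))
    np.divide(num, den, out=out, where=np.asarray(den) != 0)
    return out


def _pair_phase(measure: str, s12: np.ndarray, p1: np.ndarray,
                p2: np.ndarray) -> np.ndarray:
    """One phase measure for one channel pair, vectorized over frequency.

    s12: (n_obs, n_freq) complex cross-spectra; p1, p2: (n_obs, n_freq)
    real auto-spectra.
    """
    n = s12.shape[0]
    if measure in ("PLI", "wPLI", "wPLI_de"):
        # imaginary parts at rounding level of |S12| are exactly zero by the
        # real-cross-spectrum convention
        im = s12.imag.copy()
        im[np.abs(im) <= 1e-12 * np.abs(s12)] = 0.0
        s12 = s12.real + 1j * im
    if measure == "COH":
        num = np.abs(s12.mean(axis=0)) ** 2
        return _safe_div(num, p1.mean(axis=0) * p2.mean(axis=0))
    if measure == "PLV":
        mag = np.abs(s12)
        unit = np.where(mag > 0, s12 / np.where(mag > 0, mag, 1.0), 0.0)
        return np.abs(unit.mean(axis=0))
    if measure == "PLI":
        return np.abs(np.sign(s12.imag).mean(axis=0))
    if measure == "wPLI":
        return _safe_div(np.abs(s12.imag.mean(axis=0)),
                         np.abs(s12.imag).mean(axis=0))
    if measure == "wPLI_de":
        im = s12.imag
        num = im.sum(axis=0) ** 2 - (im**2).sum(axis=0)
        den = np.abs(im).sum(axis=0) ** 2 - (im**2).sum(axis=0)
        return _safe_div(num, den)
    if measure == "PPC":
        mag = np.abs(s12)
        unit = np.where(mag > 0, s12 / np.where(mag > 0, mag, 1.0), 0.0)
        r2 = np.abs(unit.sum(axis=0)) ** 2
        return (r2 - n) / (n * (n - 1))
    if measure == "wPPC":
        num = np.abs(s12.sum(axis=0)) ** 2 - (np.abs(s12) ** 2).sum(axis=0)
        den = np.abs(s12).sum(axis=0) ** 2 - (np.abs(s12) ** 2).sum(axis=0)
        return _safe_div(num, den)
    raise ValueError(f"unknown phase measure {measure!r}")


def phase_measure(S: SpectralObservations, measure: str) -> ConnectivityStack:
    """Phase-synchronization measure per channel pair and frequency.

    COH follows the magnitude-squared coherence definition
    ``|<S12>|^2 / (<S11><S22>)``; PLV is the resultant length of the
    per-observation cross-spectral phases; the PLI family uses only the sign
    or magnitude of ``Im S12``; PPC/wPPC are the bias-corrected pairwise
    consistency statistics. All 0/0 cases follow the -> 0 convention.
    """
    if measure not in PHASE_MEASURES:
        raise ValueError(f"unknown phase measure {measure!r}")
    if S.n_obs < 2:
        raise ValueError("need at least 2 observations")
    nch, nfreq = S.n_channels, len(S.freqs)
    power = np.abs(S.coeffs) ** 2  # (n_obs, n_freq, n_ch)
    out = np.zeros((nfreq, nch, nch))
    for i in range(nch):
        for j in range(i, nch):
            s12 = S.coeffs[:, :, i] * S.coeffs[:, :, j].conj()
            v = _pair_phase(measure, s12, power[:, :, i], power[:, :, j])
            out[:, i, j] = v
            out[:, j, i] = v
    return ConnectivityStack(measure, out, S.freqs, False,
                             list(S.channel_labels), S.subject_id)


def _orthogonalized_logpower_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation of log power envelopes after orthogonalizing y on x.

    x, y: complex (n_obs,) coefficients at one frequency. The component of
    y orthogonal to x is Im(y conj(x) / |x|); its power envelope across
    observations is correlated with the power envelope of x.
    """
    ax = np.abs(x)
    y_orth = np.where(ax > 0, (y * x.conj()).imag / np.where(ax > 0, ax, 1.0), 0.0)
    px = np.log(ax**2 + _EPS)
    py = np.log(y_orth**2 + _EPS)
    if px.std() == 0 or py.std() == 0:
        return 0.0
    return float(np.corrcoef(px, py)[0, 1])


def amplitude_measure(S: SpectralObservations, measure: str) -> ConnectivityStack:
    """Amplitude-based measures per frequency.

    CSD is the magnitude of the observation-averaged cross-spectrum.
    POWCORR correlates log-power envelopes after pairwise orthogonalization
    (each signal's coefficient made orthogonal to the other), symmetrized
    over the two directions; shared zero-lag signal is thereby removed.
    """
    if measure not in AMPLITUDE_MEASURES:
        raise ValueError(f"unknown amplitude measure {measure!r}")
    if S.n_obs < 2:
        raise ValueError("need at least 2 observations")
    nch, nfreq = S.n_channels, len(S.freqs)
    out = np.zeros((nfreq, nch, nch))
    if measure == "CSD":
        for i in range(nch):
            for j in range(i, nch):
                s12 = S.coeffs[:, :, i] * S.coeffs[:, :, j].conj()
                v = np.abs(s12.mean(axis=0))
                out[:, i, j] = v
                out[:, j, i] = v
        return ConnectivityStack(measure, out, S.freqs, False,
                                 list(S.channel_labels), S.subject_id)
    warned = False
    for f in range(nfreq):
        for i in range(nch):
            for j in range(i + 1, nch):
                x = S.coeffs[:, f, i]
                y = S.coeffs[:, f, j]
                r1 = _orthogonalized_logpower_corr(x, y)
                r2 = _orthogonalized_logpower_corr(y, x)
                if (x.std() == 0 or y.std() == 0) and not warned:
                    warnings.warn("zero-variance envelope; POWCORR entry set to 0")
                    warned = True
                v = 0.5 * (r1 + r2)
                out[f, i, j] = v
                out[f, j, i] = v
    return ConnectivityStack(measure, out, S.freqs, False,
                             list(S.channel_labels), S.subject_id)


# ---------------------------------------------------------------------------
# MVAR substrate and directed measures


@dataclass
class MVARModel:
    """Stable multivariate autoregressive model y_t = sum_k A_k y_{t-k} + e_t."""

    coeffs: np.ndarray  # (p, n_ch, n_ch)
    noise_cov: np.ndarray  # (n_ch, n_ch) symmetric positive definite
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (p, n_ch, n_ch)")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")
        if self.spectral_radius() >= 1.0:
            raise ValueError(
                "unstable MVAR model (companion spectral radius >= 1); "
                "consider a lower order"
            )

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        p, n = self.order, self.n_channels
        comp = np.zeros((n * p, n * p))
        comp[:n] = self.coeffs.transpose(1, 0, 2).reshape(n, n * p)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def fourier_coeff_matrix(self, freqs: np.ndarray) -> np.ndarray:
        """A(f) = I - sum_k A_k exp(-2*pi*i*f*k/fs), shape (n_freq, n, n)."""
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        k = np.arange(1, self.order + 1)
        phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / self.fs)
        af = np.eye(self.n_channels)[None] - np.einsum(
            "fk,kij->fij", phase, self.coeffs.astype(complex)
        )
        return af

    def transfer(self, freqs: np.ndarray) -> np.ndarray:
        """Spectral transfer matrix H(f) = A(f)^-1, shape (n_freq, n, n)."""
        af = self.fourier_coeff_matrix(freqs)
        out = np.empty_like(af)
        for fi, a in enumerate(af):
            try:
                out[fi] = np.linalg.inv(a)
            except np.linalg.LinAlgError as err:
                f = np.atleast_1d(freqs)[fi]
                raise np.linalg.LinAlgError(
                    f"singular coefficient matrix A(f) at {f} Hz"
                ) from err
        return out

    def spectral_matrix(self, freqs: np.ndarray) -> np.ndarray:
        """Model-implied cross-spectral matrix S(f) = H Sigma H*."""
        h = self.transfer(freqs)
        return np.einsum("fij,jk,flk->fil", h, self.noise_cov, h.conj())


def _lagged_moments(ep: EpochedRecording, p: int) -> tuple[np.ndarray, int]:
    """Accumulate sum_t w_t w_t' with w_t = [y_t; y_{t-1}; ...; y_{t-p}].

    Pooled across epochs (no samples cross an epoch boundary). Returns the
    ((p+1)n x (p+1)n) moment matrix and the number of contributing samples.
    """
    n_ep, n_ch, n_len = ep.epochs.shape
    if n_len <= p:
        raise ValueError("epochs shorter than the model order")
    dim = (p + 1) * n_ch
    g = np.zeros((dim, dim))
    n_eff = 0
    for e in range(n_ep):
        x = ep.epochs[e]
        w = np.concatenate(
            [x[:, p - k: n_len - k] for k in range(p + 1)], axis=0
        )  # (dim, n_len - p)
        g += w @ w.T
        n_eff += n_len - p
    return g, n_eff


def _fit_from_moments(g: np.ndarray, n_eff: int, p: int,
                      n_ch: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares MVAR coefficients and noise covariance from moments."""
    t = slice(0, n_ch)
    z = slice(n_ch, (p + 1) * n_ch)
    gzz = g[z, z]
    gtz = g[t, z]
    b = np.linalg.solve(gzz + 1e-12 * np.eye(gzz.shape[0]), gtz.T).T
    sigma = (g[t, t] - b @ gtz.T) / n_eff
    sigma = 0.5 * (sigma + sigma.T)
    coeffs = b.reshape(n_ch, p, n_ch).transpose(1, 0, 2)
    return coeffs, sigma


def fit_mvar(
    ep: EpochedRecording,
    order: int | str = "auto",
    max_order: int = 20,
) -> MVARModel:
    """Least-squares MVAR fit pooled across epochs.

    With ``order="auto"`` the order minimizing AIC over 1..max_order is
    chosen. Raises if the requested order exceeds the sample support
    (fewer than ``10 * p * n_channels`` samples) or the fit is unstable.
    """
    n_ep, n_ch, n_len = ep.epochs.shape
    total = n_ep * n_len

    def _support_ok(p: int) -> bool:
        return total > 10 * p * n_ch and n_len > p

    if order == "auto":
        candidates = [p for p in range(1, max_order + 1) if _support_ok(p)]
        if not candidates:
            raise ValueError("too few samples to fit even order 1")
        p_max = candidates[-1]
        g, _ = _lagged_moments(ep, p_max)
        best = None
        for p in candidates:
            sub = _submoments(g, p_max, p, n_ch)
            n_eff = n_ep * (n_len - p_max)  # common support for comparison
            _, sigma = _fit_from_moments(sub, n_eff, p, n_ch)
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                continue
            aic = n_eff * logdet + 2 * p * n_ch**2
            if best is None or aic < best[0]:
                best = (aic, p)
        if best is None:
            raise ValueError("AIC order selection failed (degenerate covariance)")
        order = best[1]
    else:
        order = int(order)
        if order < 1:
            raise ValueError("order must be >= 1")
        if not _support_ok(order):
            raise ValueError(
                f"order {order} exceeds sample support "
                f"(need > {10 * order * n_ch} samples, have {total})"
            )

    g, n_eff = _lagged_moments(ep, order)
    coeffs, sigma = _fit_from_moments(g, n_eff, order, n_ch)
    return MVARModel(coeffs, sigma, ep.fs, list(ep.channel_labels))


def _submoments(g: np.ndarray, p_full: int, p: int, n_ch: int) -> np.ndarray:
    """Restrict a moment matrix built at lag p_full to lags 0..p."""
    keep = np.arange((p + 1) * n_ch)
    return g[np.ix_(keep, keep)]


def _gc_matrix(h: np.ndarray, s: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Pairwise spectral Granger causality from full-model quantities.

    Entry (i, j): influence of source j on target i,
    ln( S_ii / (S_ii - (Sigma_jj - Sigma_ij^2 / Sigma_ii) |H_ij|^2) ).
    """
    n = sigma.shape[0]
    s_ii = np.maximum(np.real(np.diagonal(s, axis1=-2, axis2=-1)), _EPS)
    out = np.zeros(h.shape[:-2] + (n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            corr = sigma[j, j] - sigma[i, j] ** 2 / max(sigma[i, i], _EPS)
            term = corr * np.abs(h[..., i, j]) ** 2
            denom = np.maximum(s_ii[..., i] - term, _EPS)
            out[..., i, j] = np.maximum(np.log(s_ii[..., i] / denom), 0.0)
    return out


def directed_measure(
    model: MVARModel,
    measure: str,
    freqs: np.ndarray,
) -> ConnectivityStack:
    """Directed spectral measures from a fitted MVAR model.

    ``values[f, i, j]`` quantifies the influence of channel ``j`` on
    channel ``i`` at ``freqs[f]``:

    * DTF: ``|H_ij|^2 / sum_m |H_im|^2`` (row-normalized transfer matrix);
    * PDC: ``|A_ij|^2 / sum_m |A_mj|^2`` (column-normalized A(f));
    * GC: bivariate-form spectral Granger causality with the noise
      covariance correction, applied to each ordered pair.
    """
    if measure not in DIRECTED_MEASURES:
        raise ValueError(f"unknown directed measure {measure!r}")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if measure == "PDC":
        af = model.fourier_coeff_matrix(freqs)
        num = np.abs(af) ** 2
        den = num.sum(axis=1, keepdims=True)  # column sums over targets m
        vals = _safe_div(num, den)
    elif measure == "DTF":
        h = model.transfer(freqs)
        num = np.abs(h) ** 2
        den = num.sum(axis=2, keepdims=True)  # row sums over sources m
        vals = _safe_div(num, den)
    else:  # GC
        h = model.transfer(freqs)
        s = np.einsum("fij,jk,flk->fil", h, model.noise_cov, h.conj())
        vals = _gc_matrix(h, s, model.noise_cov)
    return ConnectivityStack(measure, vals, freqs, True,
                             list(model.channel_labels))


# ---------------------------------------------------------------------------
# Band averaging and vectorization


def band_average_and_vectorize(
    stack: ConnectivityStack,
    band: tuple[float, float] = (1.0, 45.0),
    full_directed: bool = False,
) -> FeatureVector:
    """Average matrices over the band and vectorize to channel-pair features.

    The default keeps the upper triangle (i < j in montage order), giving
    n(n-1)/2 features — 190 for 20 channels — for directed measures too.
    ``full_directed=True`` instead emits all n(n-1) ordered pairs of a
    directed measure.
    """
    lo, hi = band
    mask = (stack.freqs >= lo) & (stack.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    mat = stack.values[mask].mean(axis=0)
    n = mat.shape[0]
    labels = stack.channel_labels or [f"ch{i}" for i in range(n)]
    names: list[str] = []
    vals: list[float] = []
    if full_directed and stack.directed:
        for i in range(n):
            for j in range(n):
                if i != j:
                    names.append(f"{stack.measure}_{labels[j]}->{labels[i]}")
                    vals.append(mat[i, j])
    else:
        for i in range(n):
            for j in range(i + 1, n):
                names.append(f"{stack.measure}_{labels[i]}-{labels[j]}")
                vals.append(mat[i, j])
    return FeatureVector(np.array(vals), names, stack.measure, stack.subject_id)


def _pairwise_gc_stack(ep: EpochedRecording, freqs: np.ndarray,
                       order: int | str) -> ConnectivityStack:
    """GC from a separate bivariate MVAR model per channel pair."""
    n_ch = ep.epochs.shape[1]
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    out = np.zeros((len(freqs), n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            sub = EpochedRecording(
                ep.epochs[:, [i, j], :], ep.epoch_length_s,
                ep.overlap_fraction, ep.fs,
                [f"ch{i}", f"ch{j}"], ep.subject_id,
            )
            model = fit_mvar(sub, order=order)
            gc = directed_measure(model, "GC", freqs).values
            out[:, i, j] = gc[:, 0, 1]  # j -> i in pair coords: (x=j) -> (y=i)
            out[:, j, i] = gc[:, 1, 0]
    return ConnectivityStack("GC", out, freqs, True,
                             list(ep.channel_labels), ep.subject_id)


def connectivity_features(
    ep: EpochedRecording,
    measure: str,
    band: tuple[float, float] = (1.0, 45.0),
    order: int | str = "auto",
    full_directed: bool = False,
) -> FeatureVector:
    """End-to-end connectivity features for one measure on one recording.

    Nonparametric measures share the per-epoch Hann spectral observations;
    DTF/PDC come from one pooled MVAR model; GC is fitted bivariately per
    channel pair, matching its two-signal definition.
    """
    if measure in PHASE_MEASURES or measure in AMPLITUDE_MEASURES:
        spec = compute_spectra(ep, band[0], band[1])
        if measure in PHASE_MEASURES:
            stack = phase_measure(spec, measure)
        else:
            stack = amplitude_measure(spec, measure)
    elif measure in ("DTF", "PDC"):
        model = fit_mvar(ep, order=order)
        grid = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1)
        stack = directed_measure(model, measure, grid)
        stack.subject_id = ep.subject_id
    elif measure == "GC":
        grid = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1)
        stack = _pairwise_gc_stack(ep, grid, order)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return band_average_and_vectorize(stack, band, full_directed=full_directed)
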