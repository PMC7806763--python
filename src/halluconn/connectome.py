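"""Weighted functional connectomes from wavelet-scale band coherence.

Each regional signal is passed through a maximal overlap discrete wavelet
transform (MODWT) and the level-j detail coefficient series retained; the
default level 4 isolates [fs/32, fs/16] Hz, i.e. 0.05-0.10 Hz at the default
1.6 Hz sampling rate.  Edge weights are Welch magnitude-squared coherence
between coefficient series, averaged over the in-band frequency bins, giving
one symmetric N x N matrix per subject with weights in [0, 1].

The MODWT here is the non-decimated, shift-invariant pyramid transform with
filters rescaled by 1/sqrt(2) per level (so the per-scale coefficient
variances sum to the signal variance), computed by circular convolution with
upsampled filters; the "reflection" boundary extends the series with its
time-reverse before the circular transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortTimeSeries

#: The least-asymmetric length-8 wavelet (LA(8)), the common MODWT default.
DEFAULT_WAVELET = "sym4"


@dataclass(frozen=True)
class WaveletConfig:
    level: int = 4
    wavelet: str = DEFAULT_WAVELET
    boundary: str = "reflection"  # or "periodic"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.boundary not in ("reflection", "periodic"):
            raise ValueError("boundary must be 'reflection' or 'periodic'")

    def band(self, fs: float) -> tuple[float, float]:
        """Frequency band [fs/2^(j+1), fs/2^j] isolated by the detail level."""
        return fs / 2 ** (self.level + 1), fs / 2**self.level


@dataclass
class ConnectivityMatrix:
    """Symmetric coherence weights for one subject, zero diagonal, in [0,1]."""

    weights: np.ndarray
    subject_id: str
    band: tuple[float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < -1e-10 or w.max() > 1 + 1e-10:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    return (np.asarray(w.dec_lo) / np.sqrt(2), np.asarray(w.dec_hi) / np.sqrt(2))


def modwt_details(x: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> tuple[np.ndarray, np.ndarray]:
    """All detail series up to ``cfg.level`` plus the final smooth.

    Parameters
    ----------
    x : array, shape (..., n_timepoints)

    Returns
    -------
    details : array, shape (level, ..., n_timepoints)
    smooth : array, shape (..., n_timepoints)
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n0 = x.shape[-1]
    if n0 < 2 ** (cfg.level + 1):
        raise ValueError(f"signal length {n0} too short for level {cfg.level} (need >= {2 ** (cfg.level + 1)})")
    g, h = _modwt_filters(cfg.wavelet)
    if cfg.boundary == "reflection":
        x = np.concatenate([x, x[..., ::-1]], axis=-1)
    n = x.shape[-1]
    if (len(g) - 1) * 2 ** (cfg.level - 1) + 1 > n:
        raise ValueError("signal too short for the upsampled filter at this level")

    Vf = np.fft.rfft(x, axis=-1)
    details = []
    taps = np.arange(len(g))
    for j in range(1, cfg.level + 1):
        pos = (taps * 2 ** (j - 1)) % n
        gj = np.zeros(n)
        hj = np.zeros(n)
        np.add.at(gj, pos, g)
        np.add.at(hj, pos, h)
        Hf = np.fft.rfft(hj)
        Gf = np.fft.rfft(gj)
        details.append(np.fft.irfft(Vf * Hf, n=n, axis=-1))
        Vf = Vf * Gf
    smooth = np.fft.irfft(Vf, n=n, axis=-1)
    details = np.stack(details, axis=0)
    return details[..., :n0], smooth[..., :n0]


def modwt_filter(signal: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Level-``cfg.level`` MODWT detail coefficient series (same length as input)."""
    details, _ = modwt_details(signal, cfg)
    return details[-1]


def _welch_params(n_timepoints: int, nperseg: int | None) -> int:
    if nperseg is not None:
        return int(nperseg)
    # default: timepoints/8 rounded down to a power of two, at least 16
    return max(16, 2 ** int(np.log2(max(n_timepoints // 8, 16))))


def pairwise_band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    nperseg: int | None = None,
    noverlap: int | None = None,
    window: str = "hann",
) -> float:
    """Welch magnitude-squared coherence between two series, averaged in-band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: coherence undefined")
    nperseg = _welch_params(len(x), nperseg)
    if noverlap is None:
        noverlap = nperseg // 2
    if (len(x) - noverlap) // (nperseg - noverlap) < 2:
        raise ValueError("need at least 2 Welch segments")
    f, cxy = sps.coherence(x, y, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    sel = (f >= band[0] - 1e-12) & (f <= band[1] + 1e-12)
    if not np.any(sel):
        raise ValueError(f"no frequency bins inside band {band}")
    return float(np.mean(cxy[sel]))


def _coherence_matrix(
    coeffs: np.ndarray,
    fs: float,
    band: tuple[float, float],
    nperseg: int,
    noverlap: int,
    window: str,
) -> np.ndarray:
    """All-pairs in-band MSC from (n_nodes, T) coefficient series.

    Computes each node's windowed segment FFTs once and forms the full
    cross-spectral array by einsum; identical (to rounding) to calling
    :func:`pairwise_band_coherence` on every pair.
    """
    n_nodes, T = coeffs.shape
    win = sps.get_window(window, nperseg)
    step = nperseg - noverlap
    nseg = (T - noverlap) // step
    idx = step * np.arange(nseg)[:, None] + np.arange(nperseg)
    segs = coeffs[:, idx]  # (nodes, nseg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    F = np.fft.rfft(win * segs, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    sel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    if not np.any(sel):
        raise ValueError(f"no frequency bins inside band {band}")
    F = F[..., sel]
    Sxy = np.einsum("isf,jsf->ijf", F, F.conj()) / nseg
    Pxx = np.einsum("isf,isf->if", F, F.conj()).real / nseg
    denom = Pxx[:, None, :] * Pxx[None, :, :]
    coh = np.abs(Sxy) ** 2 / denom
    out = coh.mean(axis=-1).real
    np.fill_diagonal(out, 0.0)
    return np.clip((out + out.T) / 2, 0.0, 1.0)


class WaveletCoherence(BaseEstimator, TransformerMixin):
    """Transformer: cohort time series -> per-subject coherence matrices.

    Parameters
    ----------
    level : int
        MODWT detail level analyzed (default 4).
    wavelet : str
        PyWavelets filter name; default the least-asymmetric length-8.
    boundary : {"reflection", "periodic"}
    nperseg, noverlap, window :
        Welch estimator settings; defaults are segment length timepoints/8
        (power of two), 50% overlap, Hann window.
    band : tuple or None
        Averaging band in Hz; ``None`` derives it from the wavelet scale.
    """

    def __init__(
        self,
        level: int = 4,
        wavelet: str = DEFAULT_WAVELET,
        boundary: str = "reflection",
        nperseg: int | None = None,
        noverlap: int | None = None,
        window: str = "hann",
        band: tuple[float, float] | None = None,
    ):
        self.level = level
        self.wavelet = wavelet
        self.boundary = boundary
        self.nperseg = nperseg
        self.noverlap = noverlap
        self.window = window
        self.band = band

    def fit(self, X: CohortTimeSeries, y=None):
        if not isinstance(X, CohortTimeSeries):
            raise TypeError("X must be a CohortTimeSeries")
        self.n_nodes_ = X.n_nodes
        return self

    def transform(self, X: CohortTimeSeries) -> np.ndarray:
        """Return stacked weights, shape (n_subjects, n_nodes, n_nodes)."""
        if not isinstance(X, CohortTimeSeries):
            raise TypeError("X must be a CohortTimeSeries")
        cfg = WaveletConfig(self.level, self.wavelet, self.boundary)
        fs = X.fs
        band = self.band if self.band is not None else cfg.band(fs)
        nperseg = _welch_params(X.n_timepoints, self.nperseg)
        noverlap = self.noverlap if self.noverlap is not None else nperseg // 2
        sd = X.data.std(axis=-1)
        if np.any(sd == 0):
            s, n = np.argwhere(sd == 0)[0]
            raise ValueError(
                f"zero-variance signal for subject {X.subject_ids[s]!r}, node {n}: coherence undefined"
            )
        out = np.empty((X.n_subjects, X.n_nodes, X.n_nodes))
        for s in range(X.n_subjects):
            coeffs = modwt_filter(X.data[s], cfg)
            out[s] = _coherence_matrix(coeffs, fs, band, nperseg, noverlap, self.window)
        return out


def build_connectomes(
    cohort: CohortTimeSeries,
    cfg: WaveletConfig = WaveletConfig(),
    nperseg: int | None = None,
    noverlap: int | None = None,
    window: str = "hann",
    band: tuple[float, float] | None = None,
) -> list[ConnectivityMatrix]:
    """One :class:`ConnectivityMatrix` per subject (MODWT then band coherence)."""
    tr = WaveletCoherence(cfg.level, cfg.wavelet, cfg.boundary, nperseg, noverlap, window, band)
    weights = tr.fit(cohort).transform(cohort)
    b = band if band is not None else cfg.band(cohort.fs)
    return [
        ConnectivityMatrix(weights[s], cohort.subject_ids[s], b)
        for s in range(cohort.n_subjects)
    ]


def as_weight_stack(matrices) -> np.ndarray:
    """Coerce a list of ConnectivityMatrix (or an array) to (S, N, N) floats."""
    if isinstance(matrices, np.ndarray):
        return matrices if matrices.ndim == 3 else matrices[None]
    return np.stack([m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m) for m in matrices])
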