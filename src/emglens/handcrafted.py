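"""Handcrafted sEMG feature bank: 56 methods producing 79 scalar features.

Each method operates on a single channel of a single window and is tagged
with one of five functional groups:

- ``SAP``: signal amplitude and power
- ``FI``:  frequency information
- ``NLC``: non-linear complexity
- ``TSM``: time-series modeling
- ``UNI``: unique / other

Multi-output methods (AR, CC, DAR, DCC with order 4; HIST with 3 bins;
MHW/MTW with 3 sub-windows; TSPSD with 6 descriptors) are expanded into
separately named scalar features, e.g. ``AR1..AR4``.

All spectral quantities are computed from a one-sided rectangular-window
periodogram at resolution ``fs / N``; the 0 Hz bin is excluded from peak
and moment computations.  Logarithms and divisions are guarded with a
``1e-12`` floor so every feature is finite even on degenerate (e.g.
constant) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import WindowedDataset

__all__ = [
    "FeatureSpec",
    "FeatureRegistry",
    "FeatureTable",
    "build_registry",
    "compute_feature",
    "compute_all",
]

EPS = 1e-12

GROUPS = ("SAP", "FI", "NLC", "TSM", "UNI")


# ---------------------------------------------------------------------------
# helpers

def _safe_log(x: np.ndarray | float) -> np.ndarray | float:
    return np.log(np.maximum(np.abs(x), EPS))


def _safe_log10(x: np.ndarray | float) -> np.ndarray | float:
    return np.log10(np.maximum(np.abs(x), EPS))


# cache of the most recent periodogram; many features share the same input
_PGRAM_CACHE: dict = {"x": None, "fs": None, "out": None}


def periodogram(x: np.ndarray, fs: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram, no detrending."""
    if (_PGRAM_CACHE["fs"] == fs and _PGRAM_CACHE["x"] is not None
            and _PGRAM_CACHE["x"].shape == np.shape(x)
            and np.array_equal(_PGRAM_CACHE["x"], x)):
        return _PGRAM_CACHE["out"]
    f, p = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    _PGRAM_CACHE.update(x=np.array(x, copy=True), fs=fs, out=(f, p))
    return f, p


def _spectral_moments(x: np.ndarray, fs: float, orders: Sequence[int]) -> list[float]:
    f, p = periodogram(x, fs)
    f, p = f[1:], p[1:]  # drop DC
    return [float(np.sum(f ** k * p)) for k in orders]


# ---------------------------------------------------------------------------
# SAP: amplitude / power

def f_iemg(x, **kw):
    return np.sum(np.abs(x))


def f_mav(x, **kw):
    return np.mean(np.abs(x))


def f_mmav1(x, **kw):
    n = len(x)
    w = np.full(n, 0.5)
    i = np.arange(n)
    w[(i >= 0.25 * n) & (i <= 0.75 * n)] = 1.0
    return np.mean(w * np.abs(x))


def f_mmav2(x, **kw):
    n = len(x)
    i = np.arange(n, dtype=float)
    w = np.ones(n)
    lo = i < 0.25 * n
    hi = i > 0.75 * n
    w[lo] = 4 * i[lo] / n
    w[hi] = 4 * (n - i[hi]) / n
    return np.mean(w * np.abs(x))


def f_rms(x, **kw):
    return np.sqrt(np.mean(x ** 2))


def f_var(x, **kw):
    return np.sum(x ** 2) / (len(x) - 1)


def f_ssi(x, **kw):
    return np.sum(x ** 2)


def f_vorder(x, v: int = 2, **kw):
    return np.mean(np.abs(x) ** v) ** (1.0 / v)


def f_ld(x, **kw):
    return np.exp(np.mean(_safe_log(x)))


def f_max(x, **kw):
    return np.max(np.abs(x))


def f_wl(x, **kw):
    return np.sum(np.abs(np.diff(x)))


def f_tm(x, order: int = 3, **kw):
    return np.abs(np.mean(x ** order))


def f_m2(x, **kw):
    return np.sum(np.diff(x) ** 2)


def f_sm(x, fs: float = 1000.0, **kw):
    (m2,) = _spectral_moments(x, fs, [2])
    return m2


def f_mnp(x, fs: float = 1000.0, **kw):
    _, p = periodogram(x, fs)
    return np.mean(p[1:])


def f_ttp(x, fs: float = 1000.0, **kw):
    _, p = periodogram(x, fs)
    return np.sum(p[1:])


def _subwindow_energies(x: np.ndarray, window_fn: Callable[[int], np.ndarray],
                        k: int = 3) -> np.ndarray:
    """Energy of k half-overlapping windowed segments covering the signal."""
    n = len(x)
    L = n // 2
    starts = np.linspace(0, n - L, k).astype(int)
    w = window_fn(L)
    return np.array([np.sum((x[s:s + L] * w) ** 2) for s in starts])


def f_mhw(x, n_windows: int = 3, **kw):
    return _subwindow_energies(np.asarray(x), np.hamming, n_windows)


def _trapezoid_window(L: int) -> np.ndarray:
    ramp = max(1, L // 4)
    w = np.ones(L)
    w[:ramp] = np.linspace(0, 1, ramp, endpoint=False)
    w[L - ramp:] = np.linspace(1, 0, ramp, endpoint=False)[::-1]
    return w


def f_mtw(x, n_windows: int = 3, **kw):
    return _subwindow_energies(np.asarray(x), _trapezoid_window, n_windows)


def f_afb(x, ma_len: int = 32, **kw):
    """Amplitude of the first burst: first local peak of a moving-average
    of the rectified signal (falls back to the global maximum)."""
    a = np.abs(np.asarray(x, dtype=float))
    if len(a) < ma_len:
        return float(np.max(a))
    ma = np.convolve(a, np.ones(ma_len) / ma_len, mode="valid")
    for i in range(1, len(ma) - 1):
        if ma[i] > ma[i - 1] and ma[i] >= ma[i + 1]:
            return float(ma[i])
    return float(np.max(ma))


# difference-series variants: base formula applied to the first difference

def f_damv(x, **kw):
    return f_mav(np.diff(x))


def f_dasdv(x, **kw):
    return np.sqrt(np.mean(np.diff(x) ** 2))


def f_dld(x, **kw):
    return f_ld(np.diff(x))


def f_dtm(x, order: int = 3, **kw):
    return f_tm(np.diff(x), order=order)


def f_dvarv(x, **kw):
    return f_var(np.diff(x))


def f_dv(x, v: int = 2, **kw):
    return f_vorder(np.diff(x), v=v)


# ---------------------------------------------------------------------------
# FI: frequency information

def f_zc(x, threshold: float = 0.0, **kw):
    x = np.asarray(x)
    a, b = x[:-1], x[1:]
    return float(np.sum((a * b < 0) & (np.abs(a - b) >= threshold)))


def f_ssc(x, threshold: float = 0.0, **kw):
    x = np.asarray(x)
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return float(np.sum(d1 * d2 > threshold))


def f_mnf(x, fs: float = 1000.0, **kw):
    f, p = periodogram(x, fs)
    f, p = f[1:], p[1:]
    return float(np.sum(f * p) / max(np.sum(p), EPS))


def f_mdf(x, fs: float = 1000.0, **kw):
    f, p = periodogram(x, fs)
    f, p = f[1:], p[1:]
    total = np.sum(p)
    if total <= EPS:
        return 0.0
    cum = np.cumsum(p)
    return float(f[np.searchsorted(cum, total / 2.0)])


def f_fr(x, fs: float = 1000.0, split_hz: float = 250.0, low_hz: float = 20.0,
         high_hz: float = 500.0, **kw):
    f, p = periodogram(x, fs)
    num = np.sum(p[(f >= low_hz) & (f < split_hz)])
    den = np.sum(p[(f >= split_hz) & (f <= high_hz)])
    return float(num / max(den, EPS))


# ---------------------------------------------------------------------------
# NLC: non-linear complexity

def f_wamp(x, threshold: float = 50.0, **kw):
    return float(np.sum(np.abs(np.diff(x)) > threshold))


def _template_distances(x: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all length-m templates of x.

    Built incrementally from the sample-wise distance matrix:
    ``D_m[i, j] = max_{k < m} |x[i+k] - x[j+k]|``.
    """
    d0 = np.abs(x[:, None] - x[None, :])
    n = len(x) - m + 1
    d = d0[:n, :n].copy()
    for k in range(1, m):
        np.maximum(d, d0[k:k + n, k:k + n], out=d)
    return d


def f_sampen(x, m: int = 2, r_factor: float = 0.2, **kw):
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd <= EPS:
        return 0.0
    r = r_factor * sd
    # counts use templates of a common length so B >= A
    dm = _template_distances(x, m)[: len(x) - m, : len(x) - m]
    b = int(np.sum(dm <= r)) - (len(x) - m)  # drop self-matches
    dm1 = _template_distances(x, m + 1)
    a = int(np.sum(dm1 <= r)) - dm1.shape[0]
    if b == 0 or a == 0:
        return 0.0
    return float(-np.log(a / b))


def f_apen(x, m: int = 2, r_factor: float = 0.2, **kw):
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd <= EPS:
        return 0.0
    r = r_factor * sd

    def phi(mm: int) -> float:
        d = _template_distances(x, mm)
        c = np.sum(d <= r, axis=1) / d.shape[0]  # self-matches included
        return float(np.mean(np.log(np.maximum(c, EPS))))

    return phi(m) - phi(m + 1)


def _box_count_dimension(xs: np.ndarray, ys: np.ndarray) -> float:
    """Box-counting dimension of a curve given unit-square coordinates.

    Each curve segment is attributed to its starting x-column; because
    consecutive segments are connected, the occupied boxes of a column form
    one contiguous vertical run, so per-column counts are ``max - min + 1``
    over the segment endpoints in that column.
    """
    sizes = [2, 4, 8, 16, 32]
    counts = []
    for s in sizes:
        bx = np.clip((xs * s).astype(int), 0, s - 1)
        by = np.clip((ys * s).astype(int), 0, s - 1)
        col = bx[:-1]
        lo = np.minimum(by[:-1], by[1:])
        hi = np.maximum(by[:-1], by[1:])
        starts = np.flatnonzero(np.r_[True, col[1:] != col[:-1]])
        col_min = np.minimum.reduceat(lo, starts)
        col_max = np.maximum.reduceat(hi, starts)
        counts.append(int(np.sum(col_max - col_min + 1)))
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(slope)


def f_bc(x, **kw):
    x = np.asarray(x, dtype=float)
    rng = np.ptp(x)
    if rng <= EPS:
        return 1.0  # a flat line is one-dimensional
    ys = (x - np.min(x)) / rng
    xs = np.linspace(0.0, 1.0, len(x))
    return _box_count_dimension(xs, ys)


def f_katz(x, **kw):
    x = np.asarray(x, dtype=float)
    n = len(x) - 1
    steps = np.sqrt(1.0 + np.diff(x) ** 2)
    L = np.sum(steps)
    i = np.arange(1, len(x))
    d = np.max(np.sqrt(i ** 2 + (x[1:] - x[0]) ** 2))
    return float(np.log10(n) / (np.log10(n) + _safe_log10(d / max(L, EPS))))


def f_mfl(x, **kw):
    return float(_safe_log10(np.sqrt(np.sum(np.diff(x) ** 2))))


# ---------------------------------------------------------------------------
# TSM: time-series modeling

def ar_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Levinson-Durbin AR coefficients in predictor convention.

    Returns ``phi`` such that ``x_t ~= sum_k phi_k x_{t-k}``; on a long
    realization of ``x_t = 0.5 x_{t-1} + e_t`` the first entry is ~0.5.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(order + 1)])
    if r[0] <= EPS:
        return np.zeros(order)
    phi = np.zeros(order + 1)
    e = r[0]
    for k in range(1, order + 1):
        acc = r[k] - np.dot(phi[1:k], r[1:k][::-1])
        lam = acc / e
        phi[1:k] = phi[1:k] - lam * phi[1:k][::-1]
        phi[k] = lam
        e *= (1.0 - lam ** 2)
        if e <= EPS:
            break
    return phi[1:]


def cepstral_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Cepstral coefficients from the AR model via the standard recursion.

    With polynomial coefficients ``a_k = -phi_k``: ``c_1 = -a_1`` and
    ``c_n = -a_n - sum_{k=1}^{n-1} (1 - k/n) a_k c_{n-k}``.
    """
    a = -ar_coefficients(x, order)
    c = np.zeros(order)
    for n in range(1, order + 1):
        s = a[n - 1]
        for k in range(1, n):
            s += (1.0 - k / n) * a[k - 1] * c[n - k - 1]
        c[n - 1] = -s
    return c


def f_ar(x, order: int = 4, **kw):
    return ar_coefficients(np.asarray(x, dtype=float), order)


def f_cc(x, order: int = 4, **kw):
    return cepstral_coefficients(np.asarray(x, dtype=float), order)


def f_dar(x, order: int = 4, **kw):
    return ar_coefficients(np.diff(np.asarray(x, dtype=float)), order)


def f_dcc(x, order: int = 4, **kw):
    return cepstral_coefficients(np.diff(np.asarray(x, dtype=float)), order)


def f_dfa(x, **kw):
    """Detrended-fluctuation exponent; log-spaced scales 4 .. N/4."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - np.mean(x))
    n = len(x)
    scales = np.unique(np.geomspace(4, max(5, n // 4), 8).astype(int))
    flucts = []
    for s in scales:
        nseg = n // s
        if nseg < 1:
            continue
        segs = y[: nseg * s].reshape(nseg, s)
        t = np.arange(s)
        tm = t - t.mean()
        beta = segs @ tm / np.sum(tm ** 2)
        resid = segs - segs.mean(axis=1, keepdims=True) - beta[:, None] * tm
        flucts.append(np.sqrt(np.mean(resid ** 2)))
    flucts = np.maximum(np.asarray(flucts), EPS)
    if len(flucts) < 2:
        return 0.0
    return float(np.polyfit(np.log(scales[: len(flucts)]), np.log(flucts), 1)[0])


def f_psr(x, fs: float = 1000.0, band_hz: float = 10.0, **kw):
    f, p = periodogram(x, fs)
    f, p = f[1:], p[1:]
    total = np.sum(p)
    if total <= EPS:
        return 0.0
    peak = f[np.argmax(p)]
    sel = np.abs(f - peak) <= band_hz
    return float(np.sum(p[sel]) / total)


def f_snr(x, fs: float = 1000.0, **kw):
    """Signal-to-noise ratio with the noise power estimated from the mean of
    the lowest decile of periodogram bins (no rest baseline assumed)."""
    _, p = periodogram(x, fs)
    p = p[1:]
    k = max(1, len(p) // 10)
    noise = np.mean(np.sort(p)[:k]) * len(p)
    return float(10.0 * np.log10(max(np.sum(p), EPS) / max(noise, EPS)))


# ---------------------------------------------------------------------------
# UNI: unique / other

def f_kurt(x, **kw):
    x = np.asarray(x, dtype=float)
    m2 = np.var(x)
    if m2 <= EPS:
        return 0.0
    return float(np.mean((x - np.mean(x)) ** 4) / m2 ** 2)


def f_skew(x, **kw):
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd <= EPS:
        return 0.0
    return float(np.mean((x - np.mean(x)) ** 3) / sd ** 3)


def f_pkf(x, fs: float = 1000.0, **kw):
    f, p = periodogram(x, fs)
    return float(f[1:][np.argmax(p[1:])])


def f_vcf(x, fs: float = 1000.0, **kw):
    m0, m1, m2 = _spectral_moments(x, fs, [0, 1, 2])
    m0 = max(m0, EPS)
    return float(m2 / m0 - (m1 / m0) ** 2)


def f_ohm(x, fs: float = 1000.0, **kw):
    m0, m1, m2 = _spectral_moments(x, fs, [0, 1, 2])
    m0 = max(m0, EPS)
    denom = max(m1 / m0, EPS)
    return float(np.sqrt(max(m2 / m0, 0.0)) / denom)


def f_dpr(x, fs: float = 1000.0, smooth_bins: int = 20, **kw):
    _, p = periodogram(x, fs)
    p = p[1:]
    if len(p) >= smooth_bins:
        p = np.convolve(p, np.ones(smooth_bins) / smooth_bins, mode="valid")
    return float(np.max(p) / max(np.min(p), EPS))


def f_smr(x, fs: float = 1000.0, split_hz: float = 35.0, **kw):
    f, p = periodogram(x, fs)
    num = np.sum(p[(f >= split_hz) & (f <= 500.0)])
    den = np.sum(p[f < split_hz])
    return float(num / max(den, EPS))


def f_mavs(x, **kw):
    x = np.asarray(x)
    h = len(x) // 2
    return float(np.mean(np.abs(x[h:])) - np.mean(np.abs(x[:h])))


def f_hist(x, bins: int = 3, sigma_span: float = 3.0, **kw):
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    span = max(sigma_span * sd, EPS)
    counts, _ = np.histogram(x, bins=bins, range=(-span, span))
    return counts.astype(float)


def f_ce(x, max_lag: int = 10, **kw):
    """Critical exponent from the power-law scaling of increment variances."""
    x = np.asarray(x, dtype=float)
    lags = np.arange(1, max_lag + 1)
    v = np.array([np.var(x[k:] - x[:-k]) for k in lags])
    v = np.maximum(v, EPS)
    slope = np.polyfit(np.log(lags), np.log(v), 1)[0]
    return float(slope / 2.0)  # Hurst-like exponent of the increments


def f_vfd(x, max_lag: int = 10, **kw):
    """Variance fractal dimension: ``2 - H`` with ``H`` from increment scaling."""
    return 2.0 - f_ce(x, max_lag=max_lag)


def f_psdfd(x, fs: float = 1000.0, **kw):
    """Box-counting dimension of the min-max-normalized PSD curve."""
    _, p = periodogram(x, fs)
    p = p[1:]
    rng = np.ptp(p)
    if rng <= EPS:
        return 1.0
    ys = (p - np.min(p)) / rng
    xs = np.linspace(0.0, 1.0, len(p))
    return _box_count_dimension(xs, ys)


def f_tspsd(x, **kw):
    """Six log-scaled power-spectral descriptors computed in the time domain
    from the first three even spectral moments (via signal derivatives)."""
    x = np.asarray(x, dtype=float)
    d1 = np.diff(x)
    d2 = np.diff(x, 2)

    def root_power(v):
        return np.sqrt(max(np.sum(v ** 2), EPS))

    m0, m2, m4 = root_power(x), root_power(d1), root_power(d2)
    m0, m2, m4 = (m ** 0.1 / 0.1 for m in (m0, m2, m4))
    sparseness = m0 / max(np.sqrt(np.abs((m0 - m2) * (m0 - m4))), EPS)
    irregularity = m2 / max(np.sqrt(m0 * m4), EPS)
    waveform_ratio = np.sum(np.abs(d1)) / max(np.sum(np.abs(d2)), EPS)
    return np.array([
        _safe_log(m0),
        _safe_log(m0 - m2),
        _safe_log(m0 - m4),
        _safe_log(sparseness),
        _safe_log(irregularity),
        _safe_log(waveform_ratio),
    ])


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class FeatureSpec:
    """One feature-extraction method: a named callable with parameters."""

    name: str
    group: str
    fn: Callable[..., object]
    n_outputs: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def output_names(self) -> list[str]:
        if self.n_outputs == 1:
            return [self.name]
        return [f"{self.name}{i + 1}" for i in range(self.n_outputs)]


@dataclass
class FeatureRegistry:
    entries: list[FeatureSpec]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in registry")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_features(self) -> int:
        return sum(e.n_outputs for e in self.entries)

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUPS}
        for e in self.entries:
            counts[e.group] += 1
        return counts

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for e in self.entries:
            names.extend(e.output_names())
        return names

    def groups_per_feature(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            out.extend([e.group] * e.n_outputs)
        return out

    def schema(self) -> list[dict]:
        return [
            {"name": e.name, "group": e.group, "n_outputs": e.n_outputs,
             "params": dict(e.params)}
            for e in self.entries
        ]


_DEFAULT_TABLE: list[tuple[str, str, Callable, int]] = [
    # --- SAP (25 methods, 29 outputs) ---
    ("AFB", "SAP", f_afb, 1),
    ("DAMV", "SAP", f_damv, 1),
    ("DASDV", "SAP", f_dasdv, 1),
    ("DLD", "SAP", f_dld, 1),
    ("DTM", "SAP", f_dtm, 1),
    ("DVARV", "SAP", f_dvarv, 1),
    ("DV", "SAP", f_dv, 1),
    ("IEMG", "SAP", f_iemg, 1),
    ("LD", "SAP", f_ld, 1),
    ("M2", "SAP", f_m2, 1),
    ("MMAV1", "SAP", f_mmav1, 1),
    ("MMAV2", "SAP", f_mmav2, 1),
    ("MAV", "SAP", f_mav, 1),
    ("MAX", "SAP", f_max, 1),
    ("MHW", "SAP", f_mhw, 3),
    ("MNP", "SAP", f_mnp, 1),
    ("MTW", "SAP", f_mtw, 3),
    ("RMS", "SAP", f_rms, 1),
    ("SM", "SAP", f_sm, 1),
    ("SSI", "SAP", f_ssi, 1),
    ("TM", "SAP", f_tm, 1),
    ("TTP", "SAP", f_ttp, 1),
    ("VAR", "SAP", f_var, 1),
    ("V", "SAP", f_vorder, 1),
    ("WL", "SAP", f_wl, 1),
    # --- FI (5 methods, 5 outputs) ---
    ("FR", "FI", f_fr, 1),
    ("MDF", "FI", f_mdf, 1),
    ("MNF", "FI", f_mnf, 1),
    ("SSC", "FI", f_ssc, 1),
    ("ZC", "FI", f_zc, 1),
    # --- NLC (6 methods, 6 outputs) ---
    ("SAMPEN", "NLC", f_sampen, 1),
    ("APEN", "NLC", f_apen, 1),
    ("WAMP", "NLC", f_wamp, 1),
    ("BC", "NLC", f_bc, 1),
    ("KATZ", "NLC", f_katz, 1),
    ("MFL", "NLC", f_mfl, 1),
    # --- TSM (7 methods, 19 outputs) ---
    ("AR", "TSM", f_ar, 4),
    ("CC", "TSM", f_cc, 4),
    ("DAR", "TSM", f_dar, 4),
    ("DCC", "TSM", f_dcc, 4),
    ("DFA", "TSM", f_dfa, 1),
    ("PSR", "TSM", f_psr, 1),
    ("SNR", "TSM", f_snr, 1),
    # --- UNI (13 methods, 20 outputs) ---
    ("CE", "UNI", f_ce, 1),
    ("DPR", "UNI", f_dpr, 1),
    ("HIST", "UNI", f_hist, 3),
    ("KURT", "UNI", f_kurt, 1),
    ("MAVS", "UNI", f_mavs, 1),
    ("OHM", "UNI", f_ohm, 1),
    ("PKF", "UNI", f_pkf, 1),
    ("PSDFD", "UNI", f_psdfd, 1),
    ("SKEW", "UNI", f_skew, 1),
    ("SMR", "UNI", f_smr, 1),
    ("TSPSD", "UNI", f_tspsd, 6),
    ("VCF", "UNI", f_vcf, 1),
    ("VFD", "UNI", f_vfd, 1),
]


def build_registry(overrides: dict[str, dict] | None = None) -> FeatureRegistry:
    """Build the default 56-method / 79-feature registry.

    ``overrides`` maps a feature name to extra keyword parameters for its
    callable (e.g. ``{"ZC": {"threshold": 10.0}}``).
    """
    overrides = overrides or {}
    entries = [
        FeatureSpec(name, group, fn, n_out, params=dict(overrides.get(name, {})))
        for name, group, fn, n_out in _DEFAULT_TABLE
    ]
    return FeatureRegistry(entries)


def compute_feature(spec: FeatureSpec, x: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Evaluate one method on a single-channel window; returns ``n_outputs`` values."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input window")
    out = np.atleast_1d(np.asarray(spec.fn(x, fs=fs, **spec.params), dtype=float))
    if out.shape != (spec.n_outputs,):
        raise RuntimeError(
            f"{spec.name} produced shape {out.shape}, expected ({spec.n_outputs},)")
    return out


# ---------------------------------------------------------------------------
# feature tables

class FeatureTable:
    """Per-(window, channel) values of named scalar features.

    Stored as an array of shape ``(n_windows, n_channels, n_features)``
    together with feature names, per-feature group/block labels and window
    metadata (participant, gesture, cycle).
    """

    def __init__(self, values: np.ndarray, feature_names: Sequence[str],
                 feature_labels: Sequence[str], meta: pd.DataFrame) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError("values must be (windows, channels, features)")
        if values.shape[2] != len(feature_names):
            raise ValueError("feature_names length mismatch")
        if len(feature_labels) != len(feature_names):
            raise ValueError("feature_labels length mismatch")
        if len(meta) != values.shape[0]:
            raise ValueError("metadata row count mismatch")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature table contains non-finite cells")
        self.values = values
        self.feature_names = list(feature_names)
        self.feature_labels = list(feature_labels)
        self.meta = meta.reset_index(drop=True)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def feature_matrix(self) -> np.ndarray:
        """Feature-major point cloud: ``(n_features, n_windows * n_channels)``.

        Each row is one feature's values over all (window, channel) pairs,
        windows varying slowest.
        """
        return self.values.transpose(2, 0, 1).reshape(self.n_features, -1)

    def wide(self) -> pd.DataFrame:
        """Wide DataFrame with columns ``<FEATURE>_c<channel>`` plus metadata."""
        cols = {}
        for j, name in enumerate(self.feature_names):
            for c in range(self.n_channels):
                cols[f"{name}_c{c}"] = self.values[:, c, j]
        df = pd.DataFrame(cols)
        return pd.concat([self.meta.reset_index(drop=True), df], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.wide().to_csv(path, index=False)

    def concat_features(self, other: "FeatureTable") -> "FeatureTable":
        """Join two tables computed on the same windows along the feature axis."""
        if self.values.shape[:2] != other.values.shape[:2]:
            raise ValueError("tables computed on different window sets")
        if not self.meta[["participant", "gesture", "cycle"]].equals(
                other.meta[["participant", "gesture", "cycle"]]):
            raise ValueError("window metadata mismatch between tables")
        return FeatureTable(
            np.concatenate([self.values, other.values], axis=2),
            self.feature_names + other.feature_names,
            self.feature_labels + other.feature_labels,
            self.meta,
        )


def compute_all(dataset: WindowedDataset, registry: FeatureRegistry | None = None,
                fs: float = 1000.0) -> FeatureTable:
    """Compute every registry feature on every channel of every window."""
    if registry is None:
        registry = build_registry()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    X, y, p, c = dataset.arrays()
    n_windows, n_channels, _ = X.shape
    values = np.empty((n_windows, n_channels, registry.n_features))
    for i in range(n_windows):
        for ch in range(n_channels):
            col = 0
            for spec in registry.entries:
                out = compute_feature(spec, X[i, ch], fs=fs)
                values[i, ch, col:col + spec.n_outputs] = out
                col += spec.n_outputs
    meta = pd.DataFrame({"participant": p, "gesture": y, "cycle": c})
    return FeatureTable(values, registry.feature_names(),
                        registry.groups_per_feature(), meta)
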