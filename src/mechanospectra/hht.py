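"""Hilbert spectral analysis of intrinsic mode functions.

Turns an EMD decomposition into instantaneous frequency/amplitude arrays
(the Hilbert spectrum), and provides the scalar summaries built on it:
energy-weighted central frequency, adaptation/response time, temporal
response ratio, instantaneous consumed-energy density, spatial window
sampling of a pillar field, pooled frequency distributions and their
two-sample Kolmogorov–Smirnov comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import hilbert as _analytic
from scipy.stats import ks_2samp

from .containers import DeflectionField, ForceTrace, FrequencyPDF
from .emd import IMFSet

__all__ = [
    "HilbertSpectrum", "hilbert_spectrum", "central_frequency",
    "response_time", "response_ratio", "energy_density", "window_sample",
    "frequency_distribution", "pooled_frequencies", "ks_compare",
]

#: fraction of samples at each end excluded from frequency statistics
#: (Hilbert transform edge artifacts)
EDGE_FRACTION = 0.05

#: median filter width (samples) applied to the raw instantaneous frequency
FREQ_MEDIAN_WINDOW = 5


@dataclass
class HilbertSpectrum:
    """Per-IMF instantaneous frequency (Hz) and amplitude arrays.

    Frequencies are the median-filtered derivative of the unwrapped analytic
    phase; samples where the derivative is negative (phase regression, a
    numerical artifact) are masked as NaN, as are all samples of an all-zero
    IMF. ``interior`` marks samples outside the boundary-affected edges.
    """

    frequency: np.ndarray      # (n_imfs, n) Hz, NaN where undefined
    amplitude: np.ndarray      # (n_imfs, n) >= 0
    sampling_interval: float   # s
    edge_fraction: float = EDGE_FRACTION
    meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return self.frequency.shape[0]

    @property
    def interior(self) -> np.ndarray:
        """Boolean mask of samples unaffected by edge artifacts."""
        n = self.frequency.shape[1]
        k = int(np.ceil(self.edge_fraction * n))
        mask = np.zeros(n, dtype=bool)
        mask[k:n - k] = True
        return mask


def hilbert_spectrum(imfs: IMFSet) -> HilbertSpectrum:
    """Analytic-signal amplitude and instantaneous frequency of each IMF."""
    dt = float(np.median(np.diff(imfs.times))) if imfs.times.size > 1 else 1.0
    n = imfs.residual.size
    k = imfs.n_imfs
    freq = np.full((k, n), np.nan)
    amp = np.zeros((k, n))
    for i in range(k):
        x = imfs.imfs[i]
        if not np.any(x):
            continue
        z = _analytic(x)
        amp[i] = np.abs(z)
        phase = np.unwrap(np.angle(z))
        f = np.gradient(phase, dt) / (2.0 * np.pi)
        f = median_filter(f, size=FREQ_MEDIAN_WINDOW, mode="nearest")
        f[f < 0] = np.nan
        freq[i] = f
    return HilbertSpectrum(frequency=freq, amplitude=amp, sampling_interval=dt)


def _weighted_pool(spectrum: HilbertSpectrum, imf_index: int | None):
    """Interior (frequency, amplitude²-weight) samples of one or all IMFs."""
    interior = spectrum.interior
    if imf_index is None:
        rows = range(spectrum.n_imfs)
    else:
        rows = [imf_index] if imf_index < spectrum.n_imfs else []
    fs, ws = [], []
    for i in rows:
        f = spectrum.frequency[i, interior]
        w = spectrum.amplitude[i, interior] ** 2
        ok = np.isfinite(f) & (w > 0)
        fs.append(f[ok])
        ws.append(w[ok])
    if not fs:
        return np.array([]), np.array([])
    return np.concatenate(fs), np.concatenate(ws)


def central_frequency(spectrum: HilbertSpectrum, imf_index: int | None = None) -> float:
    """Energy-weighted mean interior instantaneous frequency, in Hz.

    ``imf_index=None`` pools across all IMFs. Returns NaN when the IMF
    carries no energy anywhere in the interior.
    """
    if imf_index is not None and not 0 <= imf_index < spectrum.n_imfs:
        raise IndexError(f"imf_index {imf_index} out of range")
    f, w = _weighted_pool(spectrum, imf_index)
    if f.size == 0 or w.sum() == 0:
        return float("nan")
    return float(np.sum(w * f) / np.sum(w))


def response_time(f_c: float) -> float:
    """Characteristic adaptation time T_c = 1 / f_c, in seconds."""
    if not f_c > 0:
        raise ValueError("central frequency must be positive")
    return 1.0 / f_c


def response_ratio(t, T_c: float):
    """Temporal force response ratio 1 - exp(-t / T_c), in [0, 1)."""
    if not T_c > 0:
        raise ValueError("response time must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = 1.0 - np.exp(-t / T_c)
    return float(out) if out.ndim == 0 else out


def energy_density(spectrum: HilbertSpectrum, n_freq_bins: int = 32):
    """Instantaneous consumed energy and its time–frequency map.

    E(t) = sum over IMFs of f_k(t) * a_k(t)^2 — the frequency-weighted
    quadratic amplitude. The map bins a^2 mass into (frequency, time) cells
    for heatmap rendering. Returns ``(energy_trace, freq_edges, matrix)``.
    """
    f = spectrum.frequency
    a2 = spectrum.amplitude ** 2
    contrib = np.where(np.isfinite(f), f, 0.0) * a2
    n = f.shape[1]
    times = np.arange(n) * spectrum.sampling_interval
    energy = ForceTrace(times=times, values=contrib.sum(axis=0), kind="global",
                        meta={"quantity": "consumed_energy"})

    finite = np.isfinite(f) & (a2 > 0)
    if finite.any():
        fmax = float(np.nanmax(f[finite]))
    else:
        fmax = 1.0
    edges = np.linspace(0.0, max(fmax, 1e-12), n_freq_bins + 1)
    matrix = np.zeros((n_freq_bins, n))
    for i in range(f.shape[0]):
        ok = finite[i]
        if not ok.any():
            continue
        idx = np.clip(np.digitize(f[i, ok], edges) - 1, 0, n_freq_bins - 1)
        cols = np.nonzero(ok)[0]
        np.add.at(matrix, (idx, cols), a2[i, ok])
    return energy, edges, matrix


def window_sample(field: DeflectionField, window_pillars: int) -> list[ForceTrace]:
    """Local force traces on non-overlapping square pillar blocks.

    Each block's trace is the per-frame sum of force-vector magnitudes over
    its masked pillars; blocks containing no masked pillar are dropped.
    Trailing partial blocks are kept so the blocks partition the grid and
    the local traces sum to the global traction trace frame by frame.
    """
    if field.forces is None:
        raise ValueError("field has no forces; run deflection_to_force first")
    rows, cols = field.grid_shape
    w = int(window_pillars)
    if w < 1:
        raise ValueError("window_pillars must be >= 1")
    if w > rows or w > cols:
        raise ValueError("window larger than the pillar grid")
    mag = np.linalg.norm(field.forces, axis=2)        # (n_times, n_pillars)
    pillar_index = np.arange(rows * cols).reshape(rows, cols)
    traces = []
    for r0 in range(0, rows, w):
        for c0 in range(0, cols, w):
            block = pillar_index[r0:r0 + w, c0:c0 + w].ravel()
            block = block[field.cell_mask[block]]
            if block.size == 0:
                continue
            traces.append(ForceTrace(
                times=field.times, values=mag[:, block].sum(axis=1),
                kind="windowed-local",
                meta={"block_origin": (r0, c0), "n_pillars": int(block.size)},
            ))
    return traces


def pooled_frequencies(spectra, imf_index: int | None = None):
    """Pool interior instantaneous frequencies (and a² weights) across
    spectra. Returns ``(frequencies, weights)``."""
    fs, ws = [], []
    for s in spectra:
        f, w = _weighted_pool(s, imf_index)
        fs.append(f)
        ws.append(w)
    return np.concatenate(fs), np.concatenate(ws)


def frequency_distribution(spectra, bins, imf_index: int | None = None) -> FrequencyPDF:
    """Amplitude²-weighted normalized histogram of pooled interior
    instantaneous frequencies across windows/cells."""
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2:
        raise ValueError("need at least 2 bin edges")
    f, w = pooled_frequencies(spectra, imf_index)
    if f.size == 0:
        raise ValueError("no finite instantaneous-frequency samples to pool")
    hist, edges = np.histogram(f, bins=bins, weights=w)
    total = hist.sum()
    if total == 0:
        raise ValueError("all pooled samples fall outside the bins")
    return FrequencyPDF(bin_edges=edges, density=hist / total,
                        n_samples=int(f.size))


def ks_compare(a, b):
    """Two-sample Kolmogorov–Smirnov test on frequency samples.

    Returns ``(D, p)`` with D = sup |ECDF_a - ECDF_b| and the asymptotic
    p-value.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample set needs at least 2 observations")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
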