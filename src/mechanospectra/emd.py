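"""Empirical mode decomposition by cubic-spline envelope sifting.

Decomposes a force trace into intrinsic mode functions (IMFs): oscillatory
components whose upper/lower envelopes are locally symmetric about zero, so
that each admits a meaningful Hilbert instantaneous frequency. Sifting
follows the classic recipe: cubic splines through the local maxima and
minima (mirror-extended past the signal ends), subtract the envelope mean,
repeat until a Cauchy-type stopping criterion is met, then peel the IMF off
and continue on the remainder.

The decomposition is exactly conservative: the IMFs plus the final residual
sum to the input to floating-point round-off, because every IMF is obtained
by subtractions from the running remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ForceTrace

__all__ = ["EMDConfig", "IMFSet", "EmpiricalModeDecomposition", "emd"]


@dataclass
class EMDConfig:
    """Sifting controls.

    max_imfs : maximum number of IMFs to extract (default 5, the number of
        modes used in the spectral characterization).
    sift_stop_sd : Cauchy stopping threshold on successive sift iterates,
        sum((h_prev - h)^2) / sum(h_prev^2) < sift_stop_sd.
    max_sifts : hard cap on sift iterations per IMF.
    boundary / spline : envelope construction; only ``mirror`` extension and
        ``cubic`` splines are implemented.
    """

    max_imfs: int = 5
    sift_stop_sd: float = 0.2
    max_sifts: int = 50
    boundary: str = "mirror"
    spline: str = "cubic"

    def __post_init__(self):
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.sift_stop_sd <= 0:
            raise ValueError("sift_stop_sd must be positive")
        if self.boundary != "mirror":
            raise ValueError("only mirror boundary extension is implemented")
        if self.spline != "cubic":
            raise ValueError("only cubic spline envelopes are implemented")


@dataclass
class IMFSet:
    """EMD result: stacked IMFs plus the non-oscillatory residual."""

    imfs: np.ndarray          # (n_imfs, n) — may be empty (0, n)
    residual: np.ndarray      # (n,)
    times: np.ndarray         # (n,) seconds
    meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima; plateaus take the midpoint."""
    dx = np.diff(x)
    # collapse exact plateaus so diff signs are informative
    sign = np.sign(dx)
    # propagate the last nonzero slope through zero runs
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
    maxima = flips[sign[flips - 1] > 0]
    minima = flips[sign[flips - 1] < 0]
    return maxima, minima


def _mirrored_knots(t, x, idx, n_sym=2):
    """Extrema knots extended by mirroring about both signal endpoints."""
    if idx.size == 0:
        return np.array([]), np.array([])
    left = idx[: min(n_sym, idx.size)]
    right = idx[-min(n_sym, idx.size):]
    t_left = 2.0 * t[0] - t[left][::-1]
    t_right = 2.0 * t[-1] - t[right][::-1]
    tk = np.concatenate([t_left, t[idx], t_right])
    xk = np.concatenate([x[left][::-1], x[idx], x[right][::-1]])
    # mirroring can duplicate the endpoint knot when an extremum sits on it
    tk, keep = np.unique(tk, return_index=True)
    return tk, xk[keep]


def _envelope_mean(t, x):
    """Mean of the cubic-spline upper/lower envelopes, or None if the
    signal has too few extrema to define them."""
    maxima, minima = _local_extrema(x)
    if maxima.size + minima.size < 3 or maxima.size < 1 or minima.size < 1:
        return None
    t_max, x_max = _mirrored_knots(t, x, maxima)
    t_min, x_min = _mirrored_knots(t, x, minima)
    if t_max.size < 2 or t_min.size < 2:
        return None
    upper = CubicSpline(t_max, x_max, bc_type="natural")(t)
    lower = CubicSpline(t_min, x_min, bc_type="natural")(t)
    return 0.5 * (upper + lower)


class EmpiricalModeDecomposition(BaseEstimator, TransformerMixin):
    """Sifting-based EMD with the estimator interface.

    Parameters mirror :class:`EMDConfig`. ``fit(X)`` decomposes a single
    1-D signal (sampled uniformly at ``sampling_interval``); the components
    are then available as ``imfs_`` and ``residual_``, and ``transform``
    returns the stacked IMF matrix.
    """

    def __init__(self, max_imfs=5, sift_stop_sd=0.2, max_sifts=50,
                 sampling_interval=1.0):
        self.max_imfs = max_imfs
        self.sift_stop_sd = sift_stop_sd
        self.max_sifts = max_sifts
        self.sampling_interval = sampling_interval

    def _sift_one(self, t, r):
        h = r
        for _ in range(self.max_sifts):
            mean = _envelope_mean(t, h)
            if mean is None:
                return None
            h_new = h - mean
            denom = float(np.sum(h * h))
            if denom == 0.0:
                return None
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < self.sift_stop_sd:
                break
        return h

    def fit(self, X, y=None):
        cfg = EMDConfig(max_imfs=self.max_imfs, sift_stop_sd=self.sift_stop_sd,
                        max_sifts=self.max_sifts)
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 8:
            raise ValueError("signal must have at least 8 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("signal contains non-finite values")
        t = np.arange(x.size, dtype=float) * float(self.sampling_interval)

        imfs = []
        residual = x.copy()
        for _ in range(cfg.max_imfs):
            imf = self._sift_one(t, residual)
            if imf is None:
                break
            imfs.append(imf)
            residual = residual - imf
            maxima, minima = _local_extrema(residual)
            if maxima.size + minima.size < 3:
                break
        self.imfs_ = (np.vstack(imfs) if imfs
                      else np.empty((0, x.size), dtype=float))
        self.residual_ = residual
        self.n_imfs_ = self.imfs_.shape[0]
        return self

    def transform(self, X=None):
        if not hasattr(self, "imfs_"):
            raise ValueError("call fit before transform")
        return self.imfs_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def emd(trace: ForceTrace, config: EMDConfig | None = None) -> IMFSet:
    """Decompose a force trace into intrinsic mode functions.

    Monotonic input yields zero IMFs with the residual equal to the input.
    """
    cfg = config or EMDConfig()
    est = EmpiricalModeDecomposition(
        max_imfs=cfg.max_imfs, sift_stop_sd=cfg.sift_stop_sd,
        max_sifts=cfg.max_sifts, sampling_interval=trace.dt,
    ).fit(trace.values)
    return IMFSet(imfs=est.imfs_, residual=est.residual_, times=trace.times)
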