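"""Kelvin–Voigt–Myosin (KVM) model of cytoskeletal force generation.

A viscoelastic stress-fiber element (spring K_SF = k_sf·C_α in parallel
with a dashpot η) in series with a contractile myosin element generates
the tension read out by the micropillar array. The crosslinker α-actinin2
abundance C_α sets both the stress-fiber stiffness and the power-law
exponent β = k_{β,α}/C_α of cytoskeletal creep, giving the biphasic
response to a transient stimulus:

rise (0 < t ≤ t1):
    F(t) = k_sf·C_α·k_m·C_m,max · (τ^β + β²·τ^(β−1)),   τ = t / t_ref
relaxation (t > t1):
    F(t) = F_rise(t1) · exp(−(t − t1)·k_rex/β)

Time is nondimensionalized by ``t_ref`` before exponentiation. The rise is
singular at t = 0 for β < 1, so evaluation starts at the first positive
time. Only the product k_sf·C_α·k_m·C_m,max is identifiable from a single
trace's amplitude; fits therefore allow at most one amplitude factor free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import ForceTrace

__all__ = [
    "KVMParams", "KVMFitResult", "kvm_beta", "kvm_force_rise",
    "kvm_force_relax", "kvm_simulate", "kvm_max_force", "sweep_c_alpha",
    "time_to_half_max", "KVMModel", "kvm_fit",
]

_POSITIVE_FIELDS = ("k_pillar", "k_sf", "c_alpha", "eta", "k_m", "c_m_max",
                    "k_beta_alpha", "k_rex", "t1", "t_ref")

#: amplitude enters only through the product k_sf·C_α·k_m·C_m,max; of these,
#: C_α also shapes the curve via β, so it may be co-fit with one other.
_AMPLITUDE_ONLY = {"k_sf", "k_m", "c_m_max"}


@dataclass
class KVMParams:
    """KVM model parameters (defaults from the shipped calibration).

    k_pillar : pillar spring constant, nN/µm (series readout element).
    k_sf : stress-fiber stiffness per unit crosslinker, so K_SF = k_sf·C_α.
    c_alpha : relative α-actinin2 abundance C_α/C_α0 (1 = healthy baseline).
    eta : stress-fiber viscosity (enters β through the creep relation).
    k_m, c_m_max : myosin force scale and maximum activated myosin, so
        F_CM,max = k_m·C_m,max; held constant across conditions because
        peak calcium influx does not change.
    k_beta_alpha : scale of the creep exponent, β = k_beta_alpha / c_alpha.
    k_rex : relaxation scale, 1/s; the relaxation e-folding time is β/k_rex.
    t1 : reinforcement duration, s (force rises on (0, t1]).
    t_ref : time unit for the power law, s.
    """

    k_pillar: float = 17.2
    k_sf: float = 1.0
    c_alpha: float = 1.0
    eta: float = 1.0
    k_m: float = 1.0
    c_m_max: float = 0.03
    k_beta_alpha: float = 0.8
    k_rex: float = 1.6e-3
    t1: float = 300.0
    t_ref: float = 10.0

    def __post_init__(self):
        for name in _POSITIVE_FIELDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError(
                f"beta = k_beta_alpha/c_alpha = {self.beta:.3g} outside (0, 1]"
            )

    @property
    def beta(self) -> float:
        return self.k_beta_alpha / self.c_alpha

    @property
    def amplitude(self) -> float:
        """Force prefactor k_sf·C_α·k_m·C_m,max, nN."""
        return self.k_sf * self.c_alpha * self.k_m * self.c_m_max

    @property
    def f_cm_max(self) -> float:
        """Maximum myosin contractile force F_CM,max = k_m·C_m,max."""
        return self.k_m * self.c_m_max


def kvm_beta(params: KVMParams) -> float:
    """Creep power-law exponent β = k_{β,α} / C_α."""
    return params.beta


def kvm_force_rise(params: KVMParams, t):
    """Tension accumulation during reinforcement, 0 < t ≤ t1."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("rise force is singular at t <= 0 for beta < 1; "
                         "evaluate at t > 0")
    if np.any(t > params.t1):
        raise ValueError("rise phase is defined for t <= t1")
    b = params.beta
    tau = t / params.t_ref
    out = params.amplitude * (tau ** b + b * b * tau ** (b - 1.0))
    return float(out) if out.ndim == 0 else out


def kvm_force_relax(params: KVMParams, t):
    """Kelvin–Voigt relaxation after the reinforcement period, t > t1."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= params.t1):
        raise ValueError("relaxation is defined for t > t1")
    peak = kvm_force_rise(params, params.t1)
    out = peak * np.exp(-(t - params.t1) * params.k_rex / params.beta)
    return float(out) if out.ndim == 0 else out


def kvm_simulate(params: KVMParams, times, normalize: bool = False) -> ForceTrace:
    """Piecewise rise/relaxation force on a time grid (all times > 0).

    ``normalize=True`` scales by the peak F_rise(t1) so the trace peaks
    at 1 when the grid reaches t1.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("time grid must be strictly positive")
    values = np.empty_like(times)
    rise = times <= params.t1
    if rise.any():
        values[rise] = kvm_force_rise(params, times[rise])
    if (~rise).any():
        values[~rise] = kvm_force_relax(params, times[~rise])
    if normalize:
        values = values / kvm_force_rise(params, params.t1)
    return ForceTrace(times=times, values=values,
                      kind="normalized" if normalize else "global",
                      meta={"model": "kvm", "beta": params.beta})


def kvm_max_force(params: KVMParams) -> float:
    """Peak generated force F_rise(t1) — the force-generation ability."""
    return float(kvm_force_rise(params, params.t1))


def sweep_c_alpha(params: KVMParams, c_grid, times) -> np.ndarray:
    """Row-normalized force dynamics over a grid of C_α/C_α0 values.

    Returns a (len(c_grid), len(times)) matrix; each row is the simulated
    trace for that crosslinker level, normalized to its own maximum.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid <= 0):
        raise ValueError("c_grid must be positive")
    rows = []
    for c in c_grid:
        trace = kvm_simulate(replace(params, c_alpha=float(c)), times)
        rows.append(trace.values / trace.values.max())
    return np.vstack(rows)


def time_to_half_max(params: KVMParams, times) -> float:
    """First grid time at which the normalized force reaches half its
    grid maximum."""
    trace = kvm_simulate(params, times)
    half = 0.5 * trace.values.max()
    idx = int(np.argmax(trace.values >= half))
    return float(trace.times[idx])


@dataclass
class KVMFitResult:
    params: KVMParams
    free: tuple
    estimates: dict
    stderr: dict
    rss: float
    success: bool
    meta: dict = field(default_factory=dict)


class KVMModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of the KVM force law to a trace.

    Parameters
    ----------
    free : sequence of parameter names to fit (default ``("c_alpha",
        "k_rex")``). At most one of the amplitude-only factors
        {k_sf, k_m, c_m_max} may be free (the rest are degenerate with it).
    base_params : KVMParams holding the fixed values and the initial guess.
    bounds_factor : free parameters are bounded to
        [default/bounds_factor, default*bounds_factor].
    n_starts : multi-start count (log-spaced perturbations of the guess).
    random_state : seed for the start perturbations.
    """

    def __init__(self, free=("c_alpha", "k_rex"), base_params=None,
                 bounds_factor=10.0, n_starts=4, random_state=0):
        self.free = free
        self.base_params = base_params
        self.bounds_factor = bounds_factor
        self.n_starts = n_starts
        self.random_state = random_state

    def _validate_free(self):
        free = tuple(self.free)
        if len(free) == 0:
            raise ValueError("free parameter set is empty")
        unknown = [f for f in free if f not in _POSITIVE_FIELDS]
        if unknown:
            raise ValueError(f"unknown parameters: {unknown}")
        amp_free = _AMPLITUDE_ONLY.intersection(free)
        if len(amp_free) > 1:
            raise ValueError(
                "only the product k_sf*c_alpha*k_m*c_m_max is identifiable "
                f"from a single trace; free set {sorted(amp_free)} is "
                "degenerate — leave at most one amplitude factor free"
            )
        return free

    def fit(self, t, F):
        free = self._validate_free()
        base = self.base_params or KVMParams()
        t = np.asarray(t, dtype=float).ravel()
        F = np.asarray(F, dtype=float).ravel()
        if t.size != F.size:
            raise ValueError("t and F must have equal length")
        if t.max() <= base.t1 or t.min() > base.t1:
            raise ValueError("trace must cover both rise and relaxation")

        x0 = np.array([getattr(base, name) for name in free])
        lo, hi = x0 / self.bounds_factor, x0 * self.bounds_factor
        # beta = k_beta_alpha/c_alpha must stay in (0, 1]
        if "c_alpha" in free and "k_beta_alpha" not in free:
            i = free.index("c_alpha")
            lo[i] = max(lo[i], base.k_beta_alpha * (1 + 1e-9))

        def residuals(x):
            p = replace(base, **dict(zip(free, x)))
            return kvm_simulate(p, t).values - F

        rng = np.random.default_rng(self.random_state)
        best = None
        for k in range(self.n_starts):
            start = x0 if k == 0 else np.clip(
                x0 * np.exp(rng.uniform(-1.0, 1.0, x0.size)), lo, hi)
            try:
                sol = least_squares(residuals, start, bounds=(lo, hi),
                                    method="trf")
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all fit starts failed")

        # per-parameter uncertainty from the Gauss-Newton approximation
        m = max(t.size - len(free), 1)
        s2 = 2.0 * best.cost / m
        JtJ = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(JtJ)
            stderr = dict(zip(free, np.sqrt(np.maximum(np.diag(cov), 0.0))))
        except np.linalg.LinAlgError:
            stderr = {name: float("nan") for name in free}

        self.params_ = replace(base, **dict(zip(free, best.x)))
        self.result_ = KVMFitResult(
            params=self.params_, free=free,
            estimates=dict(zip(free, map(float, best.x))),
            stderr={k: float(v) for k, v in stderr.items()},
            rss=float(2.0 * best.cost), success=bool(best.success),
        )
        return self

    def predict(self, t):
        if not hasattr(self, "params_"):
            raise ValueError("call fit before predict")
        return kvm_simulate(self.params_, np.asarray(t, dtype=float)).values


def kvm_fit(observed: ForceTrace, base_params: KVMParams | None = None,
            free=("c_alpha", "k_rex"), **kwargs) -> KVMFitResult:
    """Fit free KVM parameters to an observed force trace."""
    model = KVMModel(free=free, base_params=base_params, **kwargs)
    model.fit(observed.times, observed.values)
    return model.result_
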