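"""Seeded synthetic inputs with the statistical structure of the real assay.

Generators for every downstream stage: calibration tones for the spectral
code, KVM force traces with known parameters, micropillar deflection
fields with a cell footprint (biphasic stimulus response, centripetal
traction, peripheral force enhancement, optional stochastic frequency
fluctuations drawn from the Fokker–Planck stationary PDF), Hertz
indentation curves with known modulus, and draws from the stationary
frequency distribution.

All generators are deterministic given (seed, config). Noise is additive
i.i.d. Gaussian on the measurement channel; the noise-free generators
agree exactly with their forward models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DeflectionField, ForceTrace
from .fokker_planck import FPParams, sample_stationary
from .hertz import IndentationCurve
from .kvm import KVMParams, kvm_simulate

__all__ = [
    "SyntheticConfig", "ToneSpec", "gen_tone_signal", "gen_kvm_trace",
    "gen_pillar_field", "gen_hertz_curve", "gen_frequency_samples",
]


@dataclass
class SyntheticConfig:
    """Study conditions of the emulated experiment.

    Defaults follow the measured protocol: frames every 10 s over a 30 min
    observation window with the transient stimulus at t = 300 s, a pillar
    grid with ~2 µm pitch and a cell footprint covering most of it.
    ``noise_sd`` is the absolute measurement noise on forces (nN);
    ``fluct_rel`` is the relative amplitude of the stochastic cytoskeletal
    force fluctuation used when a Fokker–Planck parameter set is supplied.
    """

    seed: int = 0
    sampling_interval: float = 10.0    # s
    duration: float = 2100.0           # s
    noise_sd: float = 0.02             # nN
    grid_rows: int = 12
    grid_cols: int = 12
    pillar_spacing: float = 2.0        # µm
    cell_radius: float = 9.0           # µm
    stimulus_onset: float = 300.0      # s
    fluct_rel: float = 0.05

    def __post_init__(self):
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling_interval must be positive")
        if self.noise_sd < 0 or self.fluct_rel < 0:
            raise ValueError("noise_sd and fluct_rel must be non-negative")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dims must be >= 1")

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval

    def time_grid(self, start: float | None = None) -> np.ndarray:
        t0 = self.sampling_interval if start is None else start
        return np.arange(t0, self.duration + 0.5 * self.sampling_interval,
                         self.sampling_interval)


@dataclass
class ToneSpec:
    """Sum-of-sinusoids fixture: components are (frequency Hz, amplitude,
    phase rad) triples; an optional linear chirp rate (Hz/s) sweeps every
    component's frequency upward over the trace."""

    components: tuple = ()
    chirp_rate: float | None = None


def gen_tone_signal(spec: ToneSpec, config: SyntheticConfig) -> ForceTrace:
    """Sampled sum of sinusoids (+ optional chirp) with Gaussian noise."""
    t = config.time_grid(start=0.0)
    for comp in spec.components:
        f = comp[0]
        f_end = f + (spec.chirp_rate or 0.0) * config.duration
        if not 0 < f < config.nyquist or f_end >= config.nyquist:
            raise ValueError(
                f"component at {f} Hz reaches {max(f, f_end):.4g} Hz, at or "
                f"above the Nyquist frequency {config.nyquist:.4g} Hz"
            )
    x = np.zeros_like(t)
    for f, a, phi in spec.components:
        inst = f * t + (0.5 * (spec.chirp_rate or 0.0)) * t * t
        x += a * np.sin(2.0 * np.pi * inst + phi)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        x = x + rng.normal(0.0, config.noise_sd, t.size)
    return ForceTrace(times=t, values=x, kind="synthetic",
                      meta={"generator": "tone"})


def gen_kvm_trace(params: KVMParams, config: SyntheticConfig) -> ForceTrace:
    """KVM forward model plus i.i.d. Gaussian measurement noise.

    The time grid starts at the first positive sample (the rise law is
    singular at t = 0). Ground-truth parameters travel in ``meta``.
    """
    t = config.time_grid()
    trace = kvm_simulate(params, t)
    values = trace.values
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        values = values + rng.normal(0.0, config.noise_sd, t.size)
    return ForceTrace(times=t, values=values, kind="synthetic",
                      meta={"generator": "kvm", "truth": params})


def _footprint(config: SyntheticConfig):
    rows, cols = config.grid_rows, config.grid_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    positions = np.column_stack([cc.ravel() * config.pillar_spacing,
                                 rr.ravel() * config.pillar_spacing])
    center = positions.mean(axis=0)
    radial = positions - center
    r = np.linalg.norm(radial, axis=1)
    mask = r <= config.cell_radius
    return positions, center, radial, r, mask


def gen_pillar_field(basal_force_per_pillar: float, params: KVMParams,
                     config: SyntheticConfig,
                     fp: FPParams | None = None) -> DeflectionField:
    """Pillar-grid force field for one cell.

    In-footprint pillars carry centripetal force vectors whose magnitude is
    a radially weighted share of the cell tension: the basal level (mean
    ``basal_force_per_pillar`` over the footprint at t = 0, linearly larger
    toward the periphery), plus the KVM stimulus response after
    ``stimulus_onset``, plus — when ``fp`` is given — a sinusoidal
    cytoskeletal fluctuation whose angular frequency is drawn per pillar
    from the Fokker–Planck stationary PDF. Pillars outside the footprint
    carry only measurement noise.
    """
    if basal_force_per_pillar <= 0:
        raise ValueError("basal_force_per_pillar must be positive")
    positions, center, radial, r, mask = _footprint(config)
    if not mask.any():
        raise ValueError("cell footprint covers no pillar; increase "
                         "cell_radius or shrink pillar_spacing")
    t = config.time_grid(start=0.0)
    n_pillars = positions.shape[0]
    rng = np.random.default_rng(config.seed)

    # linear radial weighting, normalized to mean 1 over the footprint
    w = 0.5 + r / config.cell_radius
    w = w / w[mask].mean()

    # stimulus response clocked from onset; zero before
    resp = np.zeros_like(t)
    post = t > config.stimulus_onset
    if post.any():
        resp[post] = kvm_simulate(params, t[post] - config.stimulus_onset).values

    # per-pillar magnitude over time (n_times, n_pillars)
    magnitude = np.zeros((t.size, n_pillars))
    base = basal_force_per_pillar
    fluct = np.zeros((t.size, n_pillars))
    if fp is not None and config.fluct_rel > 0:
        omega = sample_stationary(fp, n_pillars, seed=int(rng.integers(2**31)))
        phase = rng.uniform(0.0, 2.0 * np.pi, n_pillars)
        fluct = (config.fluct_rel * base
                 * np.sin(omega[None, :] * t[:, None] + phase[None, :]))
    magnitude[:, mask] = (w[mask][None, :]
                          * (base + resp[:, None] + fluct[:, mask]))

    # centripetal unit vectors
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r[:, None] > 0, -radial / np.maximum(r, 1e-12)[:, None], 0.0)
    forces = magnitude[:, :, None] * u[None, :, :]
    if config.noise_sd > 0:
        forces = forces + rng.normal(0.0, config.noise_sd, forces.shape)

    return DeflectionField(
        times=t, positions=positions,
        grid_shape=(config.grid_rows, config.grid_cols),
        cell_mask=mask, forces=forces,
        meta={"generator": "pillar_field", "basal": base,
              "truth": params, "fp": fp},
    )


def gen_hertz_curve(E_kpa: float, nu: float, R_um: float,
                    contact_point_nm: float, max_depth_nm: float,
                    config: SyntheticConfig, noise_rel: float = 0.0,
                    n_points: int = 400) -> IndentationCurve:
    """Indentation curve: zero force before contact, Hertz law after,
    with multiplicative (relative) Gaussian noise on the force."""
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    if E_kpa <= 0 or max_depth_nm <= 0:
        raise ValueError("E and max_depth must be positive")
    if noise_rel < 0:
        raise ValueError("noise_rel must be non-negative")
    from .hertz import hertz_force
    z = np.linspace(0.0, contact_point_nm + max_depth_nm, n_points)
    delta = np.maximum(z - contact_point_nm, 0.0)
    F = hertz_force(E_kpa, nu, R_um, delta)
    if noise_rel > 0:
        rng = np.random.default_rng(config.seed)
        F = F * (1.0 + rng.normal(0.0, noise_rel, F.size))
    return IndentationCurve(indentation=z, force=F, probe_radius_um=R_um,
                            poisson_nu=nu,
                            meta={"E_true_kpa": E_kpa,
                                  "contact_true_nm": contact_point_nm})


def gen_frequency_samples(fp: FPParams, n: int, seed: int) -> np.ndarray:
    """Seeded draws of angular frequency from the stationary PDF."""
    return sample_stationary(fp, n, seed)
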