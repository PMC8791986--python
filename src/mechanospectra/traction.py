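"""Micropillar traction: deflections to forces and scalar tension summaries.

Each elastic micropillar acts as a linear cantilever spring: the traction
force a cell exerts on a pillar tip is the pillar spring constant times the
tip deflection, F = K_pillar·ΔL_pillar. Global traction is the sum of
per-pillar force magnitudes over the cell footprint (the vector sum of a
contractile cell's tractions is near zero, so magnitudes are summed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import DeflectionField, ForceTrace

__all__ = [
    "PillarGeometry", "pillar_spring_constant", "deflection_to_force",
    "total_traction", "mean_force_per_pillar", "normalize_trace",
    "traction_heatmap",
]


@dataclass
class PillarGeometry:
    """PDMS micropillar geometry. ``spring_constant`` (nN/µm), when given,
    overrides the value derived from the beam formula."""

    height_um: float = 7.0
    radius_um: float = 1.0
    elastic_modulus_mpa: float = 2.5
    spring_constant: float | None = None

    def __post_init__(self):
        for name in ("height_um", "radius_um", "elastic_modulus_mpa"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.spring_constant is not None and not self.spring_constant > 0:
            raise ValueError("spring_constant must be positive")

    @property
    def k(self) -> float:
        """Effective spring constant in nN/µm (supplied value wins)."""
        if self.spring_constant is not None:
            return self.spring_constant
        return pillar_spring_constant(self)


def pillar_spring_constant(geom: PillarGeometry) -> float:
    """Euler–Bernoulli cantilever bending stiffness k = 3πE r⁴/(4L³),
    returned in nN/µm (1 N/m = 1000 nN/µm)."""
    k_n_per_m = (3.0 * np.pi * geom.elastic_modulus_mpa * 1e6
                 * (geom.radius_um * 1e-6) ** 4
                 / (4.0 * (geom.height_um * 1e-6) ** 3))
    return k_n_per_m * 1e3  # N/m -> nN/µm


def deflection_to_force(field: DeflectionField, geom: PillarGeometry) -> DeflectionField:
    """Fill per-pillar force vectors F = k·ΔL (componentwise), nN."""
    if field.deflections is None:
        raise ValueError("field has no deflections")
    return replace(field, forces=field.deflections * geom.k)


def total_traction(field: DeflectionField) -> ForceTrace:
    """Per-frame sum of force-vector magnitudes over masked pillars."""
    if field.forces is None:
        raise ValueError("field has no forces")
    if not field.cell_mask.any():
        raise ValueError("cell mask is empty")
    mag = np.linalg.norm(field.forces[:, field.cell_mask, :], axis=2)
    return ForceTrace(times=field.times, values=mag.sum(axis=1), kind="global")


def _window_indices(times: np.ndarray, window) -> np.ndarray:
    t0, t1 = window
    idx = np.nonzero((times >= t0) & (times <= t1))[0]
    if idx.size == 0:
        raise ValueError(f"time window [{t0}, {t1}] contains no frames")
    return idx


def mean_force_per_pillar(field: DeflectionField, window) -> float:
    """Mean basal tension per pillar over the time window (t0, t1), nN."""
    trace = total_traction(field)
    idx = _window_indices(trace.times, window)
    n = int(field.cell_mask.sum())
    return float(trace.values[idx].mean() / n)


def normalize_trace(trace: ForceTrace, baseline_window) -> ForceTrace:
    """Divide by the mean over the baseline window (baseline maps to 1)."""
    idx = _window_indices(trace.times, baseline_window)
    baseline = float(trace.values[idx].mean())
    if baseline <= 0:
        raise ValueError("baseline mean must be positive")
    return ForceTrace(times=trace.times, values=trace.values / baseline,
                      kind="normalized", meta={"baseline": baseline})


def traction_heatmap(field: DeflectionField, window) -> np.ndarray:
    """Time-mean per-pillar |F| on the (row, col) grid; out-of-mask
    entries are NaN."""
    if field.forces is None:
        raise ValueError("field has no forces")
    idx = _window_indices(field.times, window)
    mag = np.linalg.norm(field.forces[idx], axis=2).mean(axis=0)
    mag = np.where(field.cell_mask, mag, np.nan)
    return mag.reshape(field.grid_shape)
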