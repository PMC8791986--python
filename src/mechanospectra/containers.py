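"""Core in-memory containers shared across the analysis stages.

Conventions: times in seconds, forces in nanonewtons, lengths in
micrometres (pillar plane) or nanometres (indentation axis), ordinary
frequencies in hertz, angular frequencies in rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ForceTrace:
    """A scalar force time series.

    Parameters
    ----------
    times : ndarray of shape (n,)
        Strictly increasing sample times in seconds.
    values : ndarray of shape (n,)
        Force in nN, or dimensionless after normalization.
    kind : str
        One of ``{"global", "per-pillar-mean", "windowed-local",
        "normalized", "synthetic"}`` — provenance tag, not enforced
        beyond being a string.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "global"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        if self.times.size < 2:
            raise ValueError("trace has fewer than 2 samples")
        return float(np.median(np.diff(self.times)))

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DeflectionField:
    """Per-pillar deflection/force vectors over time on a regular grid.

    ``deflections``/``forces`` have shape (n_times, n_pillars, 2) with the
    last axis holding (x, y) components in µm and nN respectively. Pillar
    order is row-major over the grid; ``positions`` are in µm with the
    origin at the top-left pillar.
    """

    times: np.ndarray
    positions: np.ndarray
    grid_shape: tuple
    cell_mask: np.ndarray
    deflections: np.ndarray | None = None
    forces: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        n_pillars = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_pillars, 2)")
        if int(np.prod(self.grid_shape)) != n_pillars:
            raise ValueError("grid_shape inconsistent with pillar count")
        if self.cell_mask.shape != (n_pillars,):
            raise ValueError("cell_mask length must equal pillar count")
        for name in ("deflections", "forces"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.times.size, n_pillars, 2):
                    raise ValueError(
                        f"{name} must have shape (n_times, n_pillars, 2)"
                    )
                setattr(self, name, arr)

    @property
    def n_pillars(self) -> int:
        return self.positions.shape[0]


@dataclass
class FrequencyPDF:
    """Binned frequency distribution (probability mass per bin)."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int = 0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size != self.bin_edges.size - 1:
            raise ValueError("density must have len(bin_edges) - 1 entries")
        if np.any(self.density < 0):
            raise ValueError("probability masses must be non-negative")
        total = self.density.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("probability masses must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.density))
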