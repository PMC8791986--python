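"""Hertz-model fitting of AFM force–indentation curves.

For a spherical indenter of radius R on an elastic half-space with Young's
modulus E and Poisson ratio ν, the Hertz contact law gives

    F = (4/3) · E/(1 − ν²) · √R · δ^{3/2}

for indentation depth δ past the contact point. Given the contact point,
the least-squares modulus has the closed form Ê ∝ Σ F·δ^{3/2} / Σ δ³; the
contact point itself is found by a grid search minimizing the residual of
the piecewise (zero force, Hertz) model. Grid maps of fitted moduli and
their correlation with a co-registered intensity image support
region-level stiffness readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "IndentationCurve", "HertzFitResult", "ModulusMap", "hertz_force",
    "estimate_contact_point", "HertzModel", "hertz_fit", "modulus_map",
    "correlate_modulus_intensity",
]

DEFAULT_PROBE_RADIUS_UM = 3.05   # 6.1 µm spherical bead probe
DEFAULT_POISSON = 0.45
DEFAULT_CANTILEVER_K = 0.27      # N/m, metadata only
DEFAULT_FIT_DEPTH_NM = 500.0


@dataclass
class IndentationCurve:
    """AFM force–indentation data.

    ``indentation`` is the non-decreasing indentation axis in nm (including
    the pre-contact approach); ``force`` in nN.
    """

    indentation: np.ndarray
    force: np.ndarray
    probe_radius_um: float = DEFAULT_PROBE_RADIUS_UM
    poisson_nu: float = DEFAULT_POISSON
    cantilever_k: float = DEFAULT_CANTILEVER_K
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.shape != self.force.shape or self.indentation.ndim != 1:
            raise ValueError("indentation and force must be 1-D of equal length")
        if np.any(np.diff(self.indentation) < 0):
            raise ValueError("indentation must be non-decreasing")


@dataclass
class HertzFitResult:
    E_kpa: float
    contact_point_nm: float
    fit_depth_nm: float
    residual_rms_nn: float
    r_squared: float


@dataclass
class ModulusMap:
    """Grid of fitted Young's moduli (kPa); failed fits are NaN."""

    E_kpa: np.ndarray

    @property
    def region_mean(self) -> float:
        return float(np.nanmean(self.E_kpa))


def _hertz_prefactor_si(E_pa: float, nu: float, R_m: float) -> float:
    return (4.0 / 3.0) * E_pa / (1.0 - nu * nu) * np.sqrt(R_m)


def hertz_force(E_kpa: float, nu: float, R_um: float, delta_nm):
    """Hertz force in nN at indentation depth δ (nm)."""
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    if E_kpa <= 0 or R_um <= 0:
        raise ValueError("E and R must be positive")
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    pref = _hertz_prefactor_si(E_kpa * 1e3, nu, R_um * 1e-6)
    out = pref * (delta * 1e-9) ** 1.5 * 1e9
    return float(out) if out.ndim == 0 else out


def _closed_form_E(delta_nm, force_nn, nu, R_um):
    """Least-squares modulus given contact: Ê ∝ Σ F·δ^{3/2} / Σ δ³ (kPa)."""
    d32 = (delta_nm * 1e-9) ** 1.5
    denom = float(np.sum(d32 * d32))
    if denom == 0.0:
        return np.nan
    slope = float(np.sum(force_nn * 1e-9 * d32)) / denom   # N per m^{3/2}
    E_pa = slope * 3.0 * (1.0 - nu * nu) / (4.0 * np.sqrt(R_um * 1e-6))
    return E_pa / 1e3


def estimate_contact_point(curve: IndentationCurve, fit_depth_nm=None) -> float:
    """Contact point minimizing the piecewise (zero, Hertz) residual.

    Every interior sample position is a candidate contact point; for each,
    the closed-form modulus is computed on the post-contact region (up to
    ``fit_depth_nm`` past contact when given) and the total squared
    residual of (pre-contact forces vs 0, post-contact vs Hertz) scored.
    """
    z, F = curve.indentation, curve.force
    if z.size < 8:
        raise ValueError("curve too short for contact estimation")
    best = (np.inf, None)
    null_rss = float(np.sum(F * F))
    for i in range(1, z.size - 3):
        zc = z[i]
        delta = z - zc
        post = delta > 0
        if fit_depth_nm is not None:
            post &= delta <= fit_depth_nm
        if post.sum() < 3:
            continue
        E = _closed_form_E(delta[post], F[post], curve.poisson_nu,
                           curve.probe_radius_um)
        if not np.isfinite(E) or E <= 0:
            continue
        pred = hertz_force(E, curve.poisson_nu, curve.probe_radius_um,
                           delta[post])
        rss = float(np.sum((F[post] - pred) ** 2) + np.sum(F[~post & (delta <= 0)] ** 2))
        if rss < best[0]:
            best = (rss, zc)
    if best[1] is None or best[0] >= null_rss:
        raise ValueError("no contact point improves on the null (flat) model")
    return float(best[1])


class HertzModel(BaseEstimator, RegressorMixin):
    """Estimator interface for Hertz fitting of a single curve.

    ``fit(indentation_nm, force_nn)`` estimates the contact point (unless
    ``contact_point_nm`` is supplied) and the Young's modulus over depths
    in (0, ``fit_depth_nm``] past contact. Fitted attributes: ``E_kpa_``,
    ``contact_point_nm_``, ``residual_rms_nn_``, ``r_squared_``.
    """

    def __init__(self, probe_radius_um=DEFAULT_PROBE_RADIUS_UM,
                 poisson_nu=DEFAULT_POISSON, fit_depth_nm=DEFAULT_FIT_DEPTH_NM,
                 contact_point_nm=None):
        self.probe_radius_um = probe_radius_um
        self.poisson_nu = poisson_nu
        self.fit_depth_nm = fit_depth_nm
        self.contact_point_nm = contact_point_nm

    def fit(self, indentation_nm, force_nn):
        curve = IndentationCurve(indentation=indentation_nm, force=force_nn,
                                 probe_radius_um=self.probe_radius_um,
                                 poisson_nu=self.poisson_nu)
        if self.contact_point_nm is None:
            cp = estimate_contact_point(curve, fit_depth_nm=self.fit_depth_nm)
        else:
            cp = float(self.contact_point_nm)
        delta = curve.indentation - cp
        post = (delta > 0) & (delta <= self.fit_depth_nm)
        if post.sum() < 3:
            raise ValueError("insufficient post-contact samples within "
                             "fit_depth; deepen the curve or reduce depth")
        E = _closed_form_E(delta[post], curve.force[post], self.poisson_nu,
                           self.probe_radius_um)
        if not np.isfinite(E) or E <= 0:
            raise ValueError("Hertz fit produced a non-positive modulus")
        pred = hertz_force(E, self.poisson_nu, self.probe_radius_um, delta[post])
        resid = curve.force[post] - pred
        ss_tot = float(np.sum((curve.force[post] - curve.force[post].mean()) ** 2))
        self.E_kpa_ = float(E)
        self.contact_point_nm_ = cp
        self.residual_rms_nn_ = float(np.sqrt(np.mean(resid ** 2)))
        self.r_squared_ = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, indentation_nm):
        if not hasattr(self, "E_kpa_"):
            raise ValueError("call fit before predict")
        delta = np.maximum(np.asarray(indentation_nm, dtype=float)
                           - self.contact_point_nm_, 0.0)
        return hertz_force(self.E_kpa_, self.poisson_nu,
                           self.probe_radius_um, delta)


def hertz_fit(curve: IndentationCurve,
              fit_depth_nm: float = DEFAULT_FIT_DEPTH_NM,
              contact_point_nm: float | None = None) -> HertzFitResult:
    """Fit the Hertz model to one curve; returns modulus and diagnostics."""
    model = HertzModel(probe_radius_um=curve.probe_radius_um,
                       poisson_nu=curve.poisson_nu,
                       fit_depth_nm=fit_depth_nm,
                       contact_point_nm=contact_point_nm)
    model.fit(curve.indentation, curve.force)
    return HertzFitResult(E_kpa=model.E_kpa_,
                          contact_point_nm=model.contact_point_nm_,
                          fit_depth_nm=fit_depth_nm,
                          residual_rms_nn=model.residual_rms_nn_,
                          r_squared=model.r_squared_)


def modulus_map(curves, fit_depth_nm: float = DEFAULT_FIT_DEPTH_NM) -> ModulusMap:
    """Per-cell Hertz fits over a 2-D grid of curves (None or failed fits
    become NaN); at least one cell must fit."""
    rows = []
    any_ok = False
    for row in curves:
        vals = []
        for c in row:
            if c is None:
                vals.append(np.nan)
                continue
            try:
                vals.append(hertz_fit(c, fit_depth_nm=fit_depth_nm).E_kpa)
                any_ok = True
            except (ValueError, RuntimeError):
                vals.append(np.nan)
        rows.append(vals)
    if not any_ok:
        raise ValueError("no curve in the grid could be fitted")
    return ModulusMap(E_kpa=np.asarray(rows, dtype=float))


def correlate_modulus_intensity(mmap: ModulusMap, intensity) -> float:
    """Pearson correlation between grid moduli and a co-registered
    intensity map over paired finite cells (NaN if degenerate)."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != mmap.E_kpa.shape:
        raise ValueError("intensity map shape must match the modulus grid")
    ok = np.isfinite(mmap.E_kpa) & np.isfinite(intensity)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired finite values")
    e, x = mmap.E_kpa[ok], intensity[ok]
    if np.std(e) == 0 or np.std(x) == 0:
        import warnings
        warnings.warn("zero variance: correlation undefined", RuntimeWarning)
        return float("nan")
    return float(pearsonr(e, x).statistic)
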