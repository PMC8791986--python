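"""Pillar spring mechanics and traction summaries."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanospectra import (DeflectionField, ForceTrace, KVMParams,
                            PillarGeometry, SyntheticConfig,
                            deflection_to_force, gen_pillar_field,
                            mean_force_per_pillar, normalize_trace,
                            pillar_spring_constant, total_traction,
                            traction_heatmap)


@pytest.fixture
def geom():
    return PillarGeometry(height_um=7.0, radius_um=1.0, elastic_modulus_mpa=2.5)


def uniform_field(n_times=5, rows=3, cols=3, fx=1.0, fy=0.0, mask=None):
    n = rows * cols
    pos = np.array([(c * 2.0, r * 2.0) for r in range(rows) for c in range(cols)])
    forces = np.zeros((n_times, n, 2))
    forces[:, :, 0] = fx
    forces[:, :, 1] = fy
    return DeflectionField(
        times=np.arange(n_times, dtype=float) * 10.0, positions=pos,
        grid_shape=(rows, cols),
        cell_mask=np.ones(n, bool) if mask is None else mask, forces=forces)


class TestSpringConstant:
    def test_beam_formula_value(self, geom):
        # 3*pi*E*r^4/(4 L^3) at E=2.5 MPa, r=1 um, L=7 um -> 0.0172 N/m
        assert pillar_spring_constant(geom) == pytest.approx(17.17, rel=1e-3)

    def test_length_and_radius_scaling(self, geom):
        k = pillar_spring_constant(geom)
        assert pillar_spring_constant(replace(geom, height_um=14.0)) == \
            pytest.approx(k / 8)
        assert pillar_spring_constant(replace(geom, radius_um=2.0)) == \
            pytest.approx(16 * k)

    def test_supplied_value_wins(self, geom):
        g = replace(geom, spring_constant=42.0)
        assert g.k == 42.0

    def test_rejects_nonpositive_geometry(self):
        with pytest.raises(ValueError):
            PillarGeometry(height_um=0.0)


class TestDeflectionToForce:
    def test_linear_spring(self, geom):
        g = replace(geom, spring_constant=17.2)
        f = uniform_field()
        f = replace(f, forces=None,
                    deflections=np.full((5, 9, 2), [0.5, 0.0]))
        out = deflection_to_force(f, g)
        np.testing.assert_allclose(out.forces[..., 0], 8.6)
        np.testing.assert_allclose(out.forces[..., 1], 0.0)

    def test_zero_deflection_zero_force(self, geom):
        f = uniform_field()
        f = replace(f, forces=None, deflections=np.zeros((5, 9, 2)))
        assert np.all(deflection_to_force(f, geom).forces == 0)

    def test_round_trip(self, geom):
        rng = np.random.default_rng(0)
        defl = rng.normal(size=(5, 9, 2))
        f = replace(uniform_field(), forces=None, deflections=defl)
        out = deflection_to_force(f, geom)
        np.testing.assert_allclose(out.forces / geom.k, defl, rtol=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.floats(1e-3, 1e3))
    def test_homogeneous_degree_one(self, scale):
        geom = PillarGeometry()
        defl = np.ones((2, 9, 2))
        f1 = replace(uniform_field(2), forces=None, deflections=defl)
        f2 = replace(uniform_field(2), forces=None, deflections=scale * defl)
        out1 = deflection_to_force(f1, geom)
        out2 = deflection_to_force(f2, geom)
        np.testing.assert_allclose(out2.forces, scale * out1.forces,
                                   rtol=1e-12)

    def test_requires_deflections(self, geom):
        with pytest.raises(ValueError, match="deflections"):
            deflection_to_force(uniform_field(), geom)


class TestTotalTraction:
    def test_sum_of_magnitudes(self):
        trace = total_traction(uniform_field(fx=1.0))
        np.testing.assert_allclose(trace.values, 9.0)

    def test_mask_excludes_pillars(self):
        mask = np.zeros(9, bool)
        mask[:4] = True
        f = uniform_field(mask=mask)
        big = f.forces.copy()
        big[:, ~mask, :] = 100.0
        f2 = replace(f, forces=big)
        np.testing.assert_allclose(total_traction(f).values,
                                   total_traction(f2).values)

    def test_additive_over_disjoint_masks(self):
        f = uniform_field()
        m1 = np.zeros(9, bool); m1[:4] = True
        m2 = ~m1
        total = total_traction(f).values
        part = (total_traction(replace(f, cell_mask=m1)).values
                + total_traction(replace(f, cell_mask=m2)).values)
        np.testing.assert_allclose(total, part, rtol=1e-12)

    def test_generator_contract_at_t0(self):
        cfg = SyntheticConfig(seed=6, duration=300.0, noise_sd=0.0)
        field = gen_pillar_field(1.0, KVMParams(), cfg)
        trace = total_traction(field)
        n = field.cell_mask.sum()
        assert trace.values[0] == pytest.approx(1.0 * n, rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            total_traction(uniform_field(mask=np.zeros(9, bool)))


class TestMeanForceAndNormalize:
    def test_uniform_field_mean(self):
        f = uniform_field(fx=1.0)
        assert mean_force_per_pillar(f, (0.0, 40.0)) == pytest.approx(1.0)

    def test_basal_ratio_between_conditions(self):
        cfg = SyntheticConfig(seed=7, duration=300.0, noise_sd=0.0)
        lo = gen_pillar_field(1.0, KVMParams(), cfg)
        hi = gen_pillar_field(2.0, replace(KVMParams(), c_alpha=2.0), cfg)
        w = (0.0, 290.0)
        ratio = mean_force_per_pillar(hi, w) / mean_force_per_pillar(lo, w)
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            mean_force_per_pillar(uniform_field(), (1000.0, 2000.0))

    def test_constant_trace_normalizes_to_one(self):
        tr = ForceTrace(times=np.arange(10.0), values=np.full(10, 3.3))
        np.testing.assert_allclose(normalize_trace(tr, (0, 4)).values, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(1, 2, 50)
        tr = ForceTrace(times=np.arange(50.0), values=v)
        n1 = normalize_trace(tr, (0, 10)).values
        tr2 = ForceTrace(times=np.arange(50.0), values=7.7 * v)
        np.testing.assert_allclose(normalize_trace(tr2, (0, 10)).values, n1,
                                   rtol=1e-12)

    def test_doubling_trace_gives_two(self):
        v = np.r_[np.ones(10), 2 * np.ones(10)]
        tr = ForceTrace(times=np.arange(20.0), values=v)
        assert normalize_trace(tr, (0, 9)).values[-1] == pytest.approx(2.0)

    def test_nonpositive_baseline_rejected(self):
        tr = ForceTrace(times=np.arange(10.0), values=np.zeros(10))
        with pytest.raises(ValueError, match="baseline"):
            normalize_trace(tr, (0, 9))


class TestHeatmap:
    def test_uniform_constant_matrix(self):
        hm = traction_heatmap(uniform_field(), (0.0, 40.0))
        np.testing.assert_allclose(hm, 1.0)

    def test_sum_matches_total_traction(self):
        cfg = SyntheticConfig(seed=8, duration=300.0, noise_sd=0.0)
        field = gen_pillar_field(1.5, KVMParams(), cfg)
        hm = traction_heatmap(field, (0.0, 300.0))
        idx = np.nonzero((field.times >= 0) & (field.times <= 300.0))[0]
        mean_total = total_traction(field).values[idx].mean()
        assert np.nansum(hm) == pytest.approx(mean_total, rel=1e-9)

    def test_periphery_exceeds_center(self):
        cfg = SyntheticConfig(seed=9, duration=100.0, noise_sd=0.0)
        field = gen_pillar_field(1.0, KVMParams(), cfg)
        hm = traction_heatmap(field, (0.0, 100.0))
        r, c = field.grid_shape
        center_val = hm[r // 2, c // 2]
        ring = np.nanmax(hm)
        assert ring > center_val

    def test_out_of_mask_flagged_nan(self):
        cfg = SyntheticConfig(seed=9, duration=100.0, noise_sd=0.0,
                              cell_radius=5.0)
        field = gen_pillar_field(1.0, KVMParams(), cfg)
        hm = traction_heatmap(field, (0.0, 100.0))
        assert np.isnan(hm[0, 0])  # grid corner outside a 5 um footprint
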