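# mechanospectra

Analysis toolkit for single-cell mechanosensation measured on elastic
micropillar arrays. Vascular smooth muscle cells (VSMC) seeded on a bed of
PDMS micropillars deflect the pillar tips in proportion to their
cytoskeletal tension; after a brief local mechanical stimulus the tension
rises for a few minutes (reinforcement) and then decays (relaxation). This
package quantifies that response and models it:

* **Micropillar traction** — pillar deflections → forces via the cantilever
  spring constant `k = 3πE r⁴ / (4L³)`; global traction, basal tension per
  pillar, normalized traces and grid heatmaps.
* **Hilbert–Huang spectral analysis** — empirical mode decomposition of
  windowed local force traces into intrinsic mode functions (IMFs),
  instantaneous frequency/amplitude via the Hilbert transform,
  energy-weighted central frequency `f_c`, response time `T_c = 1/f_c`,
  the temporal response ratio `1 − e^(−t/T_c)`, and instantaneous consumed
  energy `E(t) = Σ_k f_k a_k²`.
* **Kelvin–Voigt–Myosin (KVM) model** — a viscoelastic stress-fiber element
  (spring `K_SF = k_sf·C_α`, dashpot `η`) in series with a contractile
  myosin element. The crosslinker (α-actinin2) abundance `C_α` sets the
  creep exponent `β = k_{β,α}/C_α`, giving the biphasic force law
  `F ∝ τ^β + β²τ^(β−1)` on the rise and exponential relaxation with
  e-folding time `β/k_rex` afterwards; nonlinear least-squares parameter
  recovery from measured traces.
* **Fokker–Planck frequency model** — drift–diffusion of the instantaneous
  frequency toward the central angular frequency
  `ω_c = sqrt(K_SF/m − (η/2m)²)` with noise magnitude `D`; skewed
  stationary PDF, finite-difference propagation, and PDF fitting.
* **Hertz AFM fitting** — Young's modulus from force–indentation curves for
  a spherical probe, `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`, with contact-point
  estimation, grid stiffness maps and modulus–intensity correlation.
* **Synthetic data** — seeded generators emulating every input (tones,
  KVM traces, pillar fields with a cell footprint, indentation curves,
  stationary-PDF frequency samples), so the full pipeline is testable
  without any measurement data.

The model-fitting surfaces follow scikit-learn conventions
(`EmpiricalModeDecomposition`, `KVMModel`, `HertzModel`,
`StationaryFrequencyModel` expose `fit`/`transform`/`predict`,
`get_params`, and fitted attributes with trailing underscores).

## Worked example

```python
import mechanospectra as ms

# a healthy-like synthetic cell on a 12x12 pillar grid, frames every 10 s
cfg = ms.SyntheticConfig(seed=0)
cell = ms.simulate_cohort(c_alpha=1.0, n_cells=1, config=cfg)[0]
metrics = ms.analyze_cell(cell, ms.AnalysisConfig())
print(f"basal tension       : {metrics.basal_tension_nn:.3f} nN/pillar")
print(f"max force generation: {metrics.max_force_generation:.3f}")
print(f"central frequency   : {metrics.central_frequency_hz:.4f} Hz")
print(f"response time       : {metrics.response_time_s:.1f} s")

# recover KVM parameters from a noisy trace
fit = ms.kvm_fit(
    ms.gen_kvm_trace(ms.KVMParams(c_alpha=1.4),
                     ms.SyntheticConfig(seed=1, noise_sd=0.01)),
    base_params=ms.KVMParams(), free=("c_alpha", "k_rex"))
print("recovered:", fit.estimates)
```

prints

```
basal tension       : 1.000 nN/pillar
max force generation: 0.461
central frequency   : 0.0232 Hz
response time       : 43.1 s
recovered: {'c_alpha': 1.40395..., 'k_rex': 0.00161...}
```

The basal tension is the pre-stimulus mean force per pillar; the maximum
force generation is the peak of the baseline-normalized global traction
during the reinforcement window, minus 1 (0.461 ≈ a 46% tension rise); the
central frequency is the energy-weighted mean instantaneous frequency of
the first IMF pooled over spatial windows, and the response time is its
reciprocal. The KVM fit recovers the crosslinker level (true 1.4) and the
relaxation scale (true 1.6e-3 s⁻¹) from a trace with 1% noise.

A `mechanospectra` command-line interface wraps the same functionality
(`simulate`, `analyze`, `compare`, `kvm-simulate`, `kvm-fit`, `kvm-sweep`,
`fp-stationary`, `fp-propagate`, `hertz-fit`, `hertz-map`); all tables are
TSV and all parameters/results JSON.

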