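# Methods

This note documents the models implemented in `mechanospectra`, their
assumptions, the default parameters and why they hold the values they do,
the numerical choices, and what the synthetic-data generators do and do
not emulate.

## Micropillar traction

Each micropillar is treated as a linear Euler–Bernoulli cantilever: tip
force equals `k · ΔL` with `k = 3πE r⁴ / (4L³)`. Defaults (height 7 µm,
radius 1 µm, PDMS modulus 2.5 MPa → k ≈ 17.2 nN/µm) are placeholders in
the realistic range for PDMS pillar arrays — pillar diameter, pitch and
modulus are fabrication-specific, and a calibrated spring constant, when
supplied, always overrides the beam formula. Global traction is defined as
the **sum of per-pillar force magnitudes** over the cell footprint: a
contractile cell's traction vectors point centripetally and nearly cancel
vectorially, so the vector-sum magnitude would measure only asymmetry, not
tension. Normalization divides by the mean over the pre-stimulus window;
each cell is normalized to its own baseline.

## Hilbert–Huang spectral analysis

Local force traces are sampled on non-overlapping square pillar blocks
(default 3×3; trailing partial blocks are kept so the blocks partition the
grid and local traces sum to the global trace). Each trace is decomposed
by EMD with cubic-spline envelopes, mirror extension of the boundary
extrema (two extrema reflected about each end), a Cauchy-type stopping
criterion `Σ(h_prev − h)² / Σh_prev² < 0.2` and at most 50 sift iterations
per IMF and 5 IMFs. The decomposition is conservative to round-off by
construction; a monotonic signal yields zero IMFs.

Instantaneous frequency is the time derivative of the unwrapped analytic
phase divided by 2π, median-filtered over 5 samples; negative values
(phase regression, a numerical artifact) are masked, and the first and
last 5% of samples are excluded from all frequency statistics (Hilbert
edge artifacts). The central frequency of an IMF is its amplitude²-weighted
mean interior instantaneous frequency — the standard marginal-spectrum
weighting; the response time is `T_c = 1/f_c` and the temporal response
ratio `1 − e^(−t/T_c)` (the decaying form; the growing exponent diverges
and cannot be a response *ratio*). Consumed energy is
`E(t) = Σ_k f_k(t)·a_k(t)²`.

**Which IMF enters the cohort statistics.** The per-cell pipeline pools
the **first IMF** across windows (`AnalysisConfig.pool_imf = 0`) for the
central frequency, response time and pooled frequency distributions. The
first IMF is the highest-frequency mode and carries the localized force
fluctuations the frequency analysis is about; the smooth stimulus-response
transient falls into the slow IMFs and the residual, and pooling it in
(energy weighting across all IMFs, available via `pool_imf=None`) lets its
large, condition-dependent amplitude dominate the statistic and mask the
fluctuation band. Library-level `central_frequency` and
`frequency_distribution` default to pooling all IMFs.

Two-sample frequency distributions are compared with the
Kolmogorov–Smirnov test (`scipy.stats.ks_2samp`, asymptotic p-value).
Pooled interior instantaneous-frequency samples across all windows and
cells of a group enter the test unweighted; pseudo-replication across
samples of one cell makes the p-value anticonservative, so it should be
read as a distribution-contrast summary, not a per-cell inference.

## Kelvin–Voigt–Myosin model

A stress-fiber Kelvin–Voigt element (spring `K_SF = k_sf·C_α`, dashpot
`η`) in series with a contractile myosin element shares the tension read
out by the pillar spring. Cytoskeletal creep follows a power law `t^β`
with `β = k_{β,α}/C_α ∈ (0, 1]`: more crosslinker → more elastic → smaller
β. The generated tension is

* rise, `0 < t ≤ t1`:  `F = k_sf·C_α·k_m·C_m,max · (τ^β + β²·τ^(β−1))`,
  `τ = t/t_ref`;
* relaxation, `t > t1`: `F = F_rise(t1) · e^{−(t−t1)·k_rex/β}`.

Assumptions: the maximum activated myosin `C_m,max` (hence `F_CM,max =
k_m·C_m,max`) is constant across conditions (peak calcium influx does not
differ); only the product `k_sf·C_α·k_m·C_m,max` is identifiable from a
single trace's amplitude, so fits accept at most one amplitude factor in
the free set. The rise law is singular at `t = 0` for `β < 1`; evaluation
starts at the first positive grid sample. The rise is monotone for
`τ ≥ 1`; below `τ = β(1−β) < 1/4` the singular term makes it decrease,
which is outside the sampled regime at the default 10-s frame interval.

**Defaults and calibration** (`scripts/calibrate_defaults.py`). Time is
nondimensionalized by `t_ref = 10 s`, and `k_{β,α} = 0.8`, `t1 = 300 s`
(the reinforcement duration), `k_rex = 1.6e-3 s⁻¹` (relaxation e-folding
time of 500 s at `C_α = 1`), amplitude `k_sf·k_m·C_m,max = 0.03 nN` per
pillar (a ~46% tension rise over a 1 nN basal level at `C_α = 1`). The
value of `t_ref` matters structurally: the peak force
`F_max ∝ C_α·τ1^{k_{β,α}/C_α}` decreases with `C_α` on `[1, 2]` only when
`k_{β,α}·ln(τ1) > 2`, and with `β ≤ 1` at `C_α = 1` this requires
`τ1 = t1/t_ref > e²`; `t_ref = 10 s` gives `τ1 = 30`. With these defaults
the peak generated force falls monotonically by ~2× over
`C_α/C_α0 ∈ [1, 2]` — the force-generation deficit of crosslinker-rich
cells.

**A structural note on the rise timescale.** The time to half-maximum of
the normalized rise scales as `t1·0.5^{1/β} = t1·0.5^{C_α/k_{β,α}}` and is
therefore *decreasing* in `C_α` for any admissible parameters (the
singular `β²τ^{β−1}` term only strengthens the early rise further). The
prolonged response of crosslinker-rich cells is carried not by the rise
shape but by the frequency-domain response time of the oscillator model
below. `time_to_half_max` is computed and reported as-is.

## Fokker–Planck frequency model

Instantaneous angular frequency performs drift–diffusion toward the
central frequency: `∂p/∂t = ∂[(ω−ω_c)p]/∂ω + D ∂²p/∂ω²` — an
Ornstein–Uhlenbeck process with unit relaxation rate and stationary
variance `D`. The central frequency comes from the damped oscillator
`ω_c = sqrt(K_SF/m − (η/2m)²)` with effective mass
`m = C_α V_α M_α + C_m V_m M_m`.

**Stiffness–friction co-scaling convention.** For fixed `η`, `ω_c` is
monotonically *increasing* in `C_α` (the stiffness term grows and the
damping term shrinks), which cannot produce a red shift with crosslinker
accumulation. The shipped defaults therefore adopt the convention that
crosslinker density raises internal friction along with stiffness:
`K_SF = 0.0976·C_α`, `η = 0.7266·C_α` (normalized units, unit volumes and
molecular weights, `C_m V_m M_m = 1`). The two coefficients are solved
from two anchors — `ω_c = 0.1257 rad/s` (f_c ≈ 0.020 Hz) at `C_α = 1` and
`ω_c = 0.080 rad/s` (f_c ≈ 0.0127 Hz) at `C_α = 2` — placing the healthy
fluctuation band comfortably below the Nyquist frequency (0.05 Hz) of the
10-s frame interval. Under this convention `ω_c` decreases and the
predicted response time `T_c = 2π/ω_c` (50 → 78.5 s) increases
monotonically over `C_α/C_α0 ∈ [1, 2]`. The `2π` converts the angular
central frequency to the reciprocal-of-ordinary-frequency definition of
`T_c` used by the spectral stage.

The stationary solution is extended with an error-function skew factor,
`p(ω) ∝ exp(−(ω−ω_c)²/(2Ds_D))·[1 + erf(κ(ω−ω_c)/(2Ds_D))]`,
`κ = s_{b1}·b + s_{b2}`, numerically renormalized on its evaluation grid.
This is a skew-normal family; `κ = 0` recovers the Gaussian with variance
`D·s_D`, consistent with the OU stationary solution at `s_D = 1`. The
shape factors are free parameters with defaults `s_D = 1`, `s_{b1} = 1`,
`s_{b2} = 0`, `b = 0.06` (mild positive skew, matching right-tailed
frequency histograms). `D = 9e-4 rad²/s²` puts the stationary width at
`σ_ω = 0.03 rad/s`.

Numerics: the solver uses conservative (flux-form) central differences
with zero-flux boundaries — total mass is conserved to round-off by
construction — and Crank–Nicolson stepping with `dt ≤ 0.02` relaxation
times; the default grid spans `ω_c ± 8σ` with 801 points, at which the
discrete fixed point matches the analytic Gaussian to ~3.5e-5 in L1.
Sampling from the stationary PDF is by rejection with a uniform proposal
on `[max(ω_c − 8σ, 0), ω_c + 8σ]`.

PDF fitting frees `(ω_c, D·s_D, κ)` on a binned histogram
(trust-region least squares). The skew-normal family has singular Fisher
information at `κ = 0` — location and skew trade off along a flat residual
ridge — so a symmetric restriction is also fitted and the skew term is
kept only when it significantly improves the residual (F-test, α = 0.05).
Without this, symmetric samples yield center estimates biased by several
percent of σ.

## Hertz AFM fitting

Spherical-probe Hertz contact, purely elastic: `F = (4/3)·E/(1−ν²)·√R·
δ^{3/2}` with defaults R = 3.05 µm (a 6.1 µm bead), ν = 0.45 and a fit
domain of δ ∈ (0, 500 nm] past contact (all configurable); viscoelastic
corrections are omitted (fast indentation minimizes them experimentally)
and cantilever-deflection conversion is assumed already applied. Given a
contact point the modulus has the closed form `Ê ∝ ΣFδ^{3/2}/Σδ³`; the
contact point is chosen by a grid search over sample positions minimizing
the total squared residual of the piecewise (zero, Hertz) model. Region
stiffness is the arithmetic mean of finite grid moduli; modulus–intensity
correlation is Pearson's r over paired finite cells.

## Synthetic data: what is and is not emulated

All generators are deterministic given `(seed, config)`. The defaults
encode the measured protocol: frames every 10 s, a 2100-s record with the
stimulus at t = 300 s (so the 0–5 min reinforcement and 5–30 min
relaxation windows are both covered with a 5-min pre-stimulus baseline),
a 12×12 pillar grid at 2 µm pitch with a disc-shaped cell footprint of
radius 9 µm, measurement noise of 0.02 nN per force sample, and cell
tension larger toward the cell periphery (linear radial weighting,
normalized to mean 1 over the footprint).

A synthetic cell's per-pillar force magnitude is
`w_i·(basal + F_KVM(t − onset) + fluctuation)`, directed centripetally;
pillars outside the footprint carry only noise. Basal tension scales with
crosslinker abundance (1 nN/pillar per unit `C_α/C_α0`), and the
stimulus response follows the KVM law at the cohort's `C_α`. The
fluctuation term — enabled when a Fokker–Planck parameter set is passed —
is a sinusoid per pillar with amplitude 5% of basal and angular frequency
drawn from the stationary PDF at the cohort's `ω_c`: the generator
reproduces the *stationary statistics* the frequency model describes, not
the microscopic dynamics that produce them. Real traces contain
non-sinusoidal, non-stationary fluctuations, spatially correlated pillar
motion, drift and tracking artifacts; none of these are emulated, so
passing tests demonstrate correctness of the analysis chain on data with
the assumed statistical structure, not robustness to instrument
pathologies.

The Hertz generator produces exactly zero force before contact and
multiplicative Gaussian noise after (relative noise is the dominant AFM
force-channel behaviour over a 500-nm indentation); baseline offsets and
adhesion dips are not emulated.

## Degenerate inputs and edge behaviour

Monotonic traces decompose to zero IMFs (residual = input). All-zero IMFs
have zero amplitude and masked frequency. Overdamped Fokker–Planck
parameterizations are rejected with an explicit message, as are
non-normalizable PDFs, empty cell footprints, empty masks/windows,
baselines with non-positive mean, incompressible Poisson ratios (ν ≥ 0.5),
curves with fewer than 3 post-contact samples, and KVM evaluation at the
t = 0 singularity. KVM fits reject free sets containing more than one
pure-amplitude factor as non-identifiable.

## Known limitations

* EMD is the classic single-realization sifting; no ensemble variants, so
  mode mixing under heavy noise is possible (the acceptance fixtures stay
  in the dyadic-separation regime where sifting is reliable).
* The KS p-value on pooled frequency samples is anticonservative (samples
  within a cell are correlated).
* The KVM model's rise-shape timescale shortens with crosslinker
  abundance (see the structural note above); slow-response phenotypes are
  represented by the oscillator response time, not the rise shape.
* The Fokker–Planck and KVM parameter sets are linked only through the
  shared `C_α`; the package does not derive `D`, `s_D` or the skew from
  the mechanical constituents.
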