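# Methods

## The generative model

A doubly stochastic renewal (DSR) point process is specified by a pair
{*g*(·), **λ**(t)}: a stochastic instantaneous firing rate **λ**(t) ≥ 0 and a
renewal interspike-interval density *g*(·) with mean fixed at μ_g = 1 s.
Spike trains are generated per trial in three steps: draw a rate realization
λ(t); place events in operational time by summing i.i.d. ISIs drawn from
*g*; map events to real time through the inverse cumulative rate
t = Λ⁻¹(t′), Λ(t) = ∫₀ᵗ λ(s)ds. Because the operational-time process is
stationary renewal at 1 Hz, the real-time spike density follows λ(t) while
the shape of *g* sets the irregularity independently of the rate.

We take *g* to be the gamma density parameterized by its squared coefficient
of variation φ (shape 1/φ, scale φ): mean 1, variance φ, third central
moment 2φ². φ = 1 gives exponential ISIs (an inhomogeneous Poisson process
after warping); φ < 1 is sub-Poisson, φ > 1 super-Poisson.

Model assumptions worth keeping in mind:

* **Renewal in operational time** — no adaptation or history dependence
  beyond the last spike. Serial ISI correlations in real time can still
  arise from temporally correlated rates.
* **Slow rates** — the count-moment expansion below assumes λ(t) is
  approximately constant within an analysis bin (rate timescale > T).

## Count moments and the partition

For a stationary renewal process with ISI moments (μ, σ², μ₃) the count
N_T in a bin of size T has mean T/μ and variance

σ²/μ³ · T + σ⁴/(2μ⁴) + 1/6 − μ₃/(3μ³) + O(1/T),

which for the unit-mean gamma parameterization reduces to
Var(N_T) = φT + 1/6 − φ²/6. Conditioning on a slowly varying rate and
applying the law of total variance gives the partition

Var(N_T) = Var(λT) + φ·E[N_T] + (1 − φ²)/6 + O(1/T),

splitting observed count variance into a firing-rate component Var(λT) and a
point-process component. The expansion needs E[N_T] ≳ 1 per bin; in the
trial mixture this means bins should contain at least one expected spike on
most trials. When the across-trial rate distribution has substantial mass at
very low rates (e.g. drift–diffusion paths absorbed at a 1 Hz boundary), the
low-rate trials violate the expansion and the estimator acquires a small
negative bias (measured ≈ −0.06 at φ ≤ 0.5 in that regime), still an order
of magnitude below the biases of the reference methods there.

## The two-bin-size estimator

Writing the partition at bin sizes T and αT and eliminating Var(λ) (using
Var(λT) = T²Var(λ)) yields the quadratic

((α²−1)/6)·φ² − (α²E[N_T] − E[N_{αT}])·φ + α²Var(N_T) − Var(N_{αT}) − (α²−1)/6 = 0.

α = 2 by default: α must exceed 1 for the system to be well-conditioned but
stay small enough that the rate is constant over αT. The quadratic is solved
at every window position t_i (stride T/2 by default) from across-trial count
moments (unbiased n−1 variances, half-open bins), and the final estimate is
the average of per-window roots, clipped at 0.

**Root selection.** With exact Poisson moments the roots are {1, 4m−1}; with
exact gamma-renewal moments {φ, ≈ 4E[N_T]−φ}. Only the smaller branch is
stable as the moments vary, so that branch is always selected. Under
sampling noise the stable branch can dip below zero; those values are kept
in the per-window average (which is clipped at zero only at the end).
Jumping to the distant second root whenever the stable branch turns negative
would create extreme outliers — we measured an upward bias of 0.2–0.5 at
φ ≤ 0.3 with 100 trials from exactly that rule — whereas averaging the
signed stable branch is unbiased in the same conditions. Windows with a
negative discriminant are dropped and counted in the diagnostics.

**Bin size.** T = 2/E[λ] by default (from the grand-average rate, rounded to
1 ms): large enough for the expansion, small enough for rate constancy. The
estimator needs roughly 15 or more trials before the nonlinearity of the
root in the noisy moments stops biasing it low (measured: −24% at 6 trials,
−4% at 15, unbiased at ≥ 20); analyses that segment continuous recordings
into pseudo-trials should budget segments accordingly.

## Reference estimators

* **DTR** (deterministic time rescaling): trial-averaged PSTH (60 ms sliding
  window, 10 ms steps, floored at 0.1 Hz for invertibility), cumulative
  integral, per-trial rescaling, φ̂ = CV² of pooled within-trial rescaled
  ISIs. Consistent only when the rate is identical across trials; any
  across-trial rate variance inflates the estimate.
* **MR** (minimum ratio): minimum Fano factor over window positions (60 ms
  bins). Its error decomposes into a rate-variance term growing with T and a
  renewal correction term shrinking with T (`mr_error_prediction` implements
  the closed form); the empirical minimum over many noisy windows adds a
  further order-statistic bias not covered by the closed form.

## Synthetic data generators

**Rate models.** The uniform-across-trials family (flat within trial, level
uniform on [μ−w/2, μ+w/2]) defaults to μ = 30 Hz with w in 10–30 Hz — the
benchmark settings. The drift–diffusion family uses drift ν (Hz/ms),
diffusion D (Hz²/ms), sticky boundaries b_l, b_u; Euler–Maruyama at 1 ms
with the per-ms parameters converted to per-second internally. The boundary
condition dλ/dt = 0 at b_l and b_u is implemented as absorbing: the path is
clamped and frozen at first passage (a `sticky_reentry` switch restores
clip-only semantics). Note that at the benchmark parameters (D = 5–13
Hz²/ms between bounds 1 and 60 Hz) most paths reach a boundary within
~100 ms, so the across-trial rate distribution is near-bimodal — a stringent
test of rate-variance robustness. Defaults elsewhere: b_l = 1, b_u = 60 Hz,
ν = 0.0138 Hz/ms, λ₀ = 30 Hz.

**Spike generation.** Operational-time ISIs are sampled with a burn-in of 10
mean ISIs before the window so the window sees an equilibrium renewal
process; without it, the ordinary-renewal transient biases counts in early
bins. ISIs are floored at 1 ns to preserve strict ordering. Λ is inverted by
linear interpolation on the rate grid, so spike-time resolution is limited
by the rate step (1 ms default). One root seed with per-trial substreams
(`SeedSequence` spawn keys) makes trial sets extensible without reshuffling.

The generators' defaults are the benchmark study conditions; passing tests
on them demonstrates correctness under slow or piecewise-constant rate
dynamics with gamma renewal spiking, not robustness to adaptation, bursting
with history dependence, or rates that change faster than the analysis bin.

## Voltage validation pipeline

The subthreshold membrane potential provides a firing-rate proxy that is
independent of spike timing: the pipeline detects spikes at upward −30 mV
crossings (crossings within 2 ms merged), excises −3/+5 ms around every
above-threshold run with linear interpolation, bins the trace in 50 ms
windows (the bin is configurable; 25 ms is equally defensible and supported),
averages (mean voltage, spike count) pairs within 1 mV voltage bins over
[−68, −40] mV, and fits a cubic smoothing spline with GCV-selected smoothing
(clamped at 0, constant-extrapolated outside the range). Voltage-bin centers
are geometric (−68 + (k−½)·ΔV). Rescaling spikes by Λ̂ from f(v(t)) yields
μ̂_g (≈ 1 if the proxy is faithful) and CV², an estimate of φ that uses no
trial structure.

The synthetic trace generator drives the rate through a monotone power law
f(v) = c(v−v₀)₊^p (defaults: v₀ = −70 mV, p = 2, c set for ≈ 12 Hz at the
OU mean) applied to an Ornstein–Uhlenbeck voltage (τ = 0.5 s, mean −56 mV,
SD 4 mV, clipped to the physiological range), generates DSR spikes from that
rate, and pastes a 2 ms action-potential template at spike times. Because
the template has finite width, ISIs shorter than ~2 ms are censored at
detection; at φ = 1.7 this removes ~10% of the smallest ISIs and biases the
recovered φ down by ~15%, while φ ≤ 1 is recovered within a few percent.
Real recordings share this censoring through the neuron's refractory
period.

## Spiking network

Three layers on unit-square lattices: a thalamic sheet of Poisson units at
10 Hz, and two recurrent excitatory/inhibitory layers of exponential
integrate-and-fire neurons (full sizes 40000 e + 10000 i per layer, 2500
thalamic). Connectivity is drawn per presynaptic neuron with exactly
round(P·N_post) synapses (with replacement), targets sampled with
probability ∝ f(Δx,σ)f(Δy,σ) where f is a wrapped Gaussian (images |k| ≤ 3,
< 1e-12 truncation error for σ ≤ 0.2). The product kernel factorizes over
lattice rows and columns, which the sampler exploits. Lattice placement
requires perfect-square population sizes; the printed position formula is
interpreted with √N as the row length (as the unit-square embedding
requires). Synaptic weights scale as J/√(N_e+N_i); the feedforward layer-2 →
layer-3 kernel mixes 0.2 fast + 0.8 slow (τ_r = 2 ms, τ_d = 100 ms)
components. Integration is forward Euler at dt = 0.05 ms (halving dt changes
population rates < 5%), with the exponential spike-initiation term clamped
10 mV above threshold rather than resolved.

**Desk preset and downscaling.** The shipped desk preset is 4096 e + 1024 i
per layer with 256 thalamic units (~10× reduction, thalamus reduced by the
same factor so feedforward in-degrees stay proportional). Plain 1/√N weight
scaling preserves input fluctuations but shrinks the collective coupling
J·P·√N that sustains the network's turbulent regime: at desk sizes the
plain-scaled network is mean-driven and regular (Fano ≈ 0.4), which inverts
the attention effect. The preset therefore compensates weights by
√(N_full/N_desk), keeping the per-neuron total synaptic drive (in-degree ×
weight) at its full-size value; the cost is √10 larger per-synapse shot
noise. With compensation the desk network is fluctuation-driven (layer-3
Fano ≈ 2.8, broad φ distribution across identical neurons, and the
paradoxical inhibitory response of an inhibition-stabilized network).

**Analyses.** Continuous recordings are segmented into 2 s pseudo-trials
(first second discarded); per-neuron φ uses the DSR estimator with
T = 2/rate clipped to [20 ms, seg/4]. The attention experiment (static
current to layer-3 inhibitory neurons, 0.2 vs 0.4 mV/ms) holds the graph and
all seeds fixed and uses one bin size per neuron across both states —
deriving T per state would confound rate changes with variability changes
through the Fano factor's bin dependence. At desk scale the attention
comparison reproduces the reduction of the Fano factor and of the
firing-rate variance (MI_FF ≈ −0.012, MI_Var ≈ −0.031 at 20 segments/state),
but φ is not as invariant as in the full-size model (MI_φ ≈ −0.06): the
attended state sits ~10% lower in rate and measurably deeper in the
fluctuation-driven regime — a finite-size effect documented here rather than
tuned away.

## Problem sizes in the test suite

Simulation-backed tests run at reduced sizes chosen to keep statistical
power while remaining quick: Fano-factor limits at 800–2000 trials; the
count-moment oracle at 60000 independent windows of T = 10; the estimator
benchmark at 10 φ-values × 3 variability levels × 2 rate families × 5
replicates × 100 trials; voltage closure at 150–200 s of 20 kHz trace; the
attention experiment at the desk preset with 41 s per state. The full-size
network configuration (`paper_config`) is provided but is a
multi-hour/large-memory run and is not exercised by the suite.

## Known limitations

* φ is assumed constant over the analysis window; piecewise analyses are the
  caller's responsibility.
* Overlapping windows (stride T/2) correlate per-window roots; the point
  estimate ignores this, so diagnostic window counts overstate the effective
  sample size.
* The MR error prediction models expected Fano factors, not the order
  statistics of noisy ones.
* The voltage pipeline assumes a deterministic, memoryless voltage-to-rate
  map; bursting or adaptation would violate it.
* Desk-scale network results are sign-level: magnitudes (and the near-exact
  invariance of φ under attention) require the full-size configuration.
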