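# Methods

## The model

`crstim` simulates desynchronizing Coordinated Reset (CR) stimulation of a
plastic spiking network and quantifies the resulting *anti-kindling*: the
unlearning of pathologically strong synaptic connectivity together with the
synchronized firing it sustains.

### Neurons

Each of the N neurons is a conductance-based Hodgkin–Huxley membrane,

    C dV/dt = I − g_Na m³h (V − V_Na) − g_K n⁴ (V − V_K) − g_l (V − V_l) + I(t),

with the standard squid-axon parameters C = 1 µF/cm², g_Na = 120,
g_K = 36, g_l = 0.3 mS/cm², V_Na = 50, V_K = −77, V_l = −54.4 mV.  The
gating variables m, h, n follow the classic first-order kinetics
dx/dt = α_x(V)(1−x) − β_x(V)x with the standard rate functions in the
−65 mV resting convention (e.g. α_m = 0.1(V+40)/(1−e^{−(V+40)/10}),
β_m = 4 e^{−(V+65)/18}); these rate functions are part of this package's
contract since the membrane parameters above fix that convention.  A
constant depolarizing drive I, drawn per neuron uniformly from
[10.55, 11.45] µA/cm², makes every neuron an intrinsic oscillator: at
I = 11.0 the isolated neuron fires with a period of 14.14 ms (≈71 Hz),
so the population is mildly heterogeneous (±1.7% in drive).  Initial
conditions are drawn uniformly: V ∈ [−65, 5] mV and m, h, n, s ∈ [0, 1].
A spike is the downward crossing of V = 0 mV (V = 0, dV/dt < 0).

### Network

Neurons sit on a 1-D chain of physical length d₀ = 10 with periodic
boundary conditions; the lattice spacing is d = d₀/(N−1) and distances use
the minimum-image convention d·min(|i−j|, N−|i−j|).  (The unwrapped
distance d·|i−j| is available behind the `wrap` switch; the wrapped form is
the default because boundary effects are otherwise severe on a chain of
this length.)  The structural coupling template is a Mexican hat

    M_ij = (1 − d_ij²/σ₁²) · exp(−d_ij²/(2σ₂²)),   σ₁ = 3.5, σ₂ = 2.0,

giving strong short-range excitation (M > 0 out to d = 3.5, about 70
neighbours on each side at N = 200) and weak long-range inhibition.  The
synaptic output of neuron j is a gate s_j with
ds_j/dt = 0.5(1−s_j)/(1+e^{−(V_j+5)/12}) − 2s_j (a brief ~0.5 ms pulse per
spike), and the coupling current into neuron i is the ensemble average

    S_i = N⁻¹ Σ_j (V_r,j − V_i) · c_ij · |M_ij| · s_j,

with reversal potential V_r = +20 mV on excitatory and −40 mV on
inhibitory connections and no self-coupling.  The plastic weights c_ij are
initialised from N(0.5, 0.01) clipped to [0, 1].

### Plasticity

All synapses are updated event-based by spike timing-dependent plasticity.
At every spike of neuron k, each incoming synapse c_kj is paired with
partner j's most recent spike (lag Δt = t_k − t_j ≥ 0) and each outgoing
synapse c_jk with the reversed lag, using the asymmetric kernel

    Δc(Δt) = β₁ e^{−Δt/(γ₁τ)}            for Δt ≥ 0
    Δc(Δt) = β₂ (Δt/τ) e^{Δt/(γ₂τ)}      for Δt < 0

with β₁ = 1, β₂ = 16, γ₁ = 0.12, γ₂ = 0.15, τ = 14 ms and learning rate
δ = 0.002; excitatory synapses receive +δ·Δc, inhibitory ones −δ·Δc, and
weights are clipped to [0, 1].  The potentiation window is narrow
(γ₁τ = 1.68 ms) and the total depression mass dominates (kernel integrals
1.68 vs −5.04), so uncorrelated firing erodes weights while
tightly synchronized firing strengthens the short-range excitatory
couplings — the kindling/anti-kindling mechanism the package studies.
Which synapse sets an event updates is not uniquely determined by the
phrase "event-based"; this package updates both the incoming and outgoing
synapses of the spiking neuron against each partner's most recent spike
(nearest-spike pairing), the minimal bookkeeping consistent with an online
rule.

### Coordinated Reset stimulation

N_s = 4 stimulation sites sit at the centres of four equal blocks of the
chain (neurons 25, 75, 125, 175 in 1-based counting at N = 200).  Time is
organised in ON-cycles of T_s = 16 ms — deliberately close to the intrinsic
period — during which the four sites are activated sequentially in the
order of a random permutation, each occupying a slot of T_s/4 = 4 ms:

* **RVS** (rapidly varying sequence): a fresh permutation every cycle;
* **SVS-n** (slowly varying sequence): each permutation repeated for n
  consecutive cycles (n = 100 here) before the next draw.

A site activation at t_k evokes a normalized α-conductance
G(t) = ((t−t_k)/τ_s) e^{−(t−t_k)/τ_s} with time-to-peak
τ_s = T_s/(6N_s) ≈ 0.67 ms, spreading over the chain with the quadratic
profile D(i, x_k) = 1/(1 + d²(i−x_k)²/σ_d²), σ_d = 0.08·d₀.  The evoked
current is purely excitatory,

    F_i(t) = (20 − V_i) · K · Σ_k D(i, x_k) ρ_k(t) G(t),

where ρ_k is the slot indicator of site k and K the dimensionless
intensity; the total time-varying drive is I(t) = S_i + F_i.  The α-tail is
evaluated only inside the activation's own slot (at the slot end it has
decayed to 4% of peak; the indicator in the current cuts it there).
Stages may also run an ON:OFF block pattern (e.g. 3 ON cycles : 2 OFF
cycles); the default is permanent ON.

### Protocol timeline

Every run follows: 2 s equilibration (no STDP) → 60 s kindling (STDP only;
the network synchronizes and settles into its kindled state) → one or more
CR-on stages (each with its own mode, intensity, duration) → a CR-off
period as long as the total CR-on period, with STDP active throughout.
All times are reported in ms relative to CR onset.  A *sample* is one
(initial-condition seed, sequence seed) pair; the sequence RNG is consumed
only by the CR sequence draws, so samples differing only in the sequence
seed share the identical kindled network.  Batches default to 11 samples.

## Outcome measures

* **C_av** = N⁻² Σ sgn(M_ij) c_ij — population-averaged signed synaptic
  weight, recorded at 1-s cadence.
* **Phases** — between consecutive spikes a neuron's phase grows linearly
  from 0 to 2π; the phase is undefined outside a neuron's first/last spike
  and such samples are excluded (never zero-filled).  Analyses abort when
  more than 10% of the samples in an evaluation are undefined; windowed
  averages additionally drop trailing time points past the record's last
  spikes (always ≲ one interspike interval) and abort if more than 10% of
  a window is lost.
* **Order parameter** R e^{iΦ} = N⁻¹ Σ e^{iφ_j}; R_av is R averaged over
  the last 1.6 s of the CR-off period.  Subgroup order parameters restrict
  the sum to the N/N_s = 50 neurons nearest each site.
* **Acute (after-)effect** per subgroup: 1 − R̄_on/R̄_pre and
  1 − R̄_off/R̄_pre, with 10-s averaging windows (last 10 s before CR-on,
  last 10 s of CR-on, first 10 s of CR-off); positive values mean
  desynchronization.
* **Resetting index** E(Δt) = |L⁻¹ Σ_k e^{iΦ_sg(τ_k+Δt)}| over the L
  activation onsets τ_k of the subgroup's site, Δt ∈ [−32, +32] ms at 1-ms
  lags.  A post-stimulus rise of E signals a phase reset; uniformly
  elevated E signals entrainment.  E is the ν = 1 circular-moment kernel
  applied to the cross-trial phase multiset, and the implementation shares
  that kernel.
* **λ/α indices** of the inter-subgroup phase difference
  ϑ_jk = Φ_j − Φ_k (wrapped to [0, 2π), sampled at 1-ms cadence over 10-s
  windows, P = 10,000): λ^{(ν)} = |P⁻¹ Σ e^{iνϑ}| and
  α = [λ^{(4)} − λ^{(1)}]₊.  α is blind to a single concentrated peak
  (both moments ≈ 1) but detects peaks a quarter-turn apart, whose 4th
  harmonics align while their first moments partly cancel.
* **Statistics** — Tukey boxplots (quartiles by linear interpolation of
  order statistics, 1.5·IQR fences) and the one-sided Mann–Whitney U test
  (exact null for tie-free samples up to n = 12 per group, tie-corrected
  normal approximation otherwise), via scipy/numpy.

## Synthetic phase-distribution families

The calibration generator draws qZ samples (q = 4 or 3, Z = 100)
ψ_l = ((l mod q) − 1)·(π/2)·μ_l + ξ_l with μ_l = 1 for l ≤ qm and jitter
ξ_l uniform on [−ε, ε].  x = m/Z moves mass from a single peak at 0 into q
peaks a quarter-turn apart.  With ε = 0 the index curves have closed
forms — 4-peak: λ^{(1)} = 1−x, α = x; 3-peak: λ^{(1)} = 1−2x/3, α = 2x/3;
λ^{(4)} ≡ 1 for both — reproducing the limiting values α = 1 (symmetric
4-peak) and α = 2/3 (asymmetric 3-peak) at x = 1.  Uniform jitter
attenuates the ν-th moment by sin(νε)/(νε), so ε = π/4 annihilates
λ^{(4)} and drives α to ≈ 0 at every x.  Jittered curves are averaged over
20 seed replicates by default.  Note the "3-peak" family constructed this
way places its atoms at 0, π/2 and 3π/2; its printed index values
(λ^{(1)} = 1/3, α = 2/3) follow from that construction.

## Numerics

* **Integrator**: Dormand–Prince adaptive Runge–Kutta 4(5), relative
  tolerance 1e−5 (matching the original study's ODE45 setting), absolute
  tolerance 1e−7, compiled with numba.  scipy's generic `solve_ivp` is not
  used in the hot path because its per-step overhead is prohibitive at the
  segmentation this model needs; the stepper is validated against
  `solve_ivp` on single-neuron and coupled-network problems (agreement to
  ~1e−8 in V over 50 ms at matched tolerances).
* **Segmentation**: integration restarts at every site-activation onset,
  slot end and stage boundary (segments ≤ 4 ms), so the discontinuous
  indicator ρ_k never sits inside an adaptive step.
* **Spike detection**: per accepted step, downward crossings of V = 0 are
  located by bisection on the cubic Hermite interpolant; a 2-ms minimum
  interspike interval suppresses numerical double counting.
* **STDP application**: spike events are collected per segment and applied
  at the segment end in spike-time order.  Segments are short relative to
  γ₂τ = 2.1 ms, and the deferral only delays weight changes (never
  reorders pairings), so the induced error is below the integration
  tolerance in practice.
* **State hygiene**: gating/synaptic variables are clipped to [0, 1] at
  segment ends; a NaN state aborts the run with its time stamp.
* **Determinism**: fixed seeds give bit-identical spike trains on one
  platform; all RNG use goes through seeded `numpy.random.Generator`s.

## Scaled-down test conditions

The full study conditions (N = 200, 62 s of pre-stimulation dynamics, 64 s
or 128 s CR-on, 11 samples per condition) take hours of CPU time per
figure; the automated tests therefore run two reduced configurations whose
structure is unchanged:

* a **small fixture** (N = 40, sites at the four block centres, same
  d₀, σ₁, σ₂, σ_d/d₀, T_s, same STDP constants, kindling shortened to
  20 s), used for the 11-sample anti-kindling and reset/entrainment
  properties;
* the **full network with shortened kindling** (N = 200, 20 s kindling),
  used for the kindled-state and sham phase-difference checks — the
  kindled state is statistically stationary well before 20 s, so the
  shortening changes runtime, not the state.

What these tests show: the direction and mechanism of the effects (weight
and synchrony reduction under RVS CR in ≥9/11 samples; post-stimulus phase
reset under RVS vs whole-window entrainment under SVS; a sham epoch that
leaves C_av and the inter-subgroup phase difference unchanged).  What they
do not show: effect magnitudes at the published network size and stimulation
durations, boxplot-level distributions across the published conditions, or
clinical relevance; the `reproduce` CLI presets run the full-scale designs
when hours of CPU time are acceptable.

## Known limitations and observed deviations

* In this implementation the kindled state at N = 200 equilibrates at a
  time-averaged R ≈ 0.85–0.89 with the mean excitatory weight settling
  just below its initial 0.5 (the narrow 1.68-ms potentiation window
  cannot fully overcome depression at the ~1 ms heterogeneity-induced
  phase lags of the locked state).  The network is strongly synchronized
  and all stimulation effects behave as described, but a stricter reading
  of the kindled attractor — R > 0.9 with mean excitatory weight above
  0.5 — is not met; the corresponding test documents this by failing.
  The result is insensitive to integration tolerance (1e−5 vs 1e−7),
  seed, and the wrap convention.
* The sham inter-subgroup phase difference is extremely concentrated
  (std < 0.001 rad) with a small offset from 0 whose *sign* depends on the
  network realization; its magnitude (~0.05–0.15 rad) matches the
  reference behaviour.
* Axonal delays, stochastic channel/synaptic noise, structural plasticity
  and multi-compartment morphology are out of scope.
* The ON:OFF cycle pattern is supported as specified (blocks of ON cycles
  followed by idle OFF cycles); sequence draws advance only on ON cycles.
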