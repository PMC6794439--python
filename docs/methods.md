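# Methods

## The biophysical model

The astrocyte model is the De Pittà extension of the Li–Rinzel
description of IP₃-receptor mediated calcium-induced calcium release
(CICR).  Cytosolic Ca²⁺ exchanges with the endoplasmic reticulum (ER)
through three fluxes: the IP₃R channel flux
J_chan = r_C m_∞³ n_∞³ h³ (c₀ − (1+c₁)Ca), a passive leak
J_leak = r_L (c₀ − (1+c₁)Ca), and the SERCA pump
J_pump = v_ER Ca²/(k_ER²+Ca²).  The channel is gated by IP₃ binding
(m_∞, IICR), by Ca²⁺ binding (n_∞, CICR) and by a slow inactivation
variable h with steady state h_∞ = Q₂/(Q₂+Ca) and time constant
τ_h = 1/(a₂(Q₂+Ca)), where Q₂ = d₂(IP₃+d₁)/(IP₃+d₃).  The conserved
quantity c₀ couples cytosolic and ER calcium, so Ca is confined to
(0, c₀/(1+c₁)] ≈ (0, 1.688] µM.

Synaptic input enters through a leaky integrate-and-fire neuron
(τ_m = 0.1 s, R_m I_syn = 5, V_th = 1, reset 0; closed-form ISI
τ_m ln(R_mI_syn/(R_mI_syn−V_th)) = 0.1 ln 1.25 ≈ 22.31 ms).  Each
*delivered* spike adds r_AG = 0.018 µM to a 2-AG pool decaying with
τ_AG = 10 s, and IP₃ follows
dIP₃/dt = (IP₃* − IP₃)/τ_ip3 + r_ip3 AG.  Under IP₃-clamp protocols the
2-AG/IP₃ chain and the neuron are bypassed and the clamp waveform is
substituted for IP₃.

All parameters default to the published table for this model
(`AstroParams`).  Two entries need interpretation:

* **a₂ = 0.2 is taken in 1/(µM·s)** so that τ_h comes out in seconds —
  the only dimensionally consistent reading.
* **r_C (maximal CICR rate) is absent from the published table.**  The
  literature-standard value 6 s⁻¹ does *not* reproduce the published
  qualitative behaviour at the published stimulus levels: with r_C = 6
  the FM pump/leak preset (r_L = 0.11, k_ER = 0.064) has its oscillation
  onset near IP₃ ≈ 0.48 µM and is therefore silent at the 0.4 µM
  stimulus the step protocol uses.  A numerical scan over r_C shows that
  r_C ∈ [7.3, 7.9] s⁻¹ simultaneously reproduces: steady calcium at a 0.125 µM clamp,
  sustained oscillations at 0.4–0.625 µM, a damped ring-down to an
  elevated steady state at 1.2 µM, FM behaviour of the FM preset at
  0.4/0.6 µM, and AFM behaviour of the AFM preset (at r_C = 8 the
  0.625 µM clamp stops oscillating).  The default is **r_C = 7.5 s⁻¹**,
  the centre of that window; it is an ordinary config field.

The published initial conditions (Ca = 0.071006 µM, h = 0.7791,
IP₃ = 0.16 µM, AG = 0) are initial conditions only — the (Ca, h) pair is
close to but not exactly on the baseline fixed point — so every
statistic excludes a 100 s burn-in.

### Spike-driven protocol and rate scaling

With the published neuron constants the IF rate is ≈ 45 Hz; delivering
every spike to the 2-AG pool would push steady-state IP₃ to ≈ 13 µM,
far beyond the oscillatory window.  The spike-driven protocol therefore
carries a `rate_scale` (default 0.01): every 100th spike is delivered,
giving an effective ≈ 0.45 Hz endocannabinoid drive and steady-state
IP₃ ≈ 0.44 µM, inside the oscillatory regime.  The *protocol owns the
delivered spike-time list*: both the reference and the digital astrocyte
integrate the identical drive, so the comparison isolates arithmetic and
approximation error.  (The digital IF neuron is still emulated for the V
row of the report; its Euler-quantized ISI is 23 ms vs 22.31 ms exact,
which is pure spike-phase drift and the reason the V row of the
spike-driven report shows NRMSE ≈ 0.42 while every astrocyte row is
below 0.01.)

## Reference integration

Adaptive Runge–Kutta (`scipy.integrate.solve_ivp`, RK45, rtol 1e-8,
atol 1e-10, max step 1 s), restarted at every discontinuity: clamp edges
and spike deliveries, the latter realized as instantaneous additions of
r_AG to the 2-AG pool.  Output is sampled on the digital grid
(dt = 1 ms) so comparisons need no resampling.  A float64 forward-Euler
twin (`simulate_euler_reference`) steps the system in exactly the
digital update order; it separates time-discretization error (measured
< 0.1 % NRMSE at dt = 1 ms over a ten-cycle window) from
quantization/approximation error.

## The digital circuit model

* **Format.**  One global signed Q4.34 format (39 bits; range
  [−16, 16−2⁻³⁴], resolution 2⁻³⁴).  Quantization rounds half to even;
  every operation saturates instead of wrapping, and saturation events
  are counted per step (a run with > 1 % saturating steps is flagged;
  the shipped experiments produce zero events).
* **PWL tables.**  Four scalar nonlinearities are tabulated:  Q₂(IP₃)
  and m_∞(IP₃) on [0, 2] µM, n_∞(Ca) and the unit pump Hill curve
  Ca²/(k_ER²+Ca²) on [0, c₀/(1+c₁)].  Breakpoints are placed by greedy
  minimax splitting and the interpolant's maximum error is certified on
  a dense grid (≥ 1000 points per segment).  The default budget of
  2e-4 per function yields 64–128 segments and keeps the end-to-end
  calcium error near 1 % of range; the cruder 1e-3 budget also meets
  the validated envelope.  Inputs outside a table's domain clamp to the
  endpoint value — the tables never extrapolate.
* **Cubes and the h equation.**  m_∞³, n_∞³ and h³ are formed by two
  generic multiplies each (39×39→39 with low-bit truncation), matching a
  datapath that produces m_∞³/n_∞³ as named signals.  The h update is
  evaluated division-free as dh = dt·a₂·(Q₂(1−h) − h·Ca), which is
  algebraically exact — no PWL is needed for h_∞ or 1/τ_h.
* **SCM plans.**  Each constant multiply is a signed sum of arithmetic
  right shifts (≤ 19 bits), found greedily (nearest signed power of two,
  ties to the smaller term) and stopped at the 2⁻²⁰ residual or the term
  budget (26).  A brute-force search over ≤ 3-term plans serves as the
  optimality oracle in tests.  Realizable constants are multiples of
  2⁻¹⁹, so *small fused constants are relatively inaccurate*: a single
  plan for a₂·dt = 2e-4 would carry ≈ 0.1 % relative error and detune
  the oscillation frequency.  The datapath therefore chains a
  per-constant plan with one *shared* plan for dt: every state equation
  advances on the same realized dt (a common ≈ 5.5e-4 clock skew) and
  per-constant errors stay below 1e-5.  The neuron chain applies dt
  before the 1/τ_m = 10 gain so the intermediate never leaves the ±16
  range.
* **Update order** per Euler step: (1) V with raw-integer threshold
  compare and reset, (2) 2-AG (spike increment, then decay on the
  incremented value), (3) IP₃ (production reads the updated AG
  register), (4) Q₂/h, (5) gates, fluxes, Ca.  The emulator is exactly
  deterministic: identical configs give bit-identical raw integer
  streams, and a pure-Python single-step implementation is tested
  bit-exact against the compiled (numba) core.

## Readouts and decision rules

* **Peaks** are scipy `find_peaks` local maxima with prominence
  ≥ 0.05 µM (small against the 0.5–1 µM oscillations); amplitudes are
  measured peak-to-preceding-trough; frequency is the reciprocal mean
  inter-peak interval (defined only with ≥ 2 peaks).
* **Regimes.**  *damped*: ≥ 2 full-trace peaks decaying monotonically
  (the first peak is excluded from the decay test when ≥ 3 exist, since
  its "trough" is the window start), with the largest amplitude in the
  final fifth below 10 % of the ring-down start; the transient scan uses
  a 5× finer prominence because ring-down peaks are shallow.  *steady*:
  no post-burn-in peaks.  *oscillatory*: otherwise.
* **Modulation modes.**  Per-level analysis windows start 30 s after
  each clamp edge (100 s after t = 0) and are pooled per level; the call
  compares lowest vs highest level.  AM: relative amplitude change
  > 15 % with frequency change ≤ 15 %; FM: the converse; AFM: both;
  otherwise none.  The published narrative gives no quantitative
  criterion — this rule is the package's operationalization, and both
  thresholds are parameters.
* **Error metrics.**  RMSE per the usual definition; NRMSE normalized by
  the *reference* range over the window (the reference is ground truth).
  The standard window ends at the 10th reference calcium peak, where the
  accumulated error has settled; steady traces fall back to the full
  window with a recorded note.

## Known limitations

* **The AM preset does not produce amplitude-dominant modulation in this
  model.**  Exhaustive scans over r_C (6–20 s⁻¹) show the AM preset
  (r_L = 0.014, k_ER = 0.1) at stimulus levels 0.4/0.6 µM is either
  quiescent at 0.4 µM or frequency-dominant (relative frequency change
  45–145 % vs amplitude change 8–17 %); its (ΔA, Δf) pair is not
  separable from the FM preset's in the direction the AM label requires,
  under any threshold pair that still calls the FM preset FM and the AFM
  preset AFM.  The oscillation here is born through a SNIC-like onset at
  every accessible r_C, so frequency is intrinsically the sensitive
  observable near 0.4 µM.  The corresponding acceptance test is left
  failing rather than weakened; the FM and AFM presets classify
  correctly on both the reference and the digital arm.
* The model covers a single astrocyte: no gap-junction coupling, no
  glutamate/mGluR kinetics upstream of 2-AG, no channel noise.
* The emulator reproduces the datapath's arithmetic, not its cycle-level
  pipelining; register scheduling depth does not affect the numbers and
  is not modelled.  VHDL generation, synthesis and power estimation are
  out of scope.
* Problem sizes: experiments integrate 500 s of model time at a 1 ms
  step (5×10⁵ Euler steps); the ten-cycle evaluation windows end near
  142 s (spike-driven) and 245 s (FM step).
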