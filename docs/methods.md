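# Methods

`pqnfly` simulates the *Drosophila* olfactory pathway — antenna (ORNs),
antennal lobe (PNs, four LN subclasses organised around glomeruli) and
mushroom body (KCs, APL, MBON-α1, MBON-α3) plus the downstream readout
neuron SMP354 — with piecewise quadratic neuron (PQN) dynamics, kinetic
synapses, reward-driven LTD, and an 18-bit fixed-point emulation mode.
This note records the model equations as implemented, the package's own
parameter choices and their rationale, what the synthetic generators do and
do not emulate, and the numerical conventions.

## Neuron model

Every neuron is a PQN unit: nullclines are piecewise parabolas joined
C1-continuously at a branch point, so the right-hand sides contain only
additions and multiplications (hardware-friendly; no cubics or
exponentials).  Three variants are used:

* **single-compartment** (LN subclasses, APL, SMP354): membrane potential
  `v`, recovery `n`, slow variable `q`,

      dv/dt = (φ/τ)(f(v) − n − q + I_b0 + m(I))
      dn/dt = (1/τ)(g(v) − n)
      dq/dt = (ε/τ)(h(v) − q)

* **two-compartment** (KCs, MBONs): a spike-generating axonal compartment
  (`v`, `n`, no `q`) coupled to a passive soma `v_s` through the internal
  current `I_c = k_0 (v − v_s)`,

      dv_s/dt = (θ/τ)(−α v_s + I_b1 + I_c + k_r I_r)

* **PN**: the two-compartment variant with a homeostatic gain `u ∈ [0, 1]`
  multiplying the transformed synaptic drive (`u·m(I)`); `u` moves by
  `(κ/τ)(F_t − F)` once per simulated second, where `F` is the spike count
  of the completed 1-s tumbling window, and is clamped to [0, 1].

The input transform `m(I) = k_I · clip(I, m0, m1)` scales and range-limits
the summed synaptic current; `k_I` is applied exactly once (it is part of
`m`, not a second multiplier in front of it — a double application would
square the intended gain).  The derived right-branch coefficients
(`b_fp, c_fp, …`) are always recomputed from the independent ones; a
consistency check (`PQNParameters.derived_consistent`) guards stored
parameter files.

Spikes are negative-to-nonnegative crossings of `v` (`v_old < 0` and
`v_new ≥ 0`), detected on the axonal compartment.

**Integration** is explicit Euler at `dt = 1 ms`, matching a hardware
pipeline that updates every state variable once per millisecond.  All
right-hand sides are evaluated at the pre-step state and committed
synchronously, so results are independent of neuron ordering.  Euler
stability of the spiking template requires `φ/τ ≲ 300 /s` at this step; the
default parameter sets stay inside that bound.  Non-finite states raise an
error naming the neuron and time rather than being clamped silently (a
clamped float run would diverge unpredictably from the fixed-point mode).

## Parameter sets

Electrophysiological parameter fits for these cell classes (from
whole-cell recordings) are not available as machine-readable tables, so the
classes here are hand-tuned to the documented qualitative behaviours.  All spiking classes share one excitable template,

    f: a_fn=1, b_fn=−1, c_fn=0 (v<0);  a_fp=−1 (v≥0)
    g: 0 (v<0);  4·v² (v≥0)
    q unused (ε=0)

an N-shaped fast nullcline with a rectified recovery.  It rests at
`v = −1.5`, loses its fixed points at transformed drive 0.25 above the bias
(Class-I/SNIC onset, continuous F–I curve), spikes with peak `v ≈ +2` and
~8–17 ms suprathreshold width — wide enough that a single spike drives the
kinetic synapse to ≈ 0.9, the intended "single spike → amplitude ≈ 1"
calibration of the synapse model.

Classes differ in time scale, bias and gain (see `presets.py` for the
values):

* **LN subclasses**: `τ = 18 ms` sets the antennal-lobe loop period
  (≈ 25 Hz); input gains rank NP2426_class1 > Krasavietz_class1 >
  Krasavietz_class2 > NP1227_class1, making NP2426_class1 the dominant
  oscillator and NP1227_class1 a weak participant, as in the reported
  subclass-inactivation ranking.  The bias keeps LNs subthreshold on
  spontaneous ORN input so the no-odor network is quiet.
* **PN**: bias −0.6 (silent at rest at the homeostatic operating point),
  `F_t = 4 Hz` and `κ/τ = 2×10⁻³ /Hz·s`: with the six-odor cycling protocol
  (odor 1 s in every 5 s) the equilibrium gain puts odor-window firing near
  5·F_t ≈ 20–60 Hz while spontaneous firing stays subthreshold; the gain
  settles well within the 300-s warm-up (and within the shorter warm-ups
  used by the test suite).
* **KC**: high threshold (bias −1.8) so that only coincident input from
  several of its ~4.2 presynaptic PNs fires it: odors activate a sparse
  (~10 %) KC subset, sparser than the PN representation, which is sparser
  than the ORN one.
* **APL**: a non-spiking leaky integrator — a nearly linear shallow
  parabola (`f = 0.05(v−10)² − 5`, slope ≈ −1 over the operating range),
  `τ = 0.5 s`, no recovery.  Driven by all KCs and PNs it crosses the
  synaptic release threshold `v ≥ 0` a few hundred milliseconds after odor
  onset, providing the delayed global inhibition that shapes the
  post-learning MBON-α1 time course and normalises KC drive across odors.
* **MBON-α1/α3**: identical parameter sets (no separate α3 reference
  data exists, so it mirrors α1); threshold −1.0 with the shared APL
  subtraction keeps both responsive to every odor before learning, while
  the 4× LTD depression pulls α1 below threshold for the learned odor.
* **SMP354**: a slow integrator (`τ = 0.2 s`) of the MBON balance
  (excitatory α3, inhibitory α1 at a 1:1.5 magnitude ratio).  Because both
  MBONs phase-lock to the same KC rhythm, the balance is negative or zero
  whenever α1 responds; only the sustained α1 silence produced by LTD lets
  the integrator climb to threshold.  The slow membrane is what makes the
  readout robust to single skipped α1 spikes.

Class-pair synaptic scalings `p_{x,y}` carry the transmitter sign
(ORN/PN/KC/MBON-α3 positive; LN/APL/MBON-α1 negative); the four LN
subclasses share one value.  Magnitudes are the package's own calibration
against each class's fan-in, except `p_PN_KC = 1.03125`, the documented
centre value of the learning-robustness sweep.  All parameters and
scalings can be overridden from YAML (`load_params_yaml`).

## Synapses and plasticity

Chemical synapses follow the qualitative kinetic scheme
`ds/dt = α(1−s)` while the presynaptic `v ≥ 0`, `−βs` otherwise, with
`α = 250`, `β = 203.125` (decay constant `1/β ≈ 4.92 ms ≈ 5 ms`,
the measured cholinergic/GABAergic value).  ORN synapses are event-driven:
a spike sets `s = 1`, decay is the same `β`.  Synapse states are updated
after the neuron commit from the fresh `v` (stage order of the hardware
pipeline).  The input current of neuron *i* is
`I_i = Σ_j w_ji · s_j · p_{x,y}`.

Learning is reward-driven LTD of KC→MBON-α1 weights: at a reward, every KC
whose last spike lies within the preceding 5 s has its weight set to 0.25
(absolute assignment, idempotent — the hardware stores these weights in two
bits).  Eligibility uses last-spike-time bookkeeping; the window boundary
is inclusive at both ends.  No other weight ever changes.

## Network construction

Connectome-style tables are binarised at **strictly more than ten**
synapses (`w = 1`), except LN connections, which always come from the
probabilistic procedure: subclasses are assigned as evenly as possible
(191 LNs → 48/48/48 and 47 NP2426_class1), each LN innervates each
glomerulus by an independent Bernoulli draw with the subclass probability,
and edges ORN/PN→LN, LN→PN and LN→LN are created wherever the partners
share an innervated glomerulus.  Only one probability is documented
(NP1227_class1→DA1 = 75 %); the default table is flat across glomeruli
with subclass values (0.78, 0.72, 0.75, 0.70) whose mean 0.7375 reproduces
the reported LN fan-in of 1337.4 of 1815 ORNs.  The LN→PN/LN→LN direction
reuses the same innervation draw (the reported "each LN inhibits 90.9 PNs"
statistic emerges from exactly this construction).

The synthetic generator is calibrated to the published statistics: 1815
ORNs, 121 PNs, 51 glomeruli, 191 LNs, 1884 KCs (bringing the modeled total
to ≈ 2,200; the KC count itself is not published), single
APL/MBON-α1/MBON-α3/SMP354.  Reproducing *both* printed convergence
averages (1.6 PNs per ORN and 24.0 ORNs per PN) forces glomeruli with many
PNs to hold fewer ORNs; the allocator mixes single-PN and multi-PN
glomeruli and places ORNs inversely proportional to glomerular PN count,
which hits both averages in expectation (measured: 1.58 / 23.8).  PN→KC
wiring is unstructured: each KC draws presynaptic PNs Bernoulli with mean
in-degree 4.2 (minimum 1).  APL connects reciprocally with all KCs,
receives all PNs and inhibits both MBONs; every KC drives both MBONs.

What the generator does **not** emulate: real glomerulus identities and
their measured per-glomerulus innervation probabilities, the true KC→MBON
compartment map, neuron morphology or spatial structure, and any
correlation between OR tuning and glomerular size.  Passing tests
therefore show that the mechanisms (oscillation, sparsening, LTD readout)
work on a circuit with the published wiring statistics — not that the
model reproduces the responses of the real connectome instance.

## ORN input

An ORN expressing receptor *i* fires during odorant *j* at
`r = c·k_j·r_ij + r_spo` Hz with `c = 192`, `r_spo = 8 Hz` and
`r_ij, k_j ∈ [0,1]` (maximum 200 Hz); spikes are Bernoulli(`r·dt`) per 1 ms
step, with no refractory period.  Between presentations every ORN fires at
`r_spo`.  Concentrations `k_j` default to 1 (the study's values are not
published) and are overridable per odorant.

The DoOR-style synthetic tuning table gives each odorant a strong OR
subset (fraction 0.25 of receptors, intensities uniform in [0.6, 1]) over
a weak background (uniform in [0, 0.08]); strong sets are drawn
independently per odorant, giving distinct sparse KC codes with ~25 %
pairwise overlap.  The three protocols: (1) six odors, 1 s on, one every
5 s, cycling; (2) one odorant 10 s on every 20 s; (3) the panel at
10 s/20 s.  Every run begins with protocol-1 cycling (default 300 s)
during which PN homeostasis settles.

## Analyses

* **Virtual LFP**: the mean synaptic current `s` over a class (or LN
  subclass).
* **Power spectra**: mean-removed Welch estimate, 1-s Hann segments, 50 %
  overlap; the peak is taken over 5–100 Hz.  The segment length resolves
  20–30 Hz peaks over a 10-s odor window; the linear-domain average of
  peak powers over repeats is reported.
* **Firing-rate time courses**: spike counts over 50 ms tumbling windows,
  averaged across trials where applicable.
* **Inactivation**: the accumulated stimulus input `I` of the targeted
  class is forced to zero each step.  In the experiment drivers the
  branched conditions (control, no-odor, per-subclass inactivation) share
  one homeostatic warm-up and differ only in the measurement window, so a
  20-repeat peak-power experiment costs one warm-up plus 20 × 10 s.
* **Learning experiment**: conditioning presents the target odorant for
  1 s and delivers the reward 3 s after onset (within the 5-s eligibility
  window either way); each trial presents all six odors for 1 s each at
  5-s spacing in a seeded random order, and succeeds when SMP354 spikes
  (≥ 1) in the learned odor's window and in no other.  The ≥ 1 criterion
  is the smallest unambiguous one: SMP354 is silent before learning.  The
  full protocol (and the acceptance check) averages the success rate over
  sets with different learned odorants; per-odorant rates vary because
  odorant pairs whose strong-OR sets overlap heavily are intrinsically
  confusable (on the default tuning-table realisation, five of the six
  odorants learn at 0.7–1.0 while the one with a heavily overlapping
  partner fails its trials on the partner's window).

## Fixed-point emulation

The hardware mode holds every state variable, synaptic state and
accumulated input in an 18-bit two's-complement word with 10 fractional
bits (range [−128, 128 − 2⁻¹⁰], resolution 2⁻¹⁰ ≈ 0.001).  Stage results
are computed in float64 and quantized once at each register boundary —
round-half-even by default, with a truncation option mimicking plain right
shifts; saturations are counted and reported.  Constant multiplications
decompose exactly into signed right-shift sums (`plan_shift_add`).  The
authors' exact rounding and accumulator widths are not published, so the
emulator documents its own convention rather than claiming bit-identity
with the FPGA.  Empirically, fixed-mode trajectories track float64 within
~50 × resolution on smooth segments; on limit cycles the quantization
error diffuses into a phase shift, so long-horizon comparisons are made on
rates (within a few percent), not on instantaneous states.

## Numerical conventions and degenerate inputs

* Branch points evaluate on the right ("≥") branch; continuity makes the
  value identical and the derived coefficients make the slopes agree.
* Synaptic states below 10⁻¹² are flushed to zero (multiplicative decay
  otherwise reaches the denormal range, which is orders of magnitude
  slower on commodity FPUs without changing any result).
* The compiled inner loop (numba) and the pure-numpy reference path
  implement the identical update order; they agree to ~10⁻¹³ in state and
  are cross-checked in the test suite.  The reference path serves the
  fixed-point mode and any topology whose ORN block does not factor
  through glomerulus sums (the factorisation is verified exactly before
  use and only ever changes the cost, never the result).
* All state variables start at zero.  The all-zero initial condition is
  suprathreshold for some classes and produces a brief deterministic
  transient; every experiment therefore begins with a warm-up.
* `dt = 0` is a legal no-op; `m0 > m1`, zero right-branch curvatures,
  unknown neuron ids, missing scaling entries and missing innervation rows
  raise typed errors.

## Problem sizes in the test suite

The packaged tests run the full-width antennal lobe (1815 ORNs, 121 PNs,
191 LNs) with the full 1884-KC mushroom body for the oscillation and
learning suites, but shorten the homeostatic warm-up to 60 s (the gain
settles within ~30 s at the default κ), two trials per learned odorant
(all six) per learning condition, and three repeats per spectral
condition.  The CLI defaults keep
the full 300-s warm-up, 10 sets × 10 trials and 20 repeats of the
published protocols.

## Known limitations

* The peak oscillation frequency is a network property of the hand-tuned
  LN parameters; comparable data-driven models sit at ≈ 24 Hz against
  10–15 Hz in vivo (glomerular dynamics are not modeled in either).
* Per-odor learning difficulty varies with the synthetic OR table: odors
  whose strong-OR sets overlap heavily are harder to discriminate, so the
  success rate depends on the tuning-table seed in a way the published
  DoOR-based runs do not.
* The dopaminergic reward pathway is an external event signal, not a
  modeled circuit.
* The fixed-point mode emulates arithmetic semantics, not the FPGA's
  pipeline timing, memory layout or serial protocol.
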