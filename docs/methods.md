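# Methods

## The model in brief

`granulayer` simulates a patch of the cerebellar granular layer as a sheet of
1,024 granule-cell clusters (grcs) and 1,024 Golgi cells (Gocs) on a 32×32
grid with 35 µm spacing (a 1,085 × 1,085 µm² sheet).  Each model grc stands
for a cluster of roughly a thousand real granule cells sharing a glomerulus.
Mossy-fiber input is a noiseless, piecewise-constant current injected into
every grc soma.  Granule axons (parallel fibers, PFs) excite Goc dendrites
through AMPA (rise/decay 0.03/0.5 ms) and NMDA (5/100 ms) conductances; Gocs
inhibit grc somata through GABA_A conductances (5/100 ms).  The NMDA channel
is gated by the voltage-dependent Mg²⁺ block, so the network's inhibitory
loop changes character with both the input current and the extracellular
Mg²⁺ concentration:

* **small current** (10.7 pA): grcs and Gocs fire in synchronized volleys at
  ~9 Hz — the oscillatory state;
* **large current** (22.7 pA): dendritic NMDA channels open and sustain
  Golgi firing, and the random wiring turns the population into a drifting,
  non-recurrent sequence of active clusters — the passage-of-time (POT)
  code;
* **high Mg²⁺** (13 mM): NMDA is blocked, inhibition weakens, and the grcs
  fire fast and uniformly;
* **very low Mg²⁺** (0.013 mM): NMDA is always open, Golgi cells dominate,
  and the oscillation is disrupted.

A simple spiking Purkinje cell (PC) reads the POT code out: binary
depression of the PF→PC weights of clusters active 50–100 ms before a
reinforcement signal carves a correctly timed pause into the PC response —
the delay eyeblink-conditioning readout.

## Connectivity

A Goc's dendritic field (diameter 315 µm) intercepts the PFs of every grc
whose sagittal (row) coordinate lies within 157.5 µm: up to 9 rows × 32
columns = 288 candidates, clipped at the sheet edges (no wraparound).  A
Goc's axonal field (also 315 µm) reaches the 69 grid nodes within a
Euclidean distance of 157.5 µm (inclusive, so the boundary ring counts; the
analytic estimate π(315/2)²/(35−1)² + 1 = 68.4 approximates the lattice
count).  Ten percent of the candidates are realized.  Two sampling schemes
are implemented:

* `bernoulli` — every candidate edge kept independently with p = 0.1; this
  is the scheme behind the reference in-degree statistics (means 26.8 PF
  inputs per Goc, 6.11 inhibitory inputs per grc, with binomial spread);
* `exact` — each target receives exactly `round(0.1 · candidates)`
  partners.  The default simulation network (`default_network`) uses this
  scheme.

The default model also normalizes each target's total synaptic conductance
by its in-degree (`normalize_inhibition` / `normalize_excitation` = 1):
per-connection peaks are scaled by `mean_degree / degree`.  The rationale is
the cluster interpretation: a model "synapse" aggregates hundreds of real
contacts, and the aggregate inhibitory conductance a glomerular cluster
receives is treated as homeostatically fixed, divided among its connected
Gocs.  Practically, this homogenizes the granule recovery times after an
inhibitory volley.  Without it the log-normal spread of recovery times
(the GABA conductance decays exponentially, so recovery time goes as the
logarithm of the synaptic load) disperses the population within a few
cycles and no parameter setting we explored sustains the 9 Hz rhythm.
WHICH cells connect to WHICH remains fully random — the quenched wiring
disorder that generates the burst–silent alternation is untouched: with
every candidate edge present (and conductances rescaled to keep the total
load fixed) the POT index drops well below the random network's, the
control for the role of wiring randomness.

## Cell models

All spiking compartments share one surrogate kinetic scheme: Traub–Miles
transient Na (m³h) and delayed-rectifier K (n⁴) gates, plus a
spike-triggered afterhyperpolarization (AHP) conductance with K reversal
that increments at each spike and decays exponentially.  Gate kinetics are
evaluated through lookup tables (0.05 mV grid) of the steady state and the
per-step decay factor.  Spikes are upward crossings of 0 mV with a 1 ms
lockout; they are events for the raster and for synaptic propagation,
independent of the biophysical AHP.

**Granule cluster** — one compartment: C = 3.1 pF, g_leak = 1.1 nS,
E_leak = −70 mV, g_Na = 300 nS, g_Kdr = 100 nS, AHP 0.65 nS / 8 ms.
Calibrated against two anchors: silent at zero current with rheobase just
below 7 pA, and 44 spikes/s under a constant 10.7 pA when inhibition is
removed.  The f–I curve is monotone up to at least 60 pA.

**Golgi cell** — a soma (C = 30 pF, g_leak = 3 nS, g_Na = 2,000 nS,
g_Kdr = 700 nS, AHP 40 nS / 16 ms) coupled through 8 nS of axial
conductance to one passive dendrite (C = 20 pF, g_leak = 8 nS) representing
the 300 µm dendritic shaft that carries all AMPA and NMDA input.  The leak
reversal is drawn uniformly in [−60, −50] mV per cell (heterogeneity of the
Golgi population).  The Na/K kinetics of the Goc soma are shifted +18 mV
along the voltage axis (a different channel-isoform mix), which places the
spike threshold above the leak-reversal band: Golgi cells are silent at
rest and fire only when a coincident PF volley or sustained dendritic NMDA
current drives them.  This shift is a central calibration choice: with the
unshifted kinetics the depolarized Gocs free-run at 7–14 Hz, and their
uncorrelated firing both suppresses the grcs and prevents volley
entrainment.  The axial coupling leaves the dendrite electrically
semi-isolated: a somatic AHP event attenuates an NMDA-sustained dendritic
depolarization by less than 50% (tested).

**Purkinje cell** — a single Hodgkin–Huxley-style soma (C = 100 pF,
g_leak = 10 nS, g_Na = 7,000 nS, g_Kdr = 2,300 nS, kinetics shifted +5 mV
so the rest state is stable without drive, AHP 25 nS / 20 ms so the f–I
curve is graded rather than all-or-none) driven by the conductance
`g_pf · Σᵢ wᵢ xᵢ(t)` with reversal 0 mV, where xᵢ are 30 ms exponential
spike traces.  `g_pf` is never hand-set: it is bisected until the maximum
CS-driven rate (100 ms sliding window, all weights 1) is 100 ± 2 spikes/s.
Integrated with first-order explicit Euler at 20 µs.  The graded f–I is
essential for the conditioning readout: depressing ~40% of the weights
lowers the drive everywhere, and only an adapting cell keeps firing through
the shallow part of the drop while pausing in the deep, timed dip around
the reinforcement.

## Synapses and the Mg²⁺ block

Synaptic conductances are dual exponentials
`g_peak · norm · (e^{−t/τ_d} − e^{−t/τ_r})`, peak-normalized, integrated as
two exponential state variables that receive unit increments per
presynaptic spike (exact at the sample times; verified against the closed
form to < 10⁻⁶ relative error).  Per-connection peaks (before in-degree
normalization): GABA_A 0.075 nS at −75 mV on the grc soma; AMPA 15 nS and
NMDA 4 nS at 0 mV on the Goc dendrite.  The AMPA and NMDA peaks are
cluster-scale: one presynaptic "spike" stands for a near-synchronous volley
of hundreds of real parallel fibers.

The NMDA open fraction is the sigmoid `1 / (1 + ([Mg]/k₀) e^{−V/V_s})` with
k₀ = 3.57 mM and V_s = 9 mV, evaluated at the dendritic potential.  The
functional form is the standard single-exponential block; the voltage scale
is steeper than the classic 16.13 mV fit.  This steepness is the second
central calibration choice: it is what separates the two dynamical regimes.
At rest (−55 mV) the open fraction is ~0.2%, so the sporadic volleys of the
oscillatory state leave NMDA silent; under the large current the dendrite
sits depolarized and the open fraction rises two orders of magnitude,
sustaining the Golgi inhibition that randomizes the grc population.  With
the shallower 16.13 mV scale no NMDA peak conductance achieves both: either
the oscillatory state is poisoned by resting NMDA current, or the POT state
starves.  Both k₀ and V_s remain configurable.

## Numerical integration

Compartment voltages advance by Crank–Nicolson (the two Goc compartments
through the 2×2 coupled solve) with conductances frozen over the step and
gates updated semi-implicitly from the pre-step voltage via the tables;
exponential Euler is available as a secondary integrator and agrees with
Crank–Nicolson on spike times to < 1 ms on a toy network when run at 2 µs.
The default step is 20 µs; halving it changes population rates by < 2%.
Synaptic and axonal delays are zero: they are far below the 100 ms
inhibitory kernel that sets the rhythm.  Initial conditions:
membrane potentials at the leak reversal, gates at steady state, synapses
empty; no settle time is discarded.  The common initial condition makes the
stimulus onset a global reset — the mechanism behind the perfect early
reproducibility of the POT code across trials.

The network kernel is compiled with numba; a 6 s protocol of the full
default network (300,000 steps, 2,048 neurons) runs in well under a minute
on one core.

## Population metrics

All metrics operate on 1 ms binary bins (stability under 0.5–2 ms checked
in the tests).

* **NAC(τ)** — normalized autocorrelation of the fluctuation of the number
  of active cells per bin; lag average over the valid (non-wrapping)
  overlap, lags up to min(1 s, T/2).
* **OI / f_max** — the Fourier cosine transform
  `C(f) = Σ_τ NAC(τ) cos(2πfτ) Δτ` is evaluated on a 0.25 Hz grid over
  2–100 Hz; `f_max` is the lowest frequency within 5% of the maximum (a
  sharply periodic NAC carries equal power at every harmonic).  OI is the
  height of NAC at the recovered period — the maximum of NAC within ±25%
  of 1/f_max — clipped to [0, 1].  A pure cosine and a periodic volley
  train both score 1; a flat or delta-at-zero NAC scores 0.
* **SI(τ)** — cosine similarity of the 30 ms-decay trace vectors at times
  t and t+τ, averaged over t with lag pairs inside the window; bins with a
  zero population vector are excluded and counted in a QC report.
* **PI** — an unconstrained least-squares Gaussian fit
  `(a−b)·e^{−τ²/2σ²} + b` of SI(τ) (seeded from SI(0), min SI, and the
  half-width at half height); the height from the fitted value at τ = 0
  down to the fitted minimum on the grid, divided by 0.376 (the largest
  height observed anywhere in the [Mg²⁺] × I_MF plane) and clipped to
  [0, 1].
* **RI(t)** — cosine similarity between the trace vectors of two aligned
  trials at the same time from stimulus onset.

Each definition is pinned by analytic fixtures (periodic, Poisson,
drifting, two-trial generators in `granulayer.fixtures`) whose metric
values are known in closed form, and the NAC pipeline is checked against a
brute-force O(bins²) autocorrelation to 10⁻¹⁰.

## What the synthetic fixtures do and do not show

The fixture generators emulate the *statistical signatures* the metrics
must detect — perfect periodicity, Poisson independence, non-recurrent
turnover with a known lifetime, trial divergence at a known time — not the
biophysics that produces them.  Passing the fixture suite validates the
measurement pipeline; it says nothing about whether the network itself
reaches a given dynamical state.  That is what the full-network
reproduction tests are for.

## Calibration summary and known gaps

With no tabulated reference kinetics available, every channel constant is a
surrogate, and the network was calibrated against the behavioural anchors:
the 44 spikes/s disinhibited granule rate, the ~9 Hz small-current
oscillation, the POT drift under the large current, the ~32 spikes/s
high-Mg²⁺ firing, and the 100 spikes/s PC ceiling.  The frozen defaults are
a deliberate compromise between the two regimes, which pull the Golgi
refractory dynamics in opposite directions (the oscillation wants a long
AHP "clock", the POT state wants fast NMDA-driven firing).  Known gaps of
the calibrated model, all visible in the test suite and the acceptance
report rather than hidden:

* the small-current oscillation runs at 8.0 Hz (low end of the target
  band) and its oscillation index over a 0–2 s window is ~0.75 rather than
  0.84 — the first few cycles after stimulus onset are faster than the
  steady rhythm while the inhibitory conductance charges up, and that
  transient drags the window-wide autocorrelation peak down (the steady
  rhythm alone scores ~0.9);
* the POT index measured inside the full protocol (large-current epoch
  entered *from* the oscillatory state) is ~0.6–0.7: a residual coherent
  rhythm survives the current step, whereas the same parameters reach
  0.88–0.93 when the large current starts from rest;
* after the large-current epoch the network does not rejoin the
  oscillatory limit cycle — that attractor is reachable from the
  synchronized onset reset but not from the asynchronous post-POT state;
* under fully open NMDA (0.013 mM Mg²⁺) the granule population is
  suppressed to ~1 spikes/s and retains no measurable oscillation, a
  deeper disruption than the reference value of ~0.2;
* the conditioned PC pause ends ~0.75 s after CS onset for a 0.75 s
  interval (instead of ~0.91 s): the model's burst epochs are shorter than
  the reference, so zeroing the clusters active 50–100 ms before the
  reinforcement removes drive over a narrower window.  The ordering of
  pause ends across intervals (0.5 < 0.75 < 1.0 s) is correct.

## State map

`statemap.sweep` runs a constant-current simulation per ([Mg²⁺], I_MF) grid
cell (default 2 s per cell, cached on disk by configuration hash so an
interrupted sweep resumes) and classifies each cell: **II** (POT) when
PI ≥ 0.5 at a 1–20 Hz granule rate, **I** (oscillation) when OI ≥ 0.5,
**III** (metastable) when the first quarter-window oscillates but the full
window drifts, **IV** (uniform) otherwise.  Thresholds are configurable;
the defaults follow the boundary where the POT domain opens up.  The
default desk-scale grid is coarser (~7×7) than an exhaustive map.

## Non-goals

No gap junctions between Golgi cells, no LFP synthesis, no mossy-fiber
spike-train input mode (drive is a current by construction), no plasticity
inside the granular layer, no multi-compartment dendritic trees, and no
stochastic channel gating.
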