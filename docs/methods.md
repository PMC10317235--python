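# Methods

## The model

The package simulates the honey-bee antennal lobe (AL) as 20 glomeruli,
each housing 3 uniglomerular projection neurons (PNs) and 5 inhibitory
local neurons (iLNs) — 160 neurons in total.  The only synapses are
GABAergic: each iLN inhibits every glomerulus independently with
probability 0.25 (its home glomerulus included).  A successful contact
onto a foreign glomerulus reaches all 8 of its neurons; a contact onto
the home glomerulus reaches only the 4 sibling iLNs, never the home PNs
or the iLN itself.  Under this rule an iLN inhibits on average
20 × 0.25 = 5 glomeruli and a glomerulus receives inhibition from
(95 + 5) × 0.25 = 25 distinct iLNs; the probability that one glomerulus
sends no inhibition to another is (1 − 0.25)⁵ ≈ 0.237.  These closed
forms are what `scripts/acceptance.py` re-derives by Monte Carlo.

Each neuron is a two-compartment Hodgkin–Huxley cell (soma + axon,
units mV/ms/nF/µS/nA).  The soma carries a calcium current I_Ca
(activation m³ with a voltage factor f_Ca(V) = 1/(1+exp((2+V)/24.4)), a
reversal of 0 mV), a transient potassium current I_A, the synaptic
current, optional membrane noise, and the odor input; the axon carries
I_Na (m²h, Traub-style rate functions with threshold shifts V_t), the
delayed rectifier I_Kd and a calcium-dependent I_KCa.  Intracellular
calcium follows d[Ca]/dt = 0.001(−0.35 I_Ca − MU·[Ca] + 0.04 MU²), so
[Ca] integrates spiking on a ~600 ms timescale — the model's analogue
of the ratiometric imaging signal.

Synapses are driven by the presynaptic axon potential and are shared by
all targets of an iLN.  The GABA-A gate opens at a rate
K_f σ((V_pre − 30)/2) and closes with τ = 1/K_r = 10 ms: a fast,
pulsatile inhibition locked to presynaptic spikes.  GABA-B is a
two-stage second-messenger cascade (h activated at σ(V_pre/2), m
integrating K₃h − K₄m with τ ≈ 400 ms) whose current passes through the
transfer m/(m + K_d), K_d = 100.  With the tabulated rate constants the
messenger saturates near m ≈ 120, so the transfer operates around 0.55
and rises over roughly a second — the slow tonic inhibition.  The
first-power transfer is the default (`gabaB_hill = 1`); the canonical
fourth-power form is selectable but switches on within tens of
milliseconds here, which is too fast for the slow component this
receptor is meant to carry.

Odor input is a 4-s square pulse with exponential sensory adaptation,
I = I₀·sc·exp(−rate·(t−t₀)/1000), injected identically into every
neuron of each recruited glomerulus (sc = 0.7 for PNs, 0.5 for iLNs).

## Parameter choices that matter

All tabulated constants (capacitances, leak, coupling, thresholds, MU,
sc, rate, GABA kinetics) are the published values and sit on
`CellParams`.  Three families of choices were genuinely open and are
worth recording:

**Maximal conductances.**  The per-ion ḡ values are not part of the
published parameter table.  The defaults (PN: ḡ_Na = 1100, ḡ_Kd = 450,
ḡ_Ca = 30, ḡ_A = 50, ḡ_KCa = 8 µS; iLN: ḡ_Na = 1800, ḡ_Kd = 1000,
same others) were calibrated once against four requirements: a stable,
quiescent rest at zero input; repetitive firing of a PN under a
sustained 7 nA input; spike rate and calcium monotone in the input over
0–100 nA; and a return to rest after stimulus offset.  iLNs need the
higher Na density because their axon is only weakly coupled to the
soma (g_AS = 10 µS vs 65 µS for PNs) and must still overshoot the
+30 mV transmitter-release threshold.

**The delayed-rectifier gate power.**  The rectifier uses the classical
n⁴ activation rather than a first power.  With n¹ and these rate
functions the cell cannot work at all: the resting activation of the
gate (~8%, because the leak reversal of −45 mV sits just above the
−52 mV threshold potential) shunts any realistic input when ḡ_Kd is
large, while a small ḡ_Kd cannot outweigh the Na window current near
−30 mV (m∞ and h∞ overlap there), which then traps the slow membrane
(τ ≈ 60 ms) in a stable depolarized plateau.  Raising the gate to the
fourth power removes the resting shunt (0.08⁴ ≈ 4·10⁻⁵) while keeping
the depolarized brake, and is the one reading under which the model
both rests and spikes.  Powers and reversals are configurable per ion.

**Calcium-gate half-activation.**  The Ca activation is centred at
−39.1 mV (a high-voltage-activated channel engaged by spikes), with the
mirrored reading (+39.1 mV) selectable via `CellParams.mca_half`.  At
+39.1 mV the gate only opens above the spike peak and [Ca] never moves,
which contradicts the intended role of [Ca] as the imaging-comparable
readout.

**Synaptic strengths.**  The four per-edge conductance scalars
(receptor × target role) default to gA = 1.0 µS and gB = 0.1 µS.  At
this working point the two receptor families reproduce their
experimental temporal fingerprints: zeroing gA (the picrotoxin analog)
adds response mostly in the early frames, peaking 250–375 ms after
onset, while zeroing gB (the CGP54626 analog) adds a slowly growing
component peaking near 1375 ms.  gA must be roughly tenfold gB because
the fast gate is open only a few percent of the time (τ = 10 ms,
presynaptic rates of tens of Hz) whereas the GABA-B transfer is tonic.
These scalars are the axes of the `sweep_gaba` grid search, which
scores each setting against a reference pattern with the greedy
similarity index and annotates every cell with the realized mean
inhibitory current per target role (the mapping from conductance to
current is state-dependent, so it is measured, not assumed).

## Numerics

Fixed-step classical Runge–Kutta (RK4) at dt = 0.02 ms in a compiled
(numba) kernel; halving dt moves the final membrane state by well under
0.1 mV on subthreshold protocols.  Initial state: V = V_L, gates at
their V_L steady state, [Ca] at its fixed point 0.04·MU, synaptic gates
zero; a 500 ms settling period precedes t = 0 and is discarded.  HH
gates are clamped to [0, 1] and [Ca] to ≥ 0 after every step; the
removable singularities of the Traub rate functions are evaluated by
their limits.  Membrane noise, when enabled, is a seeded
Euler–Maruyama increment on the soma potential (default off; every
analysis here is deterministic given its seeds).  A |V| > 200 mV
excursion aborts with `SimulationError`.

Analysis frames: model calcium is averaged over the 3 PNs of each
glomerulus and binned to 8 Hz (125 ms frames; a 10 s run gives exactly
80 frames).  The two analysis windows are single frames 3 and 11 frames
after odor onset (375 ms and 1375 ms), with an optional ±1-frame
average.  Times-to-peak are quantised to the frame grid.

Problem sizes: figure-level experiments default to a reduced protocol —
2.5 s total, 1.5 s odor from t = 0.5 s — which contains both analysis
windows; the full 10 s protocol is available and used for
imaging-parity checks.  The gain-curve and recruitment sweeps default
to three topology seeds per cell; the test suite uses one.

## Imaging analysis conventions

Delta(340/380) is the 100×(F340/F380) ratio minus its mean over the
eight frames of the second before odor onset.  Normalisation divides by
the saline-series maximum (per glomerulus or per bee); blocker series
may exceed 1.  The logistic concentration-response model is
Delta = a/(1 + exp(c − b·x)) with x the log10 dilution; the dynamic
range is DR = EC90 − EC10 = 2 ln 9 / b and the sensibility
Sens = 0.8 a / DR.  The mineral-oil blank has no defined log
concentration and is excluded from fits.  A glomerulus is "recruited"
when its mean response over the odor window exceeds twice the SD of its
pre-onset baseline (the window mean, rather than the maximum, keeps the
criterion unbiased under frame noise).  Pairwise pattern correlations
use Pearson r between 11-glomerulus vectors at an analysis frame;
Fisher z = atanh(r) with |r| clipped below 1; pairs are pooled by
nominal dilution ratio (the half-decade ladder's 10^0.48 and 10^0.52
snap to the 3–10–30… series).  The similarity index greedily matches
reference traces to model traces by highest Pearson r, each trace used
once, and averages the matched correlations; constant traces have
undefined correlation and are matched last with a nan contribution.
Because the matcher selects maxima, the index carries a positive
selection bias of order 1/sqrt(frames) even between independent trace
sets (≈0.2 at 80 frames); comparisons should always be made against
the self-similarity value 1, not against 0.

## The synthetic-data generator

The generator emulates the statistical structure of the recordings, not
their biophysics.  Per bee and series it produces 10 measurements (the
9-step dilution ladder plus a blank) of 11 glomeruli × 80 frames.
The noise-free response of a glomerulus is an amplitude times a
temporal profile.  The profile is a rise-and-adapt kernel multiplied by
(1 − fast bump − slow bump), unit-peak alpha functions peaking 375 ms
and 1375 ms after onset: these are the fast (GABA-A-like) and slow
(GABA-B-like) suppression components, removed by the PTX and CGP
conditions respectively.  The amplitude interpolates between two
regimes: with inhibition intact, a *stabilized* pattern — the
subtractively thresholded response pattern at a mid-ladder reference
concentration (1/100), scaled by a common gain curve and bounded above
by the glomerulus's own tuning; with inhibition blocked, the raw
per-glomerulus logistic tuning.  The default tuning has a sensitive
core group (EC50s spread over the lower ladder), a strong low-affinity
"late" group that only rises at high concentration, and two weakly
responsive glomeruli.

This structure encodes the phenomenology the analyses are meant to
detect, with known ground truth: blocker-minus-saline traces peak near
375 ms (fast removal) or 1375 ms (slow removal); the saline pattern is
concentration-stable (high cross-concentration correlation) while the
disinhibited pattern grows and rotates as the late group is recruited
(lower correlation, recruitment rising to 100%); sensibility rises
several-fold when inhibition is removed.  Two deliberate departures
from idealised behaviour: the fitted dynamic range widens under full
blockade (recruitment of the late group flattens the population
dose-response curve — under a purely multiplicative suppression DR
would be exactly invariant, but that form cannot produce the
correlation and recruitment signatures), and all variability is i.i.d.
Gaussian frame noise plus per-bee amplitude/EC50 jitter.  What passing
tests show is therefore that the *pipeline* recovers effects of this
size and structure from data of this geometry — not that real
recordings contain them.

## Known limitations

The network model's excitable regime rests on a calibrated conductance
set and two de-mangling decisions (rectifier gate power, Ca gate
centre) that published material leaves underdetermined; all are
configuration values, and conclusions should be checked against
alternative readings where they matter.  iLNs can keep firing for a few
hundred milliseconds after a very strong stimulus (≥70 nA input) ends;
PN calcium, which every analysis reads, is unaffected.  Per-edge
synaptic heterogeneity, excitatory local neurons, gap junctions and
presynaptic inhibition are out of scope, as in the underlying model.
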