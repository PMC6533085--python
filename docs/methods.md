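# Methods

`gcmli` re-implements, as a tested pipeline over synthetic data, the analysis
of short-term plasticity (STP) at unitary cerebellar granule-cell (GC) →
molecular-layer-interneuron (MLI) synapses: charge extraction from EPSC
trains, noise-referenced failure detection, minimal-stimulation quality
control, PCA + k-means phenotyping of STP profiles with knockout-cohort
projection, photostimulation charge/latency analysis, and docked-vesicle
morphometry.  Because no raw recordings are available, a quantal-release
simulator provides the inputs; its statistical structure — not any specific
recorded trace — is what the analysis is validated against.

## Quantal release model

Each synapse is a set of `n_sites` independent release sites, each occupied
or empty.  At stimulus time *t* the number of released quanta is

    k ~ Binomial(occupied, min(1, p_fr + f))

where `p_fr` is the resting release probability of a fully-releasable
vesicle and *f* is additive facilitation: after every stimulus `f` grows by
`facil_increment` and relaxes as `exp(-Δt/tau_facil)`.  Released sites refill
from the reluctant/reserve supply with probability
`1 − exp(−Δt·reluctant_gain/tau_recovery)` per inter-stimulus interval; the
gain term expresses the recruitment of reluctant vesicles by high-frequency
drive, so pool refilling is faster inside a 100 Hz train than at rest.
Trains are simulated independently because the inter-train interval (one
minute in the emulated protocol) vastly exceeds `tau_recovery`.

Two limits anchor the model: with `facil_increment = 0` and
`tau_recovery = ∞` the mean profile is purely depressing (non-increasing);
with instant refill and positive increments it is purely facilitating
(non-decreasing).  Because release and refill are linear in the occupancy and
facilitation evolves deterministically, the expected per-stimulus quanta obey
an exact mean-field recursion (`mean_release_profile`); tests use it as an
independent oracle against Monte-Carlo means.

Released quanta are rendered as negative-going biexponential EPSCs,
`A(e^{−t/τ_d} − e^{−t/τ_r})`, normalized analytically so the time integral of
one quantum equals `q_charge` (fC; 1 pA·ms = 1 fC).  Defaults: τ_r = 0.4 ms,
τ_d = 2.0 ms — fast GC→MLI kinetics chosen so that ≥ 99% of a quantum's
charge falls inside the 10 ms inter-stimulus integration window — sampling at
50 kHz, Gaussian baseline noise with SD set to one tenth of the
single-quantum peak (peak SNR 10), and mean-preserving lognormal quantal
size variability with CV 0.2.  The quantal CV matters: without it a
uniquantal synapse's measured charges form a two-point lattice and
aggregated profiles become degenerate.

## Class archetypes

Four archetypes reproduce the qualitative class phenotypes: C1, large initial
release that facilitates once then depresses (10 sites, p = 0.50, strong
increment with 40 ms refill); C2, facilitation peaking near the 3rd–4th pulse
then declining (12 sites, p = 0.15, slow 60 ms refill); C3, slowly building
sustained facilitation (12 sites, p = 0.15, slow 150 ms facilitation decay
with strong reluctant-pool gain); C4, uniquantal with small but stable
responses from the 2nd pulse on (1 site, p = 0.45, rapidly saturating
facilitation and near-instant refill).  Parameters were calibrated once
against shape predicates evaluated on the exact mean-field profile (largest
first response and post-2nd-pulse depression for C1; paired-pulse ratio
> 1.5 with a mid-train peak for C2; sustained 10th-pulse charge ≥ 80% of
maximum for C3; ≤ 1.5 max/min stability from pulse 2 for C4), with absolute
charges ordered C1 > C2 ≈ C3 > C4.  Within-cohort diversity comes from
seeded lognormal jitter (5% on probabilities and charges, 7.5% on time
constants, ±1 site).

The synapsin-II-knockout regime multiplies `p_fr` by 0.5 and removes a
quarter of the sites while leaving refill dynamics untouched, reproducing the
phenotype of reduced initial release probability, increased first-stimulus
failures and elevated paired-pulse ratio without impaired reluctant-pool
recruitment.

## Charge extraction and failure detection

Per sweep, the baseline is the mean over a fixed 300 ms pre-stimulus window
and the noise SD σ is measured on the same window.  A stimulus is a failure
when the peak negative deflection in a 1–9 ms post-stimulus search window
stays below 3σ.  The peak search runs on a lightly smoothed copy of the
trace (0.3 ms moving average, configurable): with raw 50 kHz white noise a
400-sample minimum would cross 3σ about 40% of the time, making the bare
rule useless; after smoothing the false-success rate is negligible while a
single-quantum EPSC (peak 10σ, width ≫ 0.3 ms) is essentially never missed.
Charges are trapezoidal integrals of the baseline-subtracted magnitude from
each stimulus to the next (the last window equals the inter-stimulus
interval); failures contribute their measured near-zero integral, never an
imputed zero.  A configurable artifact-blanking interval exists for real
recordings and defaults to zero.

## Minimal-stimulation QC

The acceptance rules for a stimulation intensity are implemented verbatim:
success rate at stimulus 1 must exceed 0.4, and a series is flagged for (i)
systematic first-stimulus failures, (ii) a failure rate rising at the second
stimulus, (iii) no relief of a high (0.3–0.6) first-stimulus failure rate at
the second stimulus, (iv) any train whose first-stimulus charge exceeds five
times the median over detected-success trains, and (v) any per-train
paired-pulse ratio above 4.  Rule (iv) uses the success median because the
rule screens amplitude jumps (fiber recruitment) and failures carry no
amplitude; with high-failure synapses an all-train median is just the noise
integral.  The chosen intensity is the lowest accepted one.  In the synthetic
pipeline the rules are reported as per-synapse flags but no synapse is
dropped: the artifacts they screen (recruitment of additional fibers,
intensity instability) are not simulated, and strongly facilitating or
uniquantal synapses trip rules (v) and (low success) by honest chance — at
10 trains a C3 synapse releasing one quantum at stimulus 1 and four at
stimulus 2 shows a per-train PPR above 4 with appreciable probability.

## Classification

Profile matrices hold one row per synapse of per-stimulus charges aggregated
across trains by the mean.  The median is computed and exported as well, but
the pipeline classifies on means: for a uniquantal synapse observed over 10
trains the per-stimulus median collapses onto {0, q/2, q}, and min–max
normalization turns such rows into noise.  Means are unbiased and smooth at
every site count.

Rows are normalized by a per-observation (vector-space-model) min–max map to
[0, 1], making profiles shape-comparable independent of absolute charge;
per-feature scaling is available behind a switch.  Constant rows map to 0.5
and are flagged.  PCA is a centered SVD fitted on the reference (wild-type)
cohort only, with the sign convention that each component's
largest-magnitude loading is positive; test (knockout) observations are
projected into the fitted space without influencing the eigendecomposition.
k-means (k = 4 for trains, k = 3 for photostimulation time courses; k is a
config input, no automatic selection) runs on the first two PC scores with
50 restarts, a 1e−6 tolerance and a fixed seed; labels are canonicalized by
descending cluster mean of PC1, and test observations join the nearest
reference centroid (ties to the lowest label).  Class summary tables carry
one-way ANOVA and Tukey annotations as descriptive output only; classes with
fewer than two members are excluded from the tests.

On the default cohort (24 synapses per class, 10 trains each) the four
archetypes are recovered with adjusted Rand index 0.94–1.0 across seeds, the
projected knockout mixture (C1:C2:C3:C4 = 1:3:12:12, n = 28) is recovered
within a few synapses, and excluding the first-stimulus charge changes at
most a few percent of labels — the robustness control against stimulation
threshold errors.

## Photostimulation analysis

A photostimulation episode is a granule-cell burst (default 10 spikes at
100 Hz starting 15 ms after onset with 2 ms jitter) driving the same release
model, rendered over 500 ms of baseline plus 200 ms post-onset.  Evoked
charge is binned in 5 ms bins from the onset to 100 ms; the per-synapse time
course averages ≥ 7 sweeps; the delay to EPSC peak is the center of the
largest bin (ties to the earliest — latency semantics).  Three response
archetypes are generated: phasic-large (early peak, large charge),
phasic-small (weaker, slightly later peak) and tonic (facilitation-built,
late peak), with mean-field peak delays near 15, 35 and 90 ms.

MLI spiking is an inhomogeneous Poisson process with rate
`baseline + gain × released-charge density`, the density spread over a 5 ms
causal exponential window as a crude synaptic/membrane integration stage;
negative rates clip to zero.  Defaults: baseline 12 Hz, gain 1.5 Hz per
fC/ms, 60 repeats per synapse.  The PSTH uses the same 5 ms binning; the
reported histogram is raw, and the peak search optionally applies a 3-bin
moving average (the pipeline default) because at realistic rates a
single-bin argmax is noise-dominated for weak synapses.  The repeat count
was set for stable latency estimates; a Poisson model is intrinsically
noisier than real, partially time-locked MLI firing, which is why tens of
repeats are needed where experiments resolve latencies with fewer.  On a
coupled 30-synapse cohort the Pearson correlation between delay-to-EPSC-peak
and delay-to-frequency-peak is typically 0.65–0.9, and the class-wise
orderings of the two delays agree.

A kinetic-variability screen (coefficient of variation of per-sweep
delay-to-peak, default threshold 0.5) reproduces the discard rule for
recordings with unstable kinetics; it flags rather than deletes.

## Morphometry

Vesicle positions are given as distances from the active-zone cytomatrix
(0 nm).  Vesicles within 50 nm count as docked; the boundary is inclusive,
and distance histograms use 50 nm half-open bins whose first bin is closed
at the cutoff so the first bin always equals the docked count.  The fixture
generator samples active-zone lengths from a lognormal (WT mean ≈ 520 nm;
KO mean ≈ 440 nm with the distribution truncated at 800 nm, removing the
long-AZ/high-count tail) and docked counts as Poisson in AZ length
(0.0131 nm⁻¹), planting the positive AZ-length/docked-count correlation;
non-docked vesicles add an exponential distance tail.  No image processing
is performed or claimed.

## Numerical and design notes

- All stochastic operations take explicit seeds (integers or NumPy
  generators); cohorts derive per-synapse substreams deterministically from
  the master seed, so equal seeds give bit-identical cohorts and the
  end-to-end driver writes byte-identical files on rerun (HDF5 datasets are
  written without timestamps).
- Charge units are magnitudes in fC throughout; simulated currents are
  negative-going.
- PCA degeneracies raise informative errors (zero total variance; rank below
  the component count, naming the rank).
- The run driver's defaults are the emulated study conditions: 96 wild-type
  synapses (24 per class), 28 knockout synapses (1/3/12/12), 10 pulses at
  100 Hz × 10 trains, 30 photostimulation synapses (10 per class), 108/81
  wild-type/knockout electron-microscopy profiles.

## What passing tests do and do not show

The generator emulates binomial quantal statistics, two-pool dynamics,
baseline noise, quantal size variability and class-structured heterogeneity.
It does not emulate stimulation artifacts, electrode drift, series-resistance
changes, dendritic filtering, fiber recruitment at high intensity, or
time-locked (non-Poisson) MLI firing.  Passing tests therefore demonstrate
that the analysis chain is correct and self-consistent under the stated
statistical assumptions — charge recovery to analytic truth, detector rates
matching closed forms, class and mixture recovery, latency coupling — not
that it would be robust to every artifact of real recordings.  The
quantitative cohort means of the original study are not reproducible from
code alone and are not claimed; agreement is asserted only for the
qualitative structure the classes define.
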