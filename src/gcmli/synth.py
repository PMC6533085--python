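"""Synthetic quantal-release data for unitary GC-MLI synapses.

The generator emulates the statistical structure the downstream analysis
assumes: trains of 10 stimuli at 100 Hz repeated >=7 times per synapse, EPSC
waveforms with Gaussian baseline noise, four short-term-plasticity archetypes
(C1 depressing after the 2nd pulse, C2 facilitate-then-depress, C3 sustained
facilitation, C4 small stable uniquantal), a synapsin-II-knockout regime with
reduced initial release probability, photostimulation-evoked ~100 ms release
episodes with coupled interneuron spiking, and docked-vesicle morphometry.

Release model
-------------
A depletion-facilitation site model: ``n_sites`` independent release sites,
each either occupied or empty.  At each stimulus the number of released quanta
is binomial over occupied sites with instantaneous probability
``min(1, p_fr + f)``; facilitation ``f`` grows by ``facil_increment`` after
each stimulus and decays with ``tau_facil``.  Empty sites refill exponentially
with ``tau_recovery``; during the high-frequency train the refill rate is
multiplied by ``reluctant_gain``, expressing recruitment of the reluctant
vesicle supply by high-frequency drive.  Trains are simulated independently:
the inter-train interval (a minute) vastly exceeds the recovery constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import SweepRecording
from .morphometry import SynapseProfile

__all__ = [
    "QuantalSynapseParams",
    "StimulusProtocol",
    "SimulatedSweep",
    "GCBurst",
    "SynapseRecord",
    "GroundTruthCohort",
    "CLASS_LABELS",
    "PHOTOSTIM_CLASSES",
    "simulate_release_train",
    "mean_release_profile",
    "render_sweep",
    "make_class_archetype",
    "make_cohort",
    "make_photostim_archetype",
    "simulate_photostim_episode",
    "simulate_mli_spiking",
    "make_morphometry_fixture",
    "unit_kernel",
    "kernel_peak",
    "as_generator",
]

CLASS_LABELS = ("C1", "C2", "C3", "C4")
PHOTOSTIM_CLASSES = ("phasic_large", "phasic_small", "tonic")
GENOTYPES = ("WT", "KO")


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class QuantalSynapseParams:
    """Generative ground truth for one simulated synapse.

    n_sites : release sites (>=1).
    p_fr : initial release probability of a fully-releasable vesicle per site
        per stimulus, 0-1.  Stimulus 1 always releases with exactly this
        probability (no facilitation has accrued yet).
    q_charge : quantal charge magnitude, fC.
    facil_increment : additive rise of release probability per preceding
        stimulus (dimensionless, >=0).
    tau_facil : facilitation decay constant, ms.
    tau_recovery : site refilling constant from the reluctant/reserve supply,
        ms (may be ``inf`` for a non-recovering pool).
    reluctant_gain : multiplier on the refill rate during high-frequency
        drive (>=1).
    kernel_rise / kernel_decay : EPSC biexponential time constants, ms
        (decay > rise).
    noise_sigma : baseline current noise SD, pA.
    quantal_cv : coefficient of variation of the single-quantum charge
        (mean-preserving lognormal jitter applied per released quantum;
        0 gives identical quanta).
    """

    n_sites: int
    p_fr: float
    q_charge: float
    facil_increment: float = 0.0
    tau_facil: float = 40.0
    tau_recovery: float = 50.0
    reluctant_gain: float = 1.0
    kernel_rise: float = 0.4
    kernel_decay: float = 2.0
    noise_sigma: float = 1.5
    quantal_cv: float = 0.0

    def __post_init__(self) -> None:
        # tau_recovery may be +inf (non-recovering pool); everything else finite
        for name in ("p_fr", "q_charge", "facil_increment", "tau_facil",
                     "reluctant_gain", "kernel_rise", "kernel_decay",
                     "noise_sigma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not (math.isfinite(self.tau_recovery) or self.tau_recovery == math.inf):
            raise ValueError("tau_recovery must be finite or +inf")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.p_fr <= 1.0:
            raise ValueError("p_fr must be in [0, 1]")
        if self.q_charge <= 0:
            raise ValueError("q_charge must be positive")
        if self.facil_increment < 0:
            raise ValueError("facil_increment must be >= 0")
        if self.tau_facil <= 0 or self.tau_recovery <= 0:
            raise ValueError("time constants must be positive")
        if self.reluctant_gain < 1:
            raise ValueError("reluctant_gain must be >= 1")
        if self.kernel_decay <= self.kernel_rise:
            raise ValueError("kernel_decay must exceed kernel_rise")
        if self.kernel_rise <= 0:
            raise ValueError("kernel_rise must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.quantal_cv < 1:
            raise ValueError("quantal_cv must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QuantalSynapseParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class StimulusProtocol:
    """Minimal-stimulation train protocol (10 pulses at 100 Hz by default)."""

    n_pulses: int = 10
    frequency: float = 100.0
    n_trains: int = 10
    inter_train_interval: float = 60.0  # s
    pre_stimulus_baseline: float = 300.0  # ms
    sampling_rate: float = 50_000.0  # Hz

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")
        if self.pre_stimulus_baseline < 300.0:
            raise ValueError("pre_stimulus_baseline must be >= 300 ms "
                             "(the fixed noise window must fit)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def isi_ms(self) -> float:
        return 1000.0 / self.frequency

    def stimulus_times(self) -> np.ndarray:
        """Stimulus onsets in ms, the first at ``pre_stimulus_baseline``."""
        return self.pre_stimulus_baseline + np.arange(self.n_pulses) * self.isi_ms


@dataclass
class SimulatedSweep:
    """One rendered sweep plus its ground truth."""

    time_base: np.ndarray
    current: np.ndarray
    stimulus_times: np.ndarray
    truth_quanta: np.ndarray
    sampling_rate: float
    params_id: str = ""

    def to_recording(self, baseline_ms: float = 300.0) -> SweepRecording:
        t1 = float(self.stimulus_times[0])
        return SweepRecording(
            time_base=self.time_base,
            current=self.current,
            stimulus_times=self.stimulus_times,
            sampling_rate=self.sampling_rate,
            baseline_window=(t1 - baseline_ms, t1),
        )


def _release_at_times(params: QuantalSynapseParams, times_ms: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Quanta released at each of ``times_ms`` (ascending), stochastic."""
    occupied = params.n_sites
    f = 0.0
    counts = np.zeros(times_ms.size, dtype=int)
    prev = None
    for i, t in enumerate(times_ms):
        if prev is not None:
            dt = float(t - prev)
            f *= math.exp(-dt / params.tau_facil)
            if math.isfinite(params.tau_recovery):
                refill_p = 1.0 - math.exp(-dt * params.reluctant_gain
                                          / params.tau_recovery)
                occupied += int(rng.binomial(params.n_sites - occupied, refill_p))
        p = min(1.0, params.p_fr + f)
        released = int(rng.binomial(occupied, p))
        occupied -= released
        f += params.facil_increment
        counts[i] = released
        prev = t
    return counts


def simulate_release_train(params: QuantalSynapseParams,
                           protocol: StimulusProtocol,
                           seed) -> np.ndarray:
    """Per-stimulus released quanta for one train (stochastic, seeded)."""
    rng = as_generator(seed)
    return _release_at_times(params, protocol.stimulus_times(), rng)


def mean_release_profile(params: QuantalSynapseParams,
                         times_or_protocol) -> np.ndarray:
    """Exact expected quanta per stimulus.

    The stochastic update is linear in the occupancy (binomial release and
    per-site refill), and facilitation evolves deterministically, so the
    expectation obeys the mean-field recursion exactly.  Used for archetype
    calibration and as an independent oracle in tests.
    """
    if isinstance(times_or_protocol, StimulusProtocol):
        times = times_or_protocol.stimulus_times()
    else:
        times = np.asarray(times_or_protocol, dtype=float)
    occ = float(params.n_sites)
    f = 0.0
    out = np.zeros(times.size)
    prev = None
    for i, t in enumerate(times):
        if prev is not None:
            dt = float(t - prev)
            f *= math.exp(-dt / params.tau_facil)
            if math.isfinite(params.tau_recovery):
                refill_p = 1.0 - math.exp(-dt * params.reluctant_gain
                                          / params.tau_recovery)
                occ += (params.n_sites - occ) * refill_p
        p = min(1.0, params.p_fr + f)
        out[i] = occ * p
        occ -= out[i]
        f += params.facil_increment
        prev = t
    return out


def unit_kernel(t_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Biexponential difference kernel with unit time integral (1/ms).

    ``k(t) = (exp(-t/decay) - exp(-t/rise)) / (decay - rise)`` for t >= 0,
    zero before.  Multiplying by a charge in fC yields a current in pA.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (np.exp(-tp / decay) - np.exp(-tp / rise)) / (decay - rise)
    return out


def kernel_peak(rise: float, decay: float) -> tuple[float, float]:
    """(time of peak ms, peak value of the unit kernel in 1/ms)."""
    t_peak = math.log(decay / rise) * rise * decay / (decay - rise)
    v = (math.exp(-t_peak / decay) - math.exp(-t_peak / rise)) / (decay - rise)
    return t_peak, v


def _render(times: np.ndarray, events_ms: np.ndarray, quanta: np.ndarray,
            params: QuantalSynapseParams, rng: np.random.Generator) -> np.ndarray:
    current = np.zeros(times.size)
    if params.noise_sigma > 0:
        current += rng.normal(0.0, params.noise_sigma, size=times.size)
    for t_ev, n_q in zip(events_ms, quanta):
        if n_q <= 0:
            continue
        if params.quantal_cv > 0:
            sigma = math.sqrt(math.log(1.0 + params.quantal_cv**2))
            weights = rng.lognormal(-sigma**2 / 2.0, sigma, size=int(n_q))
            amplitude = params.q_charge * float(weights.sum())
        else:
            amplitude = params.q_charge * float(n_q)
        i0 = int(np.searchsorted(times, t_ev))
        rel = times[i0:] - t_ev
        current[i0:] -= amplitude * unit_kernel(
            rel, params.kernel_rise, params.kernel_decay)
    return current


def render_sweep(quanta: np.ndarray, params: QuantalSynapseParams,
                 protocol: StimulusProtocol, seed,
                 params_id: str = "") -> SimulatedSweep:
    """Render released quanta into a noisy current trace.

    The trace covers the pre-stimulus baseline, the train, and a tail of one
    inter-stimulus interval (at least five decay constants) after the last
    stimulus.  EPSCs are negative-going; the integral of a single-quantum
    event equals ``q_charge`` (the kernel is normalized analytically).
    """
    quanta = np.asarray(quanta, dtype=int)
    if quanta.size != protocol.n_pulses:
        raise ValueError("quanta length must equal the pulse count")
    samples_per_rise = params.kernel_rise * protocol.sampling_rate / 1000.0
    if samples_per_rise < 5:
        raise ValueError(
            f"sampling_rate too low: {samples_per_rise:.1f} samples per rise "
            "constant (need >= 5)")
    rng = as_generator(seed)
    stim = protocol.stimulus_times()
    tail = max(protocol.isi_ms, 5.0 * params.kernel_decay)
    duration = float(stim[-1]) + tail
    dt = 1000.0 / protocol.sampling_rate
    times = np.arange(0.0, duration + dt / 2, dt)
    current = _render(times, stim, quanta, params, rng)
    return SimulatedSweep(time_base=times, current=current,
                          stimulus_times=stim, truth_quanta=quanta,
                          sampling_rate=protocol.sampling_rate,
                          params_id=params_id)


# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------

# Calibrated against the class shape predicates evaluated on the exact
# mean-field profile (see tests/test_synth.py): C1 largest first EPSC, PPR>1,
# depressed after the 2nd pulse; C2 PPR>1.5, peak near the 4th pulse then
# decline; C3 PPR>1.5, sustained through the 10th pulse; C4 uniquantal with
# stable charges from the 2nd pulse on.
_ARCHETYPES: dict[str, dict] = {
    "C1": dict(n_sites=10, p_fr=0.50, q_charge=50.0, facil_increment=0.50,
               tau_facil=40.0, tau_recovery=40.0, reluctant_gain=1.5),
    "C2": dict(n_sites=12, p_fr=0.15, q_charge=50.0, facil_increment=0.25,
               tau_facil=60.0, tau_recovery=60.0, reluctant_gain=1.0),
    "C3": dict(n_sites=12, p_fr=0.15, q_charge=50.0, facil_increment=0.12,
               tau_facil=150.0, tau_recovery=25.0, reluctant_gain=2.5),
    "C4": dict(n_sites=1, p_fr=0.45, q_charge=80.0, facil_increment=1.00,
               tau_facil=12.0, tau_recovery=3.0, reluctant_gain=1.0),
}

#: intra-synaptic quantal size variability applied to every archetype
QUANTAL_CV = 0.2

#: knockout regime: initial release probability scaled down and sites reduced,
#: refill dynamics untouched (recruitment of reluctant vesicles is spared)
KO_P_FACTOR = 0.5
KO_SITE_FACTOR = 0.75
#: baseline noise set to one tenth of the single-quantum EPSC peak
NOISE_OVER_PEAK = 0.1


def _noise_for(q_charge: float, rise: float, decay: float) -> float:
    _, peak = kernel_peak(rise, decay)
    return NOISE_OVER_PEAK * q_charge * peak


def make_class_archetype(class_id: str, genotype: str = "WT", seed=0,
                         jitter: float = 0.05) -> QuantalSynapseParams:
    """Parameters for one synapse of a given STP class, with seeded jitter.

    ``jitter`` is the lognormal sigma applied to the continuous parameters for
    cohort diversity (0 disables it).  The KO genotype multiplies ``p_fr`` by
    0.5 and reduces ``n_sites`` by a quarter, leaving refilling untouched.
    """
    if class_id not in _ARCHETYPES:
        raise ValueError(f"unknown class_id {class_id!r}; expected one of {CLASS_LABELS}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected WT or KO")
    base = dict(_ARCHETYPES[class_id])
    rng = as_generator(seed)
    if jitter > 0:
        for key in ("p_fr", "q_charge", "facil_increment"):
            base[key] *= float(rng.lognormal(0.0, jitter))
        for key in ("tau_facil", "tau_recovery"):
            base[key] *= float(rng.lognormal(0.0, 1.5 * jitter))
        if base["n_sites"] > 1:
            base["n_sites"] = int(max(2, base["n_sites"] + rng.integers(-1, 2)))
    if genotype == "KO":
        base["p_fr"] *= KO_P_FACTOR
        base["n_sites"] = max(1, round(KO_SITE_FACTOR * base["n_sites"]))
    base["p_fr"] = min(base["p_fr"], 0.95)
    rise = base.setdefault("kernel_rise", 0.4)
    decay = base.setdefault("kernel_decay", 2.0)
    base["noise_sigma"] = _noise_for(base["q_charge"], rise, decay)
    base["quantal_cv"] = QUANTAL_CV
    return QuantalSynapseParams(**base)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SynapseRecord:
    """One simulated synapse: parameters, labels, and its rendered sweeps."""

    synapse_id: str
    params: QuantalSynapseParams
    class_label: str
    genotype: str
    sweeps: list[SimulatedSweep] = field(default_factory=list)


@dataclass
class GroundTruthCohort:
    """A seeded collection of simulated synapses."""

    synapses: list[SynapseRecord]
    protocol: StimulusProtocol
    seed: int

    def by_id(self) -> dict[str, SynapseRecord]:
        return {s.synapse_id: s for s in self.synapses}


def make_cohort(class_counts: dict[str, int], genotype: str,
                protocol: StimulusProtocol | None = None, seed: int = 0,
                jitter: float = 0.05) -> GroundTruthCohort:
    """Simulate a cohort with the given class mixture.

    Per-synapse sub-seeds derive deterministically from the master seed, so
    identical seeds yield bit-identical cohorts.  Every synapse gets
    ``protocol.n_trains`` sweeps (>=7 to satisfy the analysis minimum is the
    caller's choice; the default protocol uses 10).
    """
    protocol = protocol or StimulusProtocol()
    synapses: list[SynapseRecord] = []
    idx = 0
    for label in CLASS_LABELS:
        count = int(class_counts.get(label, 0))
        for _ in range(count):
            # one spawned stream per synapse keeps sub-seeding deterministic
            child = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
            rng = np.random.default_rng(child)
            params = make_class_archetype(label, genotype, seed=rng,
                                          jitter=jitter)
            sid = f"{genotype}_{label}_{idx:03d}"
            sweeps = []
            for _t in range(protocol.n_trains):
                quanta = simulate_release_train(params, protocol, rng)
                sweeps.append(render_sweep(quanta, params, protocol, rng,
                                           params_id=sid))
            synapses.append(SynapseRecord(sid, params, label, genotype, sweeps))
            idx += 1
    return GroundTruthCohort(synapses=synapses, protocol=protocol, seed=seed)


# ---------------------------------------------------------------------------
# Photostimulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCBurst:
    """Granule-cell burst evoked by glutamate uncaging.

    ``n_spikes`` spikes at ``rate_hz`` starting ``onset_delay`` ms after the
    photostimulation onset, each spike jittered by a Gaussian of
    ``jitter_ms``.  Photostimulation bursts are reproducible across episodes.
    """

    n_spikes: int = 10
    rate_hz: float = 100.0
    onset_delay: float = 15.0
    jitter_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("burst rate must be positive")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")

    def spike_times(self, onset_ms: float, rng: np.random.Generator) -> np.ndarray:
        if self.n_spikes == 0:
            return np.empty(0)
        base = onset_ms + self.onset_delay + np.arange(self.n_spikes) * (
            1000.0 / self.rate_hz)
        t = base + rng.normal(0.0, self.jitter_ms, size=self.n_spikes)
        t = np.maximum(t, onset_ms + 0.5)
        return np.sort(t)


# photostimulation response classes: phasic-large peaks at the first burst
# spikes then depresses, phasic-small is weaker with a slightly later peak,
# tonic builds release up by facilitation and reluctant-pool recruitment
# (late peak, smaller early responses)
_PHOTOSTIM_ARCH: dict[str, dict] = {
    "phasic_large": dict(n_sites=10, p_fr=0.60, q_charge=50.0,
                         facil_increment=0.30, tau_facil=40.0,
                         tau_recovery=60.0, reluctant_gain=1.0),
    "phasic_small": dict(n_sites=6, p_fr=0.10, q_charge=50.0,
                         facil_increment=0.25, tau_facil=70.0,
                         tau_recovery=70.0, reluctant_gain=1.0),
    "tonic": dict(n_sites=6, p_fr=0.12, q_charge=50.0,
                  facil_increment=0.10, tau_facil=200.0,
                  tau_recovery=25.0, reluctant_gain=2.5),
}


def make_photostim_archetype(kind: str, genotype: str = "WT", seed=0,
                             jitter: float = 0.05) -> QuantalSynapseParams:
    """Synapse parameters for one photostimulation response class."""
    if kind not in _PHOTOSTIM_ARCH:
        raise ValueError(f"unknown photostimulation class {kind!r}; "
                         f"expected one of {PHOTOSTIM_CLASSES}")
    base = dict(_PHOTOSTIM_ARCH[kind])
    rng = as_generator(seed)
    if jitter > 0:
        for key in ("p_fr", "q_charge", "facil_increment"):
            base[key] *= float(rng.lognormal(0.0, jitter))
        for key in ("tau_facil", "tau_recovery"):
            base[key] *= float(rng.lognormal(0.0, 1.5 * jitter))
    if genotype == "KO":
        base["p_fr"] *= KO_P_FACTOR
        base["n_sites"] = max(1, round(KO_SITE_FACTOR * base["n_sites"]))
    base["p_fr"] = min(base["p_fr"], 0.95)
    base["kernel_rise"], base["kernel_decay"] = 0.4, 2.0
    base["noise_sigma"] = _noise_for(base["q_charge"], 0.4, 2.0)
    base["quantal_cv"] = QUANTAL_CV
    return QuantalSynapseParams(**base)


def simulate_photostim_episode(
    params: QuantalSynapseParams,
    burst: GCBurst,
    seed,
    onset_ms: float = 500.0,
    post_ms: float = 200.0,
) -> tuple[SimulatedSweep, np.ndarray, np.ndarray]:
    """One photostimulation episode.

    Returns ``(sweep, release_times_ms, release_quanta)``: the rendered trace
    covering ``onset_ms`` of pre-stimulus baseline plus ``post_ms`` after the
    photostimulation onset, and the latent per-spike release ground truth.
    The episode must extend at least 100 ms past the onset (the downstream
    binning span).
    """
    if post_ms < 100.0:
        raise ValueError("episode must cover at least 100 ms post-onset")
    rng = as_generator(seed)
    spikes = burst.spike_times(onset_ms, rng)
    quanta = _release_at_times(params, spikes, rng) if spikes.size else np.empty(0, int)
    dt = 1000.0 / 50_000.0
    times = np.arange(0.0, onset_ms + post_ms + dt / 2, dt)
    current = _render(times, spikes, quanta, params, rng)
    sweep = SimulatedSweep(time_base=times, current=current,
                           stimulus_times=np.array([onset_ms]),
                           truth_quanta=quanta, sampling_rate=50_000.0)
    return sweep, spikes, quanta


def release_rate_course(spikes: np.ndarray, quanta: np.ndarray,
                        q_charge: float, onset_ms: float, span_ms: float,
                        dt_ms: float = 1.0,
                        smooth_tau_ms: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth released charge density (fC/ms) on a regular grid.

    ``smooth_tau_ms`` spreads each release over a causal exponential window
    (a crude synaptic/membrane integration stage for driving spiking); 0
    leaves the density as point deposits.  Total charge is conserved either
    way.
    """
    edges = np.arange(0.0, span_ms + dt_ms / 2, dt_ms)
    density = np.zeros(edges.size - 1)
    for t, n_q in zip(spikes, quanta):
        rel = t - onset_ms
        if 0 <= rel < span_ms:
            density[int(rel // dt_ms)] += n_q * q_charge / dt_ms
    if smooth_tau_ms > 0:
        n = int(np.ceil(6 * smooth_tau_ms / dt_ms))
        kern = np.exp(-np.arange(n) * dt_ms / smooth_tau_ms)
        kern /= kern.sum()
        density = np.convolve(density, kern)[: density.size]
    return edges, density


def simulate_mli_spiking(
    time_grid_ms: np.ndarray,
    charge_density: np.ndarray,
    baseline_rate: float,
    gain: float,
    n_repeats: int,
    seed,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson interneuron spiking driven by evoked charge.

    ``rate(t) = baseline_rate + gain * charge_density(t)`` (Hz; density in
    fC/ms and gain in Hz per fC/ms).  Negative instantaneous rates are clipped
    to zero.  ``charge_density`` is piecewise constant on the bins defined by
    ``time_grid_ms`` (edges, ms).  Returns one spike-time array (ms) per
    repeat; with ``gain = 0`` the process is homogeneous at the baseline rate.
    """
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be >= 0")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    edges = np.asarray(time_grid_ms, dtype=float)
    density = np.asarray(charge_density, dtype=float)
    if edges.size != density.size + 1:
        raise ValueError("time_grid_ms must be bin edges for charge_density")
    rate_hz = baseline_rate + gain * density
    rate_hz = np.clip(rate_hz, 0.0, None)
    widths_s = np.diff(edges) / 1000.0
    rng = as_generator(seed)
    rasters: list[np.ndarray] = []
    for _ in range(n_repeats):
        counts = rng.poisson(rate_hz * widths_s)
        times = []
        for i, c in enumerate(counts):
            if c:
                times.append(edges[i] + rng.random(c) * (edges[i + 1] - edges[i]))
        spikes = np.sort(np.concatenate(times)) if times else np.empty(0)
        rasters.append(spikes)
    return rasters


# ---------------------------------------------------------------------------
# Morphometry fixtures
# ---------------------------------------------------------------------------

# active-zone length distributions (nm): lognormal with means near the cohort
# means reported for WT/KO terminals; the KO regime loses the long-AZ tail
_AZ_MEAN = {"WT": 520.0, "KO": 440.0}
_AZ_SIGMA = {"WT": 0.30, "KO": 0.25}
_AZ_CAP = {"WT": 1400.0, "KO": 800.0}
#: docked vesicles per nm of active zone (Poisson intensity)
_DOCK_DENSITY = 0.0131
#: mean count of non-docked vesicles per docked vesicle in the profile
_OUTER_PER_DOCKED = 3.0


def make_morphometry_fixture(n_synapses: int, genotype: str = "WT",
                             seed=0) -> list[SynapseProfile]:
    """Sample synapse profiles with a planted AZ-length/docked-count link.

    Docked counts are Poisson in the active-zone length (positive correlation
    by construction); the KO mode truncates the long-AZ tail and shortens the
    mean, removing boutons with both a long active zone and a high docked
    count.  Distances are measured from the active-zone cytomatrix (0 nm);
    vesicles within 50 nm are the docked ones.
    """
    if n_synapses < 1:
        raise ValueError("n_synapses must be >= 1")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    rng = as_generator(seed)
    mu = math.log(_AZ_MEAN[genotype]) - _AZ_SIGMA[genotype] ** 2 / 2
    profiles: list[SynapseProfile] = []
    for i in range(n_synapses):
        az = float(np.clip(rng.lognormal(mu, _AZ_SIGMA[genotype]),
                           150.0, _AZ_CAP[genotype]))
        n_docked = int(rng.poisson(_DOCK_DENSITY * az))
        docked = rng.uniform(0.0, 50.0, size=n_docked)
        n_outer = int(rng.poisson(_OUTER_PER_DOCKED * max(n_docked, 1)))
        outer = 50.0 + rng.exponential(140.0, size=n_outer)
        distances = np.sort(np.concatenate([docked, np.minimum(outer, 650.0)]))
        profiles.append(SynapseProfile(
            synapse_id=f"{genotype}_em_{i:03d}",
            az_length=az,
            vesicle_distances=distances,
            genotype=genotype,
        ))
    return profiles
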