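"""Photostimulation-episode analysis: charge time courses, PSTH, latencies.

Evoked EPSC charge is binned (5 ms bins over 0-100 ms post-onset by default)
for each sweep; interneuron spike rasters become peristimulus time histograms
with delay-to-frequency-peak and per-bin firing probability.  The delay
metrics are measured from the stimulation onset; peak-bin ties break toward
the earliest bin (latency semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import ClassificationResult, ProfileMatrix, classify_cohort
from .features import SweepRecording

__all__ = [
    "ChargeTimeCourse",
    "FiringFeatures",
    "bin_charge_time_course",
    "mean_time_course",
    "compute_psth",
    "correlate_delays",
    "classify_time_courses",
    "kinetic_variability_cv",
]


@dataclass
class ChargeTimeCourse:
    """Binned evoked-charge time course for one sweep or sweep average."""

    bin_edges: np.ndarray      # ms, relative to onset
    charge_per_bin: np.ndarray  # fC
    onset: float               # ms, absolute
    peak_charge: float         # fC
    delay_to_epsc_peak: float  # ms from onset (center of the peak bin)


@dataclass
class FiringFeatures:
    """PSTH-derived firing metrics across repeats."""

    bin_edges: np.ndarray          # ms relative to onset
    psth: np.ndarray               # Hz per bin
    baseline_rate: float           # Hz, pre-onset window
    peak_rate: float               # Hz
    delay_to_frequency_peak: float | None  # ms from onset; None when undefined
    firing_probability: np.ndarray  # per-bin fraction of repeats with >=1 spike
    n_repeats: int
    flags: list[str] = field(default_factory=list)


def bin_charge_time_course(
    sweep: SweepRecording,
    onset: float | None = None,
    bin_width: float = 5.0,
    span: float = 100.0,
    baseline: float | None = None,
) -> ChargeTimeCourse:
    """Per-bin EPSC charge from the stimulation onset to ``span`` ms after.

    ``span`` must divide evenly into ``bin_width`` bins and the trace must
    cover the full span.  The charge per bin is the trapezoidal integral of
    the baseline-subtracted, sign-flipped current; the peak is the largest
    bin and the delay the center of that bin.
    """
    if onset is None:
        onset = float(sweep.stimulus_times[0])
    n_bins_f = span / bin_width
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError(f"span {span} not divisible by bin_width {bin_width}")
    n_bins = int(round(n_bins_f))
    if onset + span > float(sweep.time_base[-1]) + 1e-9:
        raise ValueError("trace does not cover onset + span")
    if baseline is None:
        baseline = sweep.baseline_mean()
    edges = np.arange(n_bins + 1) * bin_width
    charge = np.zeros(n_bins)
    for i in range(n_bins):
        seg = -(sweep.slice(onset + edges[i], onset + edges[i + 1]) - baseline)
        charge[i] = float(np.trapezoid(seg, dx=sweep.dt))
    peak_idx = int(np.argmax(charge))  # ties -> earliest bin
    return ChargeTimeCourse(
        bin_edges=edges, charge_per_bin=charge, onset=float(onset),
        peak_charge=float(charge[peak_idx]),
        delay_to_epsc_peak=float((edges[peak_idx] + edges[peak_idx + 1]) / 2),
    )


def mean_time_course(courses: list[ChargeTimeCourse]) -> ChargeTimeCourse:
    """Average charge time course across repeated sweeps of one synapse."""
    if not courses:
        raise ValueError("at least one time course is required")
    edges = courses[0].bin_edges
    if any(c.bin_edges.size != edges.size or
           not np.allclose(c.bin_edges, edges) for c in courses):
        raise ValueError("all time courses must share the binning")
    charge = np.mean([c.charge_per_bin for c in courses], axis=0)
    peak_idx = int(np.argmax(charge))
    return ChargeTimeCourse(
        bin_edges=edges, charge_per_bin=charge,
        onset=float(np.mean([c.onset for c in courses])),
        peak_charge=float(charge[peak_idx]),
        delay_to_epsc_peak=float((edges[peak_idx] + edges[peak_idx + 1]) / 2),
    )


def kinetic_variability_cv(courses: list[ChargeTimeCourse]) -> float:
    """Coefficient of variation of per-sweep delay-to-peak.

    Recordings whose EPSCs show strong kinetic variability can be flagged for
    exclusion with a CV threshold (0.5 by default in the pipeline).
    """
    delays = np.array([c.delay_to_epsc_peak for c in courses], dtype=float)
    m = delays.mean()
    return float(delays.std(ddof=0) / m) if m > 0 else float("inf")


def compute_psth(
    rasters: list[np.ndarray],
    onset: float,
    bin_width: float = 5.0,
    span: float = 100.0,
    baseline_window: float = 500.0,
    smooth_bins: int = 1,
) -> FiringFeatures:
    """PSTH, peak rate, delay-to-frequency-peak and firing probability.

    ``rasters`` holds one spike-time array (ms, absolute) per repeat.  Rates
    are spike counts over ``n_repeats x bin_width``; the baseline rate comes
    from the ``baseline_window`` ms preceding the onset.  The reported PSTH is
    the raw histogram; ``smooth_bins`` (odd, default 1 = off) applies a
    centered moving average before the peak search only, stabilizing the
    delay estimate at low repeat counts.  Empty rasters yield an all-zero
    PSTH with an undefined (None) delay, flagged.
    """
    if not rasters:
        raise ValueError("at least one repeat is required")
    n_rep = len(rasters)
    n_bins = int(round(span / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    prob = np.zeros(n_bins)
    baseline_count = 0
    total_spikes = 0
    for spikes in rasters:
        spikes = np.asarray(spikes, dtype=float)
        total_spikes += spikes.size
        rel = spikes - onset
        in_span = rel[(rel >= 0) & (rel < span)]
        idx = np.floor(in_span / bin_width).astype(int)
        counts += np.bincount(idx, minlength=n_bins)
        prob += np.bincount(np.unique(idx), minlength=n_bins)
        baseline_count += int(np.sum((rel >= -baseline_window) & (rel < 0)))
    psth = counts / (n_rep * bin_width / 1000.0)
    firing_probability = prob / n_rep
    baseline_rate = baseline_count / (n_rep * baseline_window / 1000.0)
    flags: list[str] = []
    if total_spikes == 0:
        return FiringFeatures(bin_edges=edges, psth=psth, baseline_rate=0.0,
                              peak_rate=0.0, delay_to_frequency_peak=None,
                              firing_probability=firing_probability,
                              n_repeats=n_rep, flags=["empty_rasters"])
    search = psth
    if smooth_bins > 1:
        if smooth_bins % 2 == 0:
            raise ValueError("smooth_bins must be odd")
        kern = np.full(smooth_bins, 1.0 / smooth_bins)
        pad = smooth_bins // 2
        padded = np.pad(psth, pad, mode="edge")
        search = np.convolve(padded, kern, mode="valid")
    peak_idx = int(np.argmax(search))
    return FiringFeatures(
        bin_edges=edges, psth=psth, baseline_rate=float(baseline_rate),
        peak_rate=float(psth[peak_idx]),
        delay_to_frequency_peak=float((edges[peak_idx] + edges[peak_idx + 1]) / 2),
        firing_probability=firing_probability, n_repeats=n_rep, flags=flags,
    )


def correlate_delays(pairs: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p between EPSC-peak and firing-peak delays.

    ``pairs`` is an (n, 2) array of (delay_to_epsc_peak,
    delay_to_frequency_peak) per synapse; n >= 3 with nonzero variance in
    both coordinates.
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.shape[0] < 3 or pairs.shape[1] != 2:
        raise ValueError("need at least 3 (epsc_delay, firing_delay) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_time_courses(
    courses: list[ChargeTimeCourse],
    test_courses: list[ChargeTimeCourse] | None = None,
    k: int = 3,
    seed: int = 0,
    ids: list[str] | None = None,
    test_ids: list[str] | None = None,
) -> ClassificationResult:
    """Cluster binned charge time courses (k = 3 photostimulation classes).

    Delegates to the train-profile classifier with per-bin charges as
    features: row-wise VSM normalization, PCA fitted on the reference cohort,
    test cohort projected and assigned to the nearest centroid.
    """
    if not courses:
        raise ValueError("at least one time course is required")
    edges = courses[0].bin_edges
    for c in courses + (test_courses or []):
        if c.bin_edges.size != edges.size or not np.allclose(c.bin_edges, edges):
            raise ValueError("all time courses must share the binning")
    # binned charges can dip below zero in noise; shift per-row minimum to zero
    def matrix(cs, prefix):
        X = np.array([c.charge_per_bin for c in cs], dtype=float)
        X = X - np.minimum(X.min(axis=1, keepdims=True), 0.0)
        return ProfileMatrix(X, ids=[f"{prefix}_{i}" for i in range(len(cs))],
                             cohort=prefix)
    ref = matrix(courses, "ref")
    if ids is not None:
        ref.ids = list(ids)
    tst = None
    if test_courses:
        tst = matrix(test_courses, "test")
        if test_ids is not None:
            tst.ids = list(test_ids)
    return classify_cohort(ref, tst, k=k, seed=seed)
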