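"""Per-stimulus EPSC charge extraction, failure detection and minimal-stimulation QC.

Units follow the recording convention used throughout the package: time in ms,
current in pA, charge in fC (1 pA x 1 ms = 1 fC).  EPSCs are negative-going in
the raw trace; all reported charges are magnitudes.

A *failure* is a stimulus that evokes no detectable EPSC: the peak negative
deflection after the stimulus stays below ``k x sigma_noise`` (default ``k=3``),
with the noise SD measured on a fixed 300 ms window preceding the stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SweepRecording",
    "EPSCTrainFeatures",
    "QCVerdict",
    "estimate_noise_sigma",
    "detect_failure",
    "integrate_epsc_charge",
    "compute_train_features",
    "minimal_stimulation_qc",
    "MIN_NOISE_WINDOW_MS",
    "MIN_TRAINS",
]

#: minimum baseline window accepted by :func:`estimate_noise_sigma` (ms)
MIN_NOISE_WINDOW_MS = 300.0
#: minimum number of trains for a fully qualified feature set
MIN_TRAINS = 7


@dataclass
class SweepRecording:
    """One voltage-clamp sweep with stimulus-time annotations.

    Parameters
    ----------
    time_base:
        Sample times in ms, uniformly spaced.
    current:
        Recorded current in pA, same length as ``time_base``.
    stimulus_times:
        Stimulus onsets in ms, strictly ascending, all within the trace.
    sampling_rate:
        Acquisition rate in Hz.
    baseline_window:
        ``(start, end)`` in ms of the pre-stimulus noise window; must end at or
        before the first stimulus.
    """

    time_base: np.ndarray
    current: np.ndarray
    stimulus_times: np.ndarray
    sampling_rate: float
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.time_base = np.asarray(self.time_base, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.stimulus_times = np.atleast_1d(np.asarray(self.stimulus_times, dtype=float))
        if self.time_base.shape != self.current.shape:
            raise ValueError("time_base and current must have the same shape")
        if self.time_base.ndim != 1 or self.time_base.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if np.any(np.diff(self.stimulus_times) <= 0):
            raise ValueError("stimulus_times must be strictly ascending")
        t0, t1 = float(self.time_base[0]), float(self.time_base[-1])
        if self.stimulus_times[0] < t0 or self.stimulus_times[-1] > t1:
            raise ValueError("stimulus_times must lie within the trace")
        b0, b1 = self.baseline_window
        if b1 > self.stimulus_times[0] + 1e-9:
            raise ValueError("baseline_window must end at or before the first stimulus")
        if b0 >= b1:
            raise ValueError("baseline_window must have positive length")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.sampling_rate

    def slice(self, t_start: float, t_end: float) -> np.ndarray:
        """Current samples with ``t_start <= t < t_end`` (ms)."""
        i0 = int(np.searchsorted(self.time_base, t_start - 1e-9, side="left"))
        i1 = int(np.searchsorted(self.time_base, t_end - 1e-9, side="left"))
        if i0 < 0 or i1 > self.time_base.size or i0 >= i1:
            raise ValueError(f"window [{t_start}, {t_end}) ms outside the trace")
        return self.current[i0:i1]

    def baseline_mean(self) -> float:
        """Mean current over the baseline window (the per-sweep baseline)."""
        return float(np.mean(self.slice(*self.baseline_window)))


def estimate_noise_sigma(sweep: SweepRecording) -> float:
    """SD of the baseline-subtracted current over the pre-stimulus noise window.

    The window must span at least 300 ms (the fixed noise window used for
    threshold-based failure detection).
    """
    b0, b1 = sweep.baseline_window
    if (b1 - b0) < MIN_NOISE_WINDOW_MS - 1e-9:
        raise ValueError(
            f"noise window is {b1 - b0:.1f} ms; at least {MIN_NOISE_WINDOW_MS:.0f} ms required"
        )
    seg = sweep.slice(b0, b1)
    return float(np.std(seg - np.mean(seg), ddof=1))


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1 or x.size < n:
        return x
    kernel = np.full(n, 1.0 / n)
    return np.convolve(x, kernel, mode="valid")


def detect_failure(
    sweep: SweepRecording,
    stimulus_index: int,
    sigma: float,
    k: float = 3.0,
    window: tuple[float, float] = (1.0, 9.0),
    smooth_ms: float = 0.3,
    artifact_blank_ms: float = 0.0,
) -> bool:
    """Return ``True`` when the stimulus evoked no detectable EPSC.

    The peak negative deflection (baseline-subtracted) is searched in
    ``window`` ms after the stimulus on a lightly smoothed copy of the trace
    (moving average of ``smooth_ms``); a response is detected when the peak
    magnitude exceeds ``k * sigma``.  ``artifact_blank_ms`` shifts the search
    start to skip a stimulation artifact (simulated sweeps have none).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 <= stimulus_index < sweep.stimulus_times.size:
        raise IndexError(f"stimulus_index {stimulus_index} out of range")
    t_stim = float(sweep.stimulus_times[stimulus_index])
    w0 = t_stim + max(window[0], artifact_blank_ms)
    w1 = t_stim + window[1]
    seg = sweep.slice(w0, w1) - sweep.baseline_mean()
    n = max(1, int(round(smooth_ms * sweep.sampling_rate / 1000.0)))
    seg = _smooth(seg, n)
    peak_neg = -float(np.min(seg))
    return not peak_neg > k * sigma


def _integration_window(sweep: SweepRecording, stimulus_index: int,
                        window_ms: float | None) -> tuple[float, float]:
    times = sweep.stimulus_times
    t_stim = float(times[stimulus_index])
    if stimulus_index + 1 < times.size:
        return t_stim, float(times[stimulus_index + 1])
    if window_ms is not None:
        return t_stim, t_stim + float(window_ms)
    if times.size >= 2:
        isi = float(np.median(np.diff(times)))
        return t_stim, min(t_stim + isi, float(sweep.time_base[-1]) + sweep.dt)
    # single stimulus, no window given: integrate to the end of the trace
    return t_stim, float(sweep.time_base[-1]) + sweep.dt


def integrate_epsc_charge(
    sweep: SweepRecording,
    stimulus_index: int,
    window_ms: float | None = None,
    baseline: float | None = None,
) -> float:
    """EPSC charge magnitude (fC) over one inter-stimulus window.

    Trapezoidal integral of the baseline-subtracted, sign-flipped current from
    the stimulus time to the next stimulus (the last stimulus uses the
    inter-stimulus interval, or ``window_ms`` when given).  Failures contribute
    their near-zero measured integral; nothing is imputed.
    """
    if not 0 <= stimulus_index < sweep.stimulus_times.size:
        raise IndexError(f"stimulus_index {stimulus_index} out of range")
    if sweep.stimulus_times.size >= 2:
        min_gap = float(np.min(np.diff(sweep.stimulus_times)))
        if min_gap < 2 * sweep.dt:
            raise ValueError("stimuli closer than 2 samples: windows overlap")
    t0, t1 = _integration_window(sweep, stimulus_index, window_ms)
    if baseline is None:
        baseline = sweep.baseline_mean()
    seg = -(sweep.slice(t0, t1) - baseline)
    return abs(float(np.trapezoid(seg, dx=sweep.dt)))


@dataclass
class EPSCTrainFeatures:
    """Per-stimulus charges, failures and summary statistics for one synapse.

    ``charges``/``failures`` are (n_trains, n_stimuli) arrays; aggregated
    statistics are across trains.  ``ppr`` is charge_2 / charge_1 computed on
    the across-train mean charges; per-train PPRs (used by QC rule v) are kept
    separately and are NaN for trains whose first stimulus was a failure.
    """

    charges: np.ndarray
    failures: np.ndarray
    mean_charges: np.ndarray
    median_charges: np.ndarray
    failure_rate: np.ndarray
    success_rate_1: float
    ppr: float
    per_train_ppr: np.ndarray
    n_trains: int
    n_stimuli: int
    flags: list[str] = field(default_factory=list)


def compute_train_features(
    sweeps: list[SweepRecording],
    k: float = 3.0,
    detection_window: tuple[float, float] = (1.0, 9.0),
    smooth_ms: float = 0.3,
    last_window_ms: float | None = None,
) -> EPSCTrainFeatures:
    """Extract per-stimulus charges and failure flags from repeated trains.

    All sweeps must share the stimulus count.  Fewer than 7 sweeps is flagged
    (``"fewer_than_7_trains"``) but not fatal, matching the stated minimum of
    7 or more consecutive trains.
    """
    if not sweeps:
        raise ValueError("at least one sweep is required")
    n_stim = sweeps[0].stimulus_times.size
    if any(s.stimulus_times.size != n_stim for s in sweeps):
        raise ValueError("all sweeps must share the stimulus count")
    n_trains = len(sweeps)
    charges = np.zeros((n_trains, n_stim))
    failures = np.zeros((n_trains, n_stim), dtype=bool)
    for i, s in enumerate(sweeps):
        # noiseless (simulated) sweeps: floor sigma so any deflection counts
        sigma = max(estimate_noise_sigma(s), 1e-9)
        base = s.baseline_mean()
        for j in range(n_stim):
            charges[i, j] = integrate_epsc_charge(s, j, window_ms=last_window_ms,
                                                  baseline=base)
            failures[i, j] = detect_failure(s, j, sigma, k=k,
                                            window=detection_window,
                                            smooth_ms=smooth_ms)
    mean_charges = charges.mean(axis=0)
    median_charges = np.median(charges, axis=0)
    failure_rate = failures.mean(axis=0)
    success_rate_1 = 1.0 - float(failure_rate[0])
    if n_stim >= 2 and mean_charges[0] > 0:
        ppr = float(mean_charges[1] / mean_charges[0])
    else:
        ppr = float("nan")
    per_train_ppr = np.full(n_trains, np.nan)
    if n_stim >= 2:
        ok = ~failures[:, 0] & (charges[:, 0] > 0)
        per_train_ppr[ok] = charges[ok, 1] / charges[ok, 0]
    flags = [] if n_trains >= MIN_TRAINS else ["fewer_than_7_trains"]
    return EPSCTrainFeatures(
        charges=charges, failures=failures, mean_charges=mean_charges,
        median_charges=median_charges, failure_rate=failure_rate,
        success_rate_1=success_rate_1, ppr=ppr, per_train_ppr=per_train_ppr,
        n_trains=n_trains, n_stimuli=n_stim, flags=flags,
    )


@dataclass(frozen=True)
class QCVerdict:
    """Minimal-stimulation acceptance verdict for one stimulation intensity."""

    accepted: bool
    rejection_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.accepted != (len(self.rejection_codes) == 0):
            raise ValueError("accepted must mirror empty rejection_codes")


# rejection codes, mirroring the minimal-stimulation rules (i)-(v) plus the
# success-rate floor
QC_CODES = ("low_success", "i", "ii", "iii", "iv", "v")


def qc_verdict(
    features: EPSCTrainFeatures,
    success_floor: float = 0.4,
    high_failure_band: tuple[float, float] = (0.3, 0.6),
    amplitude_fold: float = 5.0,
    ppr_ceiling: float = 4.0,
) -> QCVerdict:
    """Apply the minimal-stimulation rejection rules to one intensity.

    Codes: ``low_success`` success rate at stimulus 1 <= 0.4; ``i`` systematic
    failures at stimulus 1; ``ii`` failure rate rises at stimulus 2; ``iii``
    no decrease of the failure rate at stimulus 2 for synapses with a high
    (0.3-0.6) failure rate at stimulus 1; ``iv`` any train whose stimulus-1
    charge exceeds 5x the median over detected-success trains (the rule
    screens response-amplitude jumps; failures carry no amplitude); ``v`` any
    per-train PPR > 4.
    """
    codes: list[str] = []
    fr = features.failure_rate
    if features.success_rate_1 <= success_floor:
        codes.append("low_success")
    if fr[0] >= 1.0:
        codes.append("i")
    if features.n_stimuli >= 2:
        if fr[1] > fr[0]:
            codes.append("ii")
        lo, hi = high_failure_band
        if lo <= fr[0] <= hi and not fr[1] < fr[0]:
            codes.append("iii")
    c1 = features.charges[:, 0]
    successes = c1[~features.failures[:, 0]]
    med1 = float(np.median(successes)) if successes.size else float(np.median(c1))
    if med1 > 0 and np.any(c1 > amplitude_fold * med1):
        codes.append("iv")
    finite = features.per_train_ppr[np.isfinite(features.per_train_ppr)]
    if finite.size and np.any(finite > ppr_ceiling):
        codes.append("v")
    # keep canonical order, drop duplicates
    codes = [c for c in QC_CODES if c in codes]
    return QCVerdict(accepted=not codes, rejection_codes=tuple(codes))


def minimal_stimulation_qc(
    features_by_intensity: dict[float, EPSCTrainFeatures],
    **rule_kwargs,
) -> tuple[dict[float, QCVerdict], float | None]:
    """QC verdict per tested intensity plus the chosen intensity.

    The chosen intensity is the lowest accepted one; ``None`` when every
    intensity is rejected.
    """
    if not features_by_intensity:
        raise ValueError("at least one stimulation intensity is required")
    verdicts = {
        float(intensity): qc_verdict(feats, **rule_kwargs)
        for intensity, feats in features_by_intensity.items()
    }
    accepted = sorted(i for i, v in verdicts.items() if v.accepted)
    return verdicts, (accepted[0] if accepted else None)
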