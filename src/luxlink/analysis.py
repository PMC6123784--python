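"""Time-series analyses for sender/receiver fluorescence traces.

Covers what is done to the measured (or simulated) traces: resampling to
the imaging interval, peak detection (local maximum + prominence +
minimum separation), period estimation as the median inter-peak interval,
signed receiver-minus-sender peak-lag statistics, the first-peak burst
ratio of the receiver, and a four-way phenotype classification
(oscillatory / accumulating / suppressed / silent) that quantifies the
qualitative read-outs of the different feedback topologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .errors import (
    InputDomainError,
    InsufficientPeaksError,
    NoMatchError,
    ResamplingError,
)
from .traces import TraceSet

__all__ = [
    "PeakList",
    "LagStats",
    "PhenotypeCall",
    "resample",
    "detect_peaks",
    "detect_channel_peaks",
    "estimate_period",
    "peak_lags",
    "classify_response",
    "first_peak_ratio",
]

#: defaults used throughout: prominence as a fraction of the channel range
#: and minimum peak separation in minutes (a quarter of the ~1 h period).
DEFAULT_PROMINENCE_FRAC = 0.2
DEFAULT_SEPARATION = 15.0


@dataclass
class PeakList:
    """Detected peaks of one channel: times (min) and amplitudes (a.u.)."""

    times: np.ndarray
    amplitudes: np.ndarray
    min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC
    min_separation: float = DEFAULT_SEPARATION

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise InputDomainError("peak times and amplitudes differ in length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InputDomainError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class LagStats:
    """Signed receiver-minus-sender peak-time lags (min)."""

    lags: np.ndarray
    median_abs_lag: float
    iqr: float
    n_matched: int
    n_unmatched_receiver: int = 0
    first_receiver_peak_excluded: bool = True

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        if self.n_matched != len(self.lags):
            raise InputDomainError("n_matched must equal the number of lags")


@dataclass
class PhenotypeCall:
    """Classification of one channel with the statistics that drove it."""

    label: str  # oscillatory | accumulating | suppressed | silent
    evidence: dict[str, float] = field(default_factory=dict)
    degraded_confidence: bool = False

    LABELS = ("oscillatory", "accumulating", "suppressed", "silent")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise InputDomainError(f"unknown phenotype label {self.label!r}")


def resample(trace: TraceSet, interval: float) -> TraceSet:
    """Resample all channels onto the imaging grid 0, interval, 2*interval, ...

    Values are linearly interpolated; the output grid covers the span of
    the input.  The interval must not be finer than the native step
    (imaging cannot be resampled *up*).
    """
    if interval <= 0:
        raise ResamplingError(f"interval must be > 0, got {interval}")
    native = trace.step
    if interval < native - 1e-12:
        raise ResamplingError(
            f"interval {interval} min is finer than the native step {native} min"
        )
    t0, t1 = trace.times[0], trace.times[-1]
    first = math.ceil(t0 / interval - 1e-9)
    last = math.floor(t1 / interval + 1e-9)
    grid = np.arange(first, last + 1) * interval
    channels = {
        name: np.interp(grid, trace.times, values)
        for name, values in trace.channels.items()
    }
    meta = dict(trace.metadata)
    meta["resample_interval_min"] = interval
    return TraceSet(grid, channels, meta)


def detect_peaks(times: np.ndarray, values: np.ndarray,
                 min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                 min_separation: float = DEFAULT_SEPARATION) -> PeakList:
    """Find strict local maxima filtered by prominence and separation.

    Prominence is measured relative to the channel range, so the result
    is invariant to positive rescaling of the signal.  When two maxima
    fall within ``min_separation`` the higher one is kept (ties: the
    earlier).  A constant channel has no peaks and returns an empty list.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 3:
        raise InputDomainError("need at least 3 samples to detect peaks")
    if not 0 < min_prominence_frac <= 1:
        raise InputDomainError(
            f"min_prominence_frac must be in (0, 1], got {min_prominence_frac}"
        )
    if min_separation <= 0:
        raise InputDomainError(f"min_separation must be > 0, got {min_separation}")
    rng = float(values.max() - values.min())
    if rng == 0.0:
        return PeakList(np.empty(0), np.empty(0),
                        min_prominence_frac, min_separation)
    step = float(np.min(np.diff(times)))
    distance = max(1, int(math.ceil(min_separation / step - 1e-9)))
    idx, _ = find_peaks(values, prominence=min_prominence_frac * rng,
                        distance=distance)
    return PeakList(times[idx], values[idx], min_prominence_frac, min_separation)


def detect_channel_peaks(trace: TraceSet, channel: str, **kw) -> PeakList:
    """Convenience wrapper: run :func:`detect_peaks` on a named channel."""
    return detect_peaks(trace.times, trace.channel(channel), **kw)


def estimate_period(peaks: PeakList) -> float:
    """Median inter-peak interval (min); needs at least three peaks."""
    if len(peaks) < 3:
        raise InsufficientPeaksError(
            f"period estimation needs >= 3 peaks, got {len(peaks)}"
        )
    return float(np.median(np.diff(peaks.times)))


def peak_lags(sender: PeakList, receiver: PeakList,
              max_window: float | None = None,
              exclude_first_receiver: bool = True) -> LagStats:
    """Match receiver peaks to nearest sender peaks and report the lags.

    Each receiver peak is paired with the nearest sender peak within
    ``max_window`` (default: half the sender period); unmatched receiver
    peaks are dropped and counted.  The first receiver peak — the strong
    transient burst seen when the responder first reaches quorum — is
    excluded by default.  Lag sign is receiver minus sender (positive =
    receiver later).
    """
    if len(sender) == 0 or len(receiver) == 0:
        raise InputDomainError("both peak lists must be non-empty")
    if max_window is None:
        max_window = estimate_period(sender) / 2.0
    if max_window <= 0:
        raise InputDomainError(f"max_window must be > 0, got {max_window}")
    rec_times = receiver.times[1:] if exclude_first_receiver else receiver.times
    lags, unmatched = [], 0
    for rt in rec_times:
        d = rt - sender.times
        j = int(np.argmin(np.abs(d)))
        if abs(d[j]) <= max_window:
            lags.append(float(d[j]))
        else:
            unmatched += 1
    if not lags:
        raise NoMatchError(
            f"no receiver peak matched a sender peak within {max_window} min "
            f"(sender: {len(sender)} peaks, receiver: {len(receiver)} peaks)"
        )
    lags = np.asarray(lags)
    abs_lags = np.abs(lags)
    q75, q25 = np.percentile(lags, [75, 25])
    return LagStats(
        lags=lags,
        median_abs_lag=float(np.median(abs_lags)),
        iqr=float(q75 - q25),
        n_matched=len(lags),
        n_unmatched_receiver=unmatched,
        first_receiver_peak_excluded=exclude_first_receiver,
    )


def first_peak_ratio(peaks: PeakList) -> float:
    """First peak amplitude over the median of the remaining amplitudes.

    A ratio > 1 marks the initial transient burst of the responder (the
    first induction overshoots before its own negative feedback builds
    up).
    """
    if len(peaks) < 3:
        raise InsufficientPeaksError(
            f"first-peak ratio needs >= 3 peaks, got {len(peaks)}"
        )
    return float(peaks.amplitudes[0] / np.median(peaks.amplitudes[1:]))


def _trough_peak_ratio(values: np.ndarray, times: np.ndarray,
                       peaks: PeakList) -> float:
    """Median of trough / mean-adjacent-peak over successive peak pairs."""
    ratios = []
    for t_left, t_right, a_left, a_right in zip(
        peaks.times[:-1], peaks.times[1:],
        peaks.amplitudes[:-1], peaks.amplitudes[1:],
    ):
        between = (times > t_left) & (times < t_right)
        if not np.any(between):
            continue
        trough = float(values[between].min())
        ratios.append(trough / ((a_left + a_right) / 2.0))
    return float(np.median(ratios)) if ratios else float("nan")


def classify_response(times: np.ndarray, values: np.ndarray, basal: float,
                      reference_peak: float | None = None,
                      min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                      min_separation: float = DEFAULT_SEPARATION,
                      silent_factor: float = 2.0,
                      suppressed_frac: float = 0.05,
                      trough_ratio_max: float = 0.5,
                      plateau_frac: float = 0.8,
                      accumulation_factor: float = 5.0) -> PhenotypeCall:
    """Classify a channel as silent / suppressed / oscillatory / accumulating.

    The rules quantify the qualitative experimental read-outs and are
    evaluated in order:

    1. *silent* — the channel never exceeds ``silent_factor`` x basal
       (the receiver behind a solid block "stays dark");
    2. *suppressed* — given a reference peak (e.g. the receiver of the
       full oscillator), the maximum stays below ``suppressed_frac`` of
       it (continuous lactonase expression quenches the response);
    3. *oscillatory* — at least three detected peaks whose intervening
       troughs drop below ``trough_ratio_max`` of the adjacent peaks;
    4. *accumulating* — the signal plateaus near its maximum
       (final >= ``plateau_frac`` x max) well above basal.

    Anything else is assigned the nearest of the four labels with
    ``degraded_confidence`` set.
    """
    if basal < 0:
        raise InputDomainError(f"basal must be >= 0, got {basal}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    vmax = float(values.max()) if values.size else 0.0
    vend = float(values[-1]) if values.size else 0.0
    evidence: dict[str, float] = {
        "max": vmax,
        "final": vend,
        "basal": float(basal),
        "end_max_ratio": vend / vmax if vmax > 0 else 0.0,
        "peak_count": 0.0,
        "trough_peak_ratio": float("nan"),
    }
    if reference_peak is not None:
        evidence["reference_peak"] = float(reference_peak)
        evidence["max_over_reference"] = (
            vmax / reference_peak if reference_peak > 0 else float("inf")
        )

    if values.size < 3 or vmax <= silent_factor * basal:
        return PhenotypeCall("silent", evidence)
    if reference_peak is not None and vmax < suppressed_frac * reference_peak:
        return PhenotypeCall("suppressed", evidence)

    peaks = detect_peaks(times, values, min_prominence_frac, min_separation)
    evidence["peak_count"] = float(len(peaks))
    if len(peaks) >= 3:
        tr = _trough_peak_ratio(values, times, peaks)
        evidence["trough_peak_ratio"] = tr
        if tr < trough_ratio_max:
            return PhenotypeCall("oscillatory", evidence)
    if vend >= plateau_frac * vmax and vmax > accumulation_factor * basal:
        return PhenotypeCall("accumulating", evidence)

    # fallback: nearest label by the same evidence, flagged low-confidence
    if len(peaks) >= 2:
        return PhenotypeCall("oscillatory", evidence, degraded_confidence=True)
    if vend >= 0.5 * vmax and vmax > silent_factor * basal:
        return PhenotypeCall("accumulating", evidence, degraded_confidence=True)
    return PhenotypeCall("silent", evidence, degraded_confidence=True)
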