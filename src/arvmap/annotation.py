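"""Reference annotation on the roving self-reference bipole.

The mapping catheter's own B2-C2 bipole times every beat: activations are
detected as supra-threshold peaks of the rectified bipolar signal, beats
whose cycle length strays from the running median are discarded, a window
of interest (WOI) is opened around each accepted annotation (and widened if
electrograms spill over its edges), and deflections coincident with
ventricular far-field events are rejected by a proximity score.  The AF
cycle length (AFCL) is estimated from consecutive appendage electrograms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

#: hard floor of the auto-sensitivity threshold (mV) — the low-amplitude
#: detection setting.
SENSITIVITY_FLOOR_MV = 0.02


class InsufficientActivationsError(ValueError):
    """Raised when fewer than three reference activations are detected."""


@dataclass(frozen=True)
class DetectorConfig:
    """Peak-amplitude reference detector settings.

    ``auto_sensitivity`` sets the threshold to 0.3x the median beat-wise
    peak-to-peak of the signal, floored at 0.02 mV; ``fixed`` uses
    ``sensitivity_mv`` directly.  ``refractory_ms`` suppresses secondary
    peaks after each detection (larger peak wins on conflict).
    """

    mode: str = "auto_sensitivity"
    sensitivity_mv: float | None = None
    refractory_ms: float = 90.0

    def __post_init__(self) -> None:
        if self.mode not in ("auto_sensitivity", "fixed"):
            raise ValueError("mode must be 'auto_sensitivity' or 'fixed'")
        if self.mode == "fixed":
            if self.sensitivity_mv is None or self.sensitivity_mv <= 0:
                raise ValueError("fixed mode requires a positive sensitivity_mv")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")


@dataclass
class ReferenceAnnotations:
    """Ordered reference activation times (ms) with the median cycle length."""

    times_ms: np.ndarray
    median_cl_ms: float
    threshold_mv: float

    def __len__(self) -> int:
        return self.times_ms.size


def auto_sensitivity_threshold(
    signal: np.ndarray, sample_rate_hz: float, window_ms: float = 200.0
) -> float:
    """0.3 x median windowed peak-to-peak, floored at 0.02 mV."""
    n_win = max(1, int(round(window_ms * sample_rate_hz / 1000.0)))
    n = (signal.size // n_win) * n_win
    if n == 0:
        return SENSITIVITY_FLOOR_MV
    chunks = signal[:n].reshape(-1, n_win)
    pp = chunks.max(axis=1) - chunks.min(axis=1)
    return max(0.3 * float(np.median(pp)), SENSITIVITY_FLOOR_MV)


def detect_reference(
    signal: np.ndarray,
    sample_rate_hz: float,
    config: DetectorConfig = DetectorConfig(),
    t_start_ms: float = 0.0,
) -> ReferenceAnnotations:
    """Detect reference activations as rectified peak amplitudes.

    Peaks of ``|signal|`` are annotated when the deflection's local
    peak-to-peak amplitude (within +/-10 ms) reaches the sensitivity
    threshold, respecting the refractory period (the larger of two
    conflicting peaks is kept; the earlier on a tie).  Raises
    :class:`InsufficientActivationsError` with fewer than 3 detections.
    """
    sig = np.asarray(signal, dtype=float)
    x = np.abs(sig)
    if config.mode == "fixed":
        thr = float(config.sensitivity_mv)
    else:
        thr = auto_sensitivity_threshold(sig, sample_rate_hz)
    distance = max(1, int(round(config.refractory_ms * sample_rate_hz / 1000.0)))
    # sensitivity applies to the deflection's peak-to-peak amplitude: a
    # symmetric biphasic of P-P v has rectified lobes of only v/2
    idx, _ = find_peaks(x, height=0.4 * thr, distance=distance)
    half = max(1, int(round(10.0 * sample_rate_hz / 1000.0)))
    keep = []
    for i in idx:
        w = sig[max(0, i - half) : i + half + 1]
        if w.max() - w.min() >= thr:
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    if idx.size < 3:
        raise InsufficientActivationsError(
            f"insufficient reference activations ({idx.size} < 3) "
            f"at sensitivity {thr:.3g} mV"
        )
    times = t_start_ms + idx * 1000.0 / sample_rate_hz
    median_cl = float(np.median(np.diff(times)))
    return ReferenceAnnotations(
        times_ms=times, median_cl_ms=median_cl, threshold_mv=thr
    )


# --- beats ------------------------------------------------------------------


@dataclass
class Beat:
    """One reference beat with its window of interest and filter state."""

    ref_time_ms: float
    woi_half_ms: float = 30.0
    accepted: bool = True
    rejection_reason: str = "none"
    ventricular_score: float | None = None

    @property
    def woi(self) -> tuple[float, float]:
        return (self.ref_time_ms - self.woi_half_ms, self.ref_time_ms + self.woi_half_ms)


def filter_beats(
    annotations: ReferenceAnnotations,
    tolerance_ms: float = 50.0,
    initial_woi_half_ms: float = 30.0,
) -> list[Beat]:
    """Apply the cycle-length tolerance filter (inclusive +/- tolerance).

    A beat is accepted iff its interval to the previous annotation deviates
    from the median cycle length by at most ``tolerance_ms``; the first beat
    is assessed against the following interval.
    """
    if tolerance_ms <= 0:
        raise ValueError("tolerance must be positive")
    t = annotations.times_ms
    beats = []
    for i, ref in enumerate(t):
        interval = t[i] - t[i - 1] if i > 0 else t[1] - t[0]
        ok = abs(interval - annotations.median_cl_ms) <= tolerance_ms
        beats.append(
            Beat(
                ref_time_ms=float(ref),
                woi_half_ms=initial_woi_half_ms,
                accepted=bool(ok),
                rejection_reason="none" if ok else "cl_tolerance",
            )
        )
    return beats


def set_woi(
    beat: Beat,
    mapping_signals: np.ndarray,
    sample_rate_hz: float,
    t_start_ms: float = 0.0,
    *,
    amplitude_threshold_mv: float = 0.1,
    widen_step_ms: float = 10.0,
    max_half_ms: float = 150.0,
    median_cl_ms: float | None = None,
) -> Beat:
    """Widen the beat's WOI while electrograms extend beyond its edges.

    The half-width grows in ``widen_step_ms`` increments while any mapping
    electrode shows supra-threshold signal in the zone one step beyond
    either window edge, capped at ``min(max_half_ms, median_cl/2)``.
    Widening is monotone — the window never shrinks.
    """
    sig = np.atleast_2d(np.asarray(mapping_signals, dtype=float).T).T  # (n, ch)
    amp = np.abs(sig).max(axis=1)
    dt = 1000.0 / sample_rate_hz
    n = amp.size
    cap = max_half_ms if median_cl_ms is None else min(max_half_ms, median_cl_ms / 2)

    def zone_active(lo_ms: float, hi_ms: float) -> bool:
        i0 = max(0, int(np.ceil((lo_ms - t_start_ms) / dt)))
        i1 = min(n, int(np.floor((hi_ms - t_start_ms) / dt)) + 1)
        return i1 > i0 and bool(np.any(amp[i0:i1] >= amplitude_threshold_mv))

    half = beat.woi_half_ms
    while half < cap:
        lo = beat.ref_time_ms - half
        hi = beat.ref_time_ms + half
        if zone_active(hi, hi + widen_step_ms) or zone_active(lo - widen_step_ms, lo):
            half = min(half + widen_step_ms, cap)
        else:
            break
    return replace(beat, woi_half_ms=half)


def ventricular_score(
    deflection_time_ms: float,
    ventricular_times_ms: np.ndarray,
    proximity_constant_ms: float = 25.0,
) -> float:
    """Proximity score in [-1, 1]: ``1 - 2 exp(-delta/tau)``.

    ``delta`` is the distance to the nearest ventricular event; deflections
    coincident with ventricular activity score -1 and are rejected by the
    >= 0 threshold, distant deflections approach +1.  With no ventricular
    events available the score defaults to 1 with a logged warning.
    """
    v = np.asarray(ventricular_times_ms, dtype=float)
    if v.size == 0:
        log.warning("no ventricular events available; score defaults to 1")
        return 1.0
    delta = float(np.min(np.abs(v - deflection_time_ms)))
    return 1.0 - 2.0 * np.exp(-delta / proximity_constant_ms)


# --- AF cycle length --------------------------------------------------------


@dataclass
class AfclEstimate:
    """Mean AF cycle length from consecutive appendage electrograms."""

    channel: str
    mean_cl_ms: float
    n_intervals: int
    flagged: bool = False


def compute_afcl(
    annotation_times_ms: np.ndarray,
    n: int = 10,
    channel: str = "LAA",
    stability_tolerance_ms: float = 50.0,
) -> AfclEstimate:
    """Mean of ``n`` consecutive inter-annotation intervals.

    The window starts at the first *stable* annotation — the first position
    whose following ``n`` intervals all lie within the cycle-length
    tolerance of the median interval (guarding against missed detections
    that would double an interval).  With fewer than ``n`` intervals the
    estimate is computed over what is available and flagged.
    """
    t = np.asarray(annotation_times_ms, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two annotations for a cycle length")
    intervals = np.diff(t)
    med = float(np.median(intervals))
    if intervals.size < n:
        warnings.warn(
            f"only {intervals.size} intervals available (requested {n})",
            stacklevel=2,
        )
        return AfclEstimate(
            channel=channel,
            mean_cl_ms=float(intervals.mean()),
            n_intervals=int(intervals.size),
            flagged=True,
        )
    ok = np.abs(intervals - med) <= stability_tolerance_ms
    start = None
    for i in range(intervals.size - n + 1):
        if np.all(ok[i : i + n]):
            start = i
            break
    if start is None:
        # no fully stable run: take the window with the most stable intervals
        counts = np.convolve(ok.astype(int), np.ones(n, dtype=int), mode="valid")
        start = int(np.argmax(counts))
        window = intervals[start : start + n]
        return AfclEstimate(
            channel=channel,
            mean_cl_ms=float(window.mean()),
            n_intervals=n,
            flagged=True,
        )
    window = intervals[start : start + n]
    return AfclEstimate(
        channel=channel, mean_cl_ms=float(window.mean()), n_intervals=n
    )
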