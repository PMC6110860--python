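"""Single-channel gating analysis.

Idealizes patch-clamp current traces into discrete conductance levels and
derives the gating statistics of tension-gated (mechanosensitive)
channels: unitary conductance, open probability (NPo), activation
threshold pressures and their ratios, opening/closing hysteresis under
symmetric pressure ramps, and current-voltage rectification.

Idealization is a half-amplitude threshold crossing with a deadband and a
minimum-dwell filter; the closed-level baseline is taken from the
zero-pressure prefix of the recording and the unitary amplitude, unless
hinted, is estimated from the separation of the two dominant modes of the
all-points current histogram and then refined from level-resolved sample
means (transition-adjacent samples excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .errors import (
    BaselineError,
    InsufficientDataError,
    InvalidInputError,
    NoActivationError,
    NoEventError,
    UndefinedConductanceError,
)
from .units import NS_TO_PS

__all__ = [
    "RecordingTrace",
    "IdealizedTrace",
    "GatingThresholds",
    "VoltagePoint",
    "RectificationResult",
    "TraceIdealizer",
    "IVRectifier",
    "idealize",
    "unitary_conductance",
    "open_probability",
    "first_opening_pressure",
    "first_opening_by_class",
    "threshold_ratio",
    "hysteresis",
    "hysteresis_voltage_curve",
    "iv_rectification",
]


@dataclass
class RecordingTrace:
    """Synchronized current/pressure samples of one patch-clamp sweep.

    ``pressure`` keeps the acquisition sign convention: suction applied to
    the pipette is negative.  ``voltage`` is the constant pipette voltage
    of the sweep in mV.
    """

    time: np.ndarray       # s
    current: np.ndarray    # pA
    pressure: np.ndarray   # mmHg, <= 0 during suction
    sampling_rate: float   # Hz
    voltage: float         # mV
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        n = len(self.time)
        if len(self.current) != n or len(self.pressure) != n:
            raise InvalidInputError("time, current and pressure must have equal length")
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be > 0")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class IdealizedTrace:
    """Discrete-level representation of a recording.

    ``transition_times[k]`` is the time of the first sample at
    ``levels[k + 1]``; ``levels[0]`` is the level at the start of the
    trace (level 0 = all channels closed).
    """

    transition_times: np.ndarray   # s, strictly increasing
    levels: np.ndarray             # int, len == len(transition_times) + 1
    baseline_current: float        # pA
    unitary_amplitude: float       # pA, signed (negative at negative voltage)
    start_time: float
    end_time: float
    substate_occupancy: float = 0.0  # fraction of open samples in the substate band

    def __post_init__(self):
        self.transition_times = np.asarray(self.transition_times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=int)
        if len(self.levels) != len(self.transition_times) + 1:
            raise InvalidInputError("levels must have one more entry than transitions")
        if np.any(np.diff(self.transition_times) <= 0):
            raise InvalidInputError("transitions must be time-ordered")
        if len(self.transition_times) and np.any(np.diff(self.levels) == 0):
            raise InvalidInputError("level must change at every transition")

    @property
    def n_transitions(self) -> int:
        return len(self.transition_times)

    @property
    def dwell_times(self) -> np.ndarray:
        """Duration of each constant-level epoch, s."""
        edges = np.concatenate(
            ([self.start_time], self.transition_times, [self.end_time]))
        return np.diff(edges)

    def level_at(self, times) -> np.ndarray:
        """Level index at the given times (piecewise-constant lookup)."""
        idx = np.searchsorted(self.transition_times, np.asarray(times, float),
                              side="right")
        return self.levels[idx]

    def has_opening(self) -> bool:
        return bool(np.any(self.levels > 0))


@dataclass(frozen=True)
class GatingThresholds:
    """First-opening and first-closing pressures of one ramp protocol."""

    opening_pressure: float   # mmHg, signed
    closing_pressure: float   # mmHg, signed (0 when stuck open)
    hysteresis_ratio: float   # |closing| / |opening|; 0 when stuck open
    stuck_open: bool = False


@dataclass(frozen=True)
class VoltagePoint:
    voltage: float
    mean_ratio: float
    sem: float
    n: int
    n_stuck: int


@dataclass(frozen=True)
class RectificationResult:
    g_pos_pS: float
    g_neg_pS: float
    reduction: float


def _baseline_prefix(trace: RecordingTrace, pressure_tol_fraction: float):
    """Index one past the zero-pressure prefix used for baseline estimation."""
    peak = float(np.max(np.abs(trace.pressure)))
    tol = pressure_tol_fraction * peak if peak > 0 else np.inf
    quiet = np.abs(trace.pressure) <= max(tol, 1e-12)
    if not quiet[0]:
        return 0
    end = int(np.argmin(quiet)) if not quiet.all() else len(trace)
    return end


class TraceIdealizer(BaseEstimator):
    """Half-amplitude threshold idealizer with deadband and dwell filtering.

    Parameters
    ----------
    unitary_amplitude : float or None
        Signed unitary current amplitude hint in pA.  When None the
        amplitude is estimated from the all-points histogram.
    deadband : float, default 0.15
        Hysteresis margin around the half-amplitude threshold, as a
        fraction of the unitary amplitude.  A level switch requires the
        signal to cross the midpoint by this extra margin, which
        suppresses threshold chatter in noise.
    min_dwell : int, default 2
        Minimum event duration in samples; shorter excursions are merged
        into the surrounding level.
    baseline_pressure_tol : float, default 0.02
        Samples whose |pressure| is below this fraction of the peak
        pressure, at the start of the sweep, form the baseline segment.
    substate_band : (float, float), default (0.25, 0.75)
        Open-level residual band (in amplitude fractions) counted as
        sub-conductance occupancy.

    Attributes
    ----------
    baseline_ : float
        Closed-level current, pA.
    unitary_amplitude_ : float
        Estimated (or hinted) signed unitary amplitude, pA.
    noise_sd_ : float
        Robust baseline noise estimate, pA.
    """

    def __init__(self, unitary_amplitude=None, deadband: float = 0.15,
                 min_dwell: int = 2, baseline_pressure_tol: float = 0.02,
                 substate_band=(0.25, 0.75)):
        self.unitary_amplitude = unitary_amplitude
        self.deadband = deadband
        self.min_dwell = min_dwell
        self.baseline_pressure_tol = baseline_pressure_tol
        self.substate_band = substate_band

    # -- fitting -----------------------------------------------------------

    def fit(self, trace: RecordingTrace, y=None):
        if len(trace) < 10:
            raise InvalidInputError("trace too short to idealize (< 10 samples)")
        n0 = _baseline_prefix(trace, self.baseline_pressure_tol)
        if n0 < 10:
            raise BaselineError(
                "no zero-pressure prefix (>= 10 samples) for baseline estimation")
        prefix = trace.current[:n0]
        self.baseline_ = float(np.median(prefix))
        mad = float(np.median(np.abs(prefix - self.baseline_)))
        self.noise_sd_ = 1.4826 * mad
        if self.unitary_amplitude is not None:
            self.unitary_amplitude_ = float(self.unitary_amplitude)
        else:
            self.unitary_amplitude_ = self._estimate_amplitude(trace.current)
        if self.unitary_amplitude_:
            self.unitary_amplitude_ = self._refine_amplitude(trace.current)
        return self

    def _estimate_amplitude(self, current: np.ndarray) -> float:
        """Separation of the two dominant modes of the all-points histogram."""
        counts, edges = np.histogram(current, bins=256)
        centers = 0.5 * (edges[:-1] + edges[1:])
        kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
        # zero-pad so modes in the first/last bin are still detected
        padded = np.concatenate(([0.0], smooth, [0.0]))
        peaks, _ = find_peaks(padded, prominence=0.01 * smooth.max())
        peaks -= 1
        if len(peaks) == 0:
            return 0.0
        # the baseline mode is the peak nearest the estimated baseline
        base_peak = peaks[np.argmin(np.abs(centers[peaks] - self.baseline_))]
        min_sep = max(4.0 * self.noise_sd_, 3.0 * (edges[1] - edges[0]))
        # a genuine open level carries real probability mass; this rejects
        # spurious tail bumps of the baseline noise distribution
        min_height = max(0.02 * smooth[base_peak], 2.0)
        others = [p for p in peaks
                  if abs(centers[p] - centers[base_peak]) >= min_sep
                  and smooth[p] >= min_height]
        if not others:
            return 0.0
        open_peak = max(others, key=lambda p: smooth[p])
        return float(centers[open_peak] - centers[base_peak])

    def _refine_amplitude(self, current: np.ndarray) -> float:
        """Refine the amplitude from level-resolved means.

        Samples adjacent to level changes are excluded so that filter
        smearing of the transitions does not bias the level means.
        """
        amp = self.unitary_amplitude_
        for _ in range(2):
            u = (current - self.baseline_) / amp
            levels = np.clip(np.round(u), 0, None).astype(int)
            changed = np.zeros(len(levels), dtype=bool)
            changed[1:] |= np.diff(levels) != 0
            changed[:-1] |= np.diff(levels) != 0
            steady = ~changed
            mask1 = steady & (levels == 1)
            if np.count_nonzero(mask1) >= 50:
                amp = float(np.mean(current[mask1]) - self.baseline_)
            else:
                open_mask = steady & (levels >= 1)
                if np.count_nonzero(open_mask) == 0:
                    return amp
                amp = float(np.mean(
                    (current[open_mask] - self.baseline_) / levels[open_mask]))
        return amp

    # -- transform ---------------------------------------------------------

    def transform(self, trace: RecordingTrace) -> IdealizedTrace:
        amp = self.unitary_amplitude_
        if not amp:
            return IdealizedTrace(
                transition_times=np.empty(0), levels=np.zeros(1, dtype=int),
                baseline_current=self.baseline_, unitary_amplitude=0.0,
                start_time=float(trace.time[0]), end_time=float(trace.time[-1]))
        u = (trace.current - self.baseline_) / amp
        levels = self._threshold_levels(u)
        levels = self._merge_short_dwells(levels)
        change = np.flatnonzero(np.diff(levels) != 0) + 1
        seq = levels[np.concatenate(([0], change))]
        occupancy = self._substate_occupancy(u, levels)
        return IdealizedTrace(
            transition_times=trace.time[change], levels=seq,
            baseline_current=self.baseline_, unitary_amplitude=float(amp),
            start_time=float(trace.time[0]), end_time=float(trace.time[-1]),
            substate_occupancy=occupancy)

    def fit_transform(self, trace: RecordingTrace, y=None) -> IdealizedTrace:
        return self.fit(trace).transform(trace)

    def _threshold_levels(self, u: np.ndarray) -> np.ndarray:
        """Hysteresis quantizer: switch level only past midpoint + deadband."""
        margin = 0.5 + self.deadband
        out = np.empty(len(u), dtype=int)
        level = 0
        for i, ui in enumerate(u):
            if abs(ui - level) > margin:
                level = max(int(round(ui)), 0)
            out[i] = level
        return out

    def _merge_short_dwells(self, levels: np.ndarray) -> np.ndarray:
        if self.min_dwell <= 1:
            return levels
        levels = levels.copy()
        for _ in range(8):  # bounded; converges in a couple of passes
            change = np.flatnonzero(np.diff(levels) != 0) + 1
            if len(change) == 0:
                break
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(levels)]))
            short = np.flatnonzero((ends - starts) < self.min_dwell)
            short = short[short > 0]  # the initial epoch is exempt
            if len(short) == 0:
                break
            for k in short:
                levels[starts[k]:ends[k]] = levels[starts[k] - 1]
        return levels

    def _substate_occupancy(self, u: np.ndarray, levels: np.ndarray) -> float:
        open_mask = levels >= 1
        if not open_mask.any():
            return 0.0
        resid = u[open_mask] - levels[open_mask]
        lo, hi = self.substate_band
        in_band = (resid <= -lo) & (resid >= -hi)
        return float(np.mean(in_band))


def idealize(trace: RecordingTrace, unitary_amplitude_hint=None,
             **kwargs) -> IdealizedTrace:
    """Idealize a recording (see :class:`TraceIdealizer`)."""
    return TraceIdealizer(unitary_amplitude=unitary_amplitude_hint,
                          **kwargs).fit_transform(trace)


def unitary_conductance(idealized: IdealizedTrace, pipette_voltage: float) -> float:
    """Unitary conductance in nS: single-channel current over voltage."""
    if pipette_voltage == 0:
        raise UndefinedConductanceError("conductance undefined at 0 mV")
    if idealized.unitary_amplitude == 0:
        return 0.0
    if not idealized.has_opening():
        raise NoEventError("no open events in the idealized trace")
    return abs(idealized.unitary_amplitude) / abs(pipette_voltage)


def open_probability(idealized: IdealizedTrace, window) -> float:
    """Time-weighted mean level index (NPo) over ``window = (t0, t1)``."""
    t0, t1 = float(window[0]), float(window[1])
    t0 = max(t0, idealized.start_time)
    t1 = min(t1, idealized.end_time)
    if t1 <= t0:
        raise InvalidInputError("empty or out-of-span window")
    edges = np.concatenate(
        ([idealized.start_time], idealized.transition_times,
         [idealized.end_time]))
    lo = np.clip(edges[:-1], t0, t1)
    hi = np.clip(edges[1:], t0, t1)
    return float(np.sum((hi - lo) * idealized.levels) / (t1 - t0))


def _pressure_at(trace: RecordingTrace, t: float) -> float:
    idx = int(np.searchsorted(trace.time, t, side="left"))
    idx = min(idx, len(trace) - 1)
    return float(trace.pressure[idx])


def first_opening_pressure(trace: RecordingTrace,
                           idealized: IdealizedTrace) -> float:
    """Pressure (mmHg, signed) at the first all-closed -> open transition."""
    openings = np.flatnonzero(
        (idealized.levels[:-1] == 0) & (idealized.levels[1:] > 0))
    if len(openings) == 0:
        raise NoActivationError("no channel opening during suction")
    return _pressure_at(trace, float(idealized.transition_times[openings[0]]))


def first_opening_by_class(trace: RecordingTrace, idealized: IdealizedTrace,
                           unitary_amplitudes) -> dict:
    """First-opening pressure per amplitude class.

    Each opening transition's current step is assigned to the nearest of
    the configured unitary amplitudes (pA, magnitudes; ties go to the
    smaller amplitude).  Used to separate channel species of well-spaced
    conductance recorded in the same patch.

    Returns a dict mapping each configured amplitude to its signed
    first-opening pressure in mmHg (absent if that class never opened).
    """
    amps = sorted(float(a) for a in unitary_amplitudes)
    if not amps or any(a <= 0 for a in amps):
        raise InvalidInputError("amplitude classes must be positive magnitudes")
    step_pA = np.diff(idealized.levels) * abs(idealized.unitary_amplitude)
    first: dict = {}
    for k, step in enumerate(step_pA):
        if step <= 0:
            continue
        cls = min(amps, key=lambda a: (abs(a - step), a))
        if cls not in first:
            first[cls] = _pressure_at(
                trace, float(idealized.transition_times[k]))
    return first


def threshold_ratio(p_reference: float, p_channel: float) -> float:
    """Activation-threshold ratio |p_reference| / |p_channel|."""
    if p_channel == 0:
        raise InvalidInputError("zero denominator threshold")
    return abs(p_reference) / abs(p_channel)


def hysteresis(trace: RecordingTrace, idealized: IdealizedTrace,
               zero_pressure_tol: float = 0.02) -> GatingThresholds:
    """Opening/closing thresholds of a symmetric loading/unloading ramp.

    The opening pressure is read at the first all-closed -> open
    transition of the loading phase; the closing pressure at the last
    open -> all-closed transition of the unloading phase (with several
    channels the return to the all-closed level is the unambiguous
    marker).  If the patch is still conducting when the suction returns
    to zero the channel is flagged stuck open and the ratio is 0.
    """
    p_open = first_opening_pressure(trace, idealized)
    t_peak = float(trace.time[np.argmax(np.abs(trace.pressure))])
    tol = zero_pressure_tol * float(np.max(np.abs(trace.pressure)))

    times, levels = idealized.transition_times, idealized.levels
    closed_idx = [k for k in range(len(times))
                  if levels[k + 1] == 0 and times[k] > t_peak]
    final_level = levels[-1]
    if final_level > 0 or not closed_idx:
        # never returned to all-closed before the end of the sweep
        return GatingThresholds(opening_pressure=p_open, closing_pressure=0.0,
                                hysteresis_ratio=0.0, stuck_open=True)
    t_close = float(times[closed_idx[-1]])
    p_close = _pressure_at(trace, t_close)
    if abs(p_close) <= tol:
        # closed only once the suction was fully released
        return GatingThresholds(opening_pressure=p_open, closing_pressure=p_close,
                                hysteresis_ratio=0.0, stuck_open=True)
    ratio = abs(p_close) / abs(p_open) if p_open != 0 else 0.0
    return GatingThresholds(opening_pressure=p_open, closing_pressure=p_close,
                            hysteresis_ratio=ratio, stuck_open=False)


def hysteresis_voltage_curve(traces, idealizer: TraceIdealizer | None = None):
    """Per-voltage mean +/- SEM of hysteresis ratios.

    Traces are grouped by their pipette voltage; each trace contributes
    one ratio (stuck-open sweeps contribute 0, as recorded in ``n_stuck``).
    Returns a list of :class:`VoltagePoint` sorted by voltage.
    """
    traces = list(traces)
    if not traces:
        raise InvalidInputError("no traces supplied")
    groups: dict = {}
    for trace in traces:
        ideal = (idealizer.fit_transform(trace) if idealizer is not None
                 else idealize(trace))
        th = hysteresis(trace, ideal)
        groups.setdefault(float(trace.voltage), []).append(th)
    out = []
    for v in sorted(groups):
        ratios = np.array([t.hysteresis_ratio for t in groups[v]])
        n = len(ratios)
        sem = float(np.std(ratios, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(VoltagePoint(
            voltage=v, mean_ratio=float(np.mean(ratios)), sem=sem, n=n,
            n_stuck=sum(t.stuck_open for t in groups[v])))
    return out


class IVRectifier(BaseEstimator):
    """Piecewise slope-conductance fit of a single-channel I-V relation.

    Fits independent least-squares lines through the positive- and
    negative-voltage points; the fitted attributes are the slope
    conductances in pS and the fractional current reduction at negative
    voltages, ``1 - G_neg / G_pos``.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        """Fit from voltages X (mV) and unitary currents y (pA)."""
        v = np.asarray(X, dtype=float).reshape(-1)
        i = np.asarray(y, dtype=float).reshape(-1)
        if v.shape != i.shape:
            raise InvalidInputError("voltages and currents must have equal length")
        pos, neg = v > 0, v < 0
        if np.count_nonzero(pos) < 2 or np.count_nonzero(neg) < 2:
            raise InsufficientDataError(
                "need >= 2 I-V points on each side of 0 mV")
        self.g_pos_ = self._slope(v[pos], i[pos]) * NS_TO_PS
        self.g_neg_ = self._slope(v[neg], i[neg]) * NS_TO_PS
        self.reduction_ = 1.0 - self.g_neg_ / self.g_pos_
        self.result_ = RectificationResult(
            g_pos_pS=self.g_pos_, g_neg_pS=self.g_neg_,
            reduction=self.reduction_)
        return self

    def _slope(self, v, i) -> float:
        if self.fit_intercept:
            from scipy.stats import linregress
            return float(linregress(v, i).slope)
        return float(np.dot(v, i) / np.dot(v, v))


def iv_rectification(points, fit_intercept: bool = True) -> RectificationResult:
    """Slope conductances (pS) from a list of (mV, pA) points."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (voltage_mV, current_pA) pairs")
    rect = IVRectifier(fit_intercept=fit_intercept)
    rect.fit(pts[:, 0], pts[:, 1])
    return rect.result_
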