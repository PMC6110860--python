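"""Synthetic data with known ground truth.

Three generators emulate the raw inputs of the analysis pipelines:

* :func:`simulate_recording` — stochastic tension-gated channel currents
  under a pressure protocol.  Each channel is a two-state (closed/open)
  Markov chain whose rates depend exponentially on the Laplace tension of
  the patch:  ``k_open = k0 * exp(beta (T - T_half))`` and
  ``k_close = k0 * exp(-beta (T - T_half)) * exp(-gamma * max(Vp, 0))``.
  The symmetric exponential is the minimal phenomenological scheme that
  reproduces tension thresholds; the ``gamma`` term suppresses closing at
  positive pipette voltages and produces voltage-dependent hysteresis up
  to the stuck-open regime.  The chain is propagated with the exact
  two-state transition probabilities with rates frozen over each sample
  interval, so transitions land on sample boundaries and the ground-truth
  event log matches the recording resolution exactly.
* :func:`generate_ma_experiment` — aspiration geometry series whose
  areal strains follow a prescribed modulus ``alpha = T / K_A + noise``;
  the protrusion length is solved (bisection) so the conical-pipette area
  reproduces each target strain, making the generator an exact inverse of
  the analysis pipeline in the noiseless limit.
* :func:`generate_slab_areas` — slab-area matrices whose mean follows
  ``A0 (1 + tau / K_A)`` with multiplicative Gaussian noise.

All randomness flows from ``NoiseSpec.seed``; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GeometrySolveError, InvalidInputError
from .gating import RecordingTrace
from .mechanics import PatchGeometry, aspirated_area, laplace_tension

__all__ = [
    "ChannelSpec",
    "NoiseSpec",
    "PressureProtocol",
    "Event",
    "PRESETS",
    "get_preset",
    "build_protocol",
    "simulate_recording",
    "generate_ma_experiment",
    "generate_slab_areas",
    "DEFAULT_PIPETTE",
]

RATE_CAP = 1e6          # 1/s; above this the chain is a per-sample stationary draw
EXP_CLIP = 60.0         # clip on rate exponents, avoids overflow far from midpoint
GEOMETRY_COLUMNS = [
    "pressure_mmHg", "tip_radius_um", "dome_radius_um",
    "protrusion_um", "dome_height_um", "curvature_um",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Phenomenological description of one mechanosensitive channel type.

    ``conductance_pos``/``conductance_neg`` are the unitary conductances
    (nS) at positive and negative pipette voltage (rectifying channels
    differ); ``tension_midpoint`` (mN/m) is the half-activation tension,
    ``sensitivity`` (1/(mN/m)) the steepness of the rate-tension coupling,
    ``base_rate`` (1/s) the rate scale at midpoint, and
    ``voltage_coupling`` (1/mV) scales the closing-rate suppression at
    positive pipette voltage.
    """

    name: str
    conductance_pos: float
    conductance_neg: float
    tension_midpoint: float
    sensitivity: float = 10.0
    base_rate: float = 5.0
    voltage_coupling: float = 0.0
    n_channels: int = 1
    substate_fractions: tuple = ()
    substate_rate: float = 25.0   # 1/s, full <-> substate flicker rate

    def __post_init__(self):
        if self.conductance_pos < 0 or self.conductance_neg < 0:
            raise InvalidInputError("conductances must be >= 0")
        if self.tension_midpoint <= 0:
            raise InvalidInputError("tension midpoint must be > 0")
        if self.sensitivity <= 0 or self.base_rate <= 0:
            raise InvalidInputError("sensitivity and base rate must be > 0")
        if self.voltage_coupling < 0:
            raise InvalidInputError("voltage coupling must be >= 0")
        if self.n_channels < 0:
            raise InvalidInputError("n_channels must be >= 0")
        if any(not 0 < f < 1 for f in self.substate_fractions):
            raise InvalidInputError("substate fractions must lie in (0, 1)")

    def conductance(self, voltage_mV: float) -> float:
        return self.conductance_pos if voltage_mV >= 0 else self.conductance_neg

    def unitary_current(self, voltage_mV: float) -> float:
        """Open-channel current in pA (nS * mV)."""
        return self.conductance(voltage_mV) * voltage_mV


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes and the seed of every generator."""

    current_noise_sd: float = 0.5    # pA
    strain_noise_sd: float = 0.02    # dimensionless
    area_noise_cv: float = 0.01      # fraction of the mean slab area
    seed: int = 0

    def __post_init__(self):
        if min(self.current_noise_sd, self.strain_noise_sd,
               self.area_noise_cv) < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class PressureProtocol:
    """Sampled time course of the applied pipette pressure."""

    time: np.ndarray       # s
    pressure: np.ndarray   # mmHg, suction negative
    sampling_rate: float   # Hz
    kind: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "pressure", np.asarray(self.pressure, dtype=float))
        if len(self.time) != len(self.pressure):
            raise InvalidInputError("time and pressure must have equal length")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class Event:
    """Ground-truth gating transition of one simulated channel."""

    time_s: float
    channel: str
    from_level: int
    to_level: int


# Channel presets of the three C. glutamicum species, parameterized from
# the published single-channel measurements.
# MscCG's negative-voltage conductance is scaled by the measured slope-
# conductance ratio (95/286); `mscCG-rect` carries those slopes verbatim
# for I-V work.  gamma for MscCG is qualitative only: chosen so the
# hysteresis-ratio curve decreases with positive pipette voltage and
# reaches the stuck-open regime near +100 mV.
PRESETS = {
    "mscCG": ChannelSpec(
        name="mscCG", conductance_pos=0.34,
        conductance_neg=0.34 * 95.0 / 286.0,
        tension_midpoint=5.5, voltage_coupling=0.65),
    "mscCG2": ChannelSpec(
        name="mscCG2", conductance_pos=1.0, conductance_neg=1.0,
        tension_midpoint=12.0, substate_fractions=(0.5,)),
    "cgmscl": ChannelSpec(
        name="cgmscl", conductance_pos=3.7, conductance_neg=3.7,
        tension_midpoint=12.0),
    "mscCG-rect": ChannelSpec(
        name="mscCG-rect", conductance_pos=0.286, conductance_neg=0.095,
        tension_midpoint=5.5, voltage_coupling=0.65),
}

DEFAULT_PIPETTE = (2.0, 2.5)   # tip and dome radius, um (aspiration scale)


def get_preset(name: str):
    """Channel list for a preset name (``wt-mix`` is all three species)."""
    if name == "wt-mix":
        return [PRESETS["mscCG"], PRESETS["mscCG2"], PRESETS["cgmscl"]]
    try:
        return [PRESETS[name]]
    except KeyError:
        raise InvalidInputError(
            f"unknown preset {name!r}; choose from "
            f"{sorted(PRESETS)} or 'wt-mix'") from None


def build_protocol(kind: str, peak_pressure: float, duration: float,
                   sampling_rate: float = 5000.0, lead: float = 0.0,
                   levels=None) -> PressureProtocol:
    """Sampled pressure protocol.

    ``kind`` is one of ``ramp`` (linear 0 -> peak), ``triangle``
    (loading and unloading at equal magnitude rates, returning to 0) or
    ``step`` (equal-duration plateaus at ``levels``, default four equal
    steps to the peak).  ``lead`` seconds of zero pressure are prepended,
    giving the idealizer a baseline segment.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise InvalidInputError("duration and sampling rate must be > 0")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    if kind == "ramp":
        p = np.linspace(0.0, peak_pressure, n)
    elif kind == "triangle":
        p = np.interp(t, [0.0, duration / 2.0, duration - 1.0 / sampling_rate],
                      [0.0, peak_pressure, 0.0])
    elif kind == "step":
        if levels is None:
            levels = [peak_pressure * k / 4.0 for k in (1, 2, 3, 4)]
        levels = list(levels)
        per = n // len(levels)
        p = np.concatenate([np.full(per, lv) for lv in levels])
        p = np.concatenate([p, np.full(n - len(p), levels[-1])])
    else:
        raise InvalidInputError(f"unknown protocol kind {kind!r}")
    if lead > 0:
        n_lead = int(round(lead * sampling_rate))
        p = np.concatenate([np.zeros(n_lead), p])
    time = np.arange(len(p)) / sampling_rate
    return PressureProtocol(time=time, pressure=p,
                            sampling_rate=sampling_rate, kind=kind)


def _gating_rates(tension, voltage_mV, spec: ChannelSpec):
    """Opening and closing rate arrays (1/s) along a tension time course."""
    x = np.clip(spec.sensitivity * (tension - spec.tension_midpoint),
                -EXP_CLIP, EXP_CLIP)
    k_open = np.minimum(spec.base_rate * np.exp(x), RATE_CAP)
    k_close = np.minimum(
        spec.base_rate * np.exp(-x)
        * math.exp(-spec.voltage_coupling * max(voltage_mV, 0.0)),
        RATE_CAP)
    return k_open, np.maximum(k_close, 1e-300)


def _simulate_states(k_open, k_close, dt, rng):
    """Exact interval-wise propagation of the two-state chain.

    State 0 = closed, 1 = open; the state of sample ``i`` is drawn from
    the analytic transition probability over one interval with the rates
    of sample ``i`` held constant.  Starts closed.
    """
    k = k_open + k_close
    decay = np.exp(-k * dt)
    pi_open = k_open / k
    p_open_from_closed = pi_open * (1.0 - decay)
    p_open_from_open = pi_open + (1.0 - pi_open) * decay
    u = rng.random(len(k))
    states = np.empty(len(k), dtype=np.int8)
    state = 0
    for i in range(len(k)):
        p = p_open_from_open[i] if state else p_open_from_closed[i]
        state = 1 if u[i] < p else 0
        states[i] = state
    return states


def _substate_factors(open_states, fractions, rate, dt, rng):
    """Amplitude factor per sample for a channel with sub-conductance levels.

    While open, the channel flickers between the full level (factor 1)
    and each substate with a symmetric Markov rate; closed samples keep
    factor 0.
    """
    levels = np.array([1.0] + list(fractions))
    m = len(levels)
    p_switch = 1.0 - math.exp(-rate * dt)
    idx = 0
    factors = np.zeros(len(open_states))
    u = rng.random(len(open_states))
    jumps = rng.integers(0, m - 1, size=len(open_states)) if m > 1 else None
    for i, s in enumerate(open_states):
        if not s:
            idx = 0
            continue
        if m > 1 and u[i] < p_switch:
            j = jumps[i]
            idx = j if j < idx else j + 1   # uniform over the other levels
        factors[i] = levels[idx]
    return factors


def _single_pole_lowpass(x, cutoff_hz, sampling_rate):
    alpha = 1.0 - math.exp(-2.0 * math.pi * cutoff_hz / sampling_rate)
    y = np.empty_like(x)
    acc = x[0]
    for i, xi in enumerate(x):
        acc += alpha * (xi - acc)
        y[i] = acc
    return y


def simulate_recording(channels, protocol: PressureProtocol,
                       geometry: PatchGeometry, voltage: float,
                       noise: NoiseSpec, filter_cutoff_hz: float | None = 2000.0):
    """Simulate a patch-clamp sweep over a pressure protocol.

    Every channel copy is simulated independently; the recorded current
    is the sum of the open-channel currents (conductance x voltage, with
    substate factors), optionally low-pass filtered (single-pole
    approximation of the acquisition filter) and with Gaussian noise
    added at the recorded bandwidth.

    Returns
    -------
    (RecordingTrace, list[Event])
        The trace and the ground-truth gating event log (times on sample
        boundaries).
    """
    channels = list(channels)
    if geometry.curvature_radius <= 0:
        raise InvalidInputError("patch curvature radius must be > 0")
    rng = np.random.default_rng(noise.seed)
    dt = 1.0 / protocol.sampling_rate
    tension = laplace_tension(np.abs(protocol.pressure),
                              geometry.curvature_radius)
    clean = np.zeros(len(protocol))
    events: list[Event] = []
    for spec in channels:
        k_open, k_close = _gating_rates(tension, voltage, spec)
        amp = spec.unitary_current(voltage)
        for copy in range(spec.n_channels):
            states = _simulate_states(k_open, k_close, dt, rng)
            if spec.substate_fractions:
                factors = _substate_factors(
                    states, spec.substate_fractions, spec.substate_rate,
                    dt, rng)
            else:
                factors = states.astype(float)
            clean += amp * factors
            label = spec.name if spec.n_channels == 1 else f"{spec.name}#{copy}"
            prev = 0
            for i in np.flatnonzero(np.diff(np.concatenate(([0], states)))):
                new = int(states[i])
                events.append(Event(time_s=float(protocol.time[i]),
                                    channel=label, from_level=prev,
                                    to_level=new))
                prev = new
    if filter_cutoff_hz:
        clean = _single_pole_lowpass(clean, filter_cutoff_hz,
                                     protocol.sampling_rate)
    current = clean + rng.normal(0.0, noise.current_noise_sd, len(clean)) \
        if noise.current_noise_sd > 0 else clean
    trace = RecordingTrace(
        time=protocol.time.copy(), current=current,
        pressure=protocol.pressure.copy(),
        sampling_rate=protocol.sampling_rate, voltage=float(voltage),
        metadata={"seed": noise.seed, "protocol": protocol.kind,
                  "channels": ",".join(s.name for s in channels)})
    events.sort(key=lambda e: e.time_s)
    return trace, events


def _solve_protrusion(tip, dome, dome_height, target_area,
                      l_max: float = 1e4, tol: float = 1e-12) -> float:
    def f(L):
        return aspirated_area(PatchGeometry(tip, dome, L, dome_height)) - target_area

    if f(0.0) > 0:
        raise GeometrySolveError(
            "target strain below the zero-protrusion area of this pipette")
    if f(l_max) < 0:
        raise GeometrySolveError("target strain unreachable (protrusion bound)")
    return float(brentq(f, 0.0, l_max, xtol=tol))


def generate_ma_experiment(true_K_A: float, pressure_steps, pipette=None,
                           noise: NoiseSpec = NoiseSpec(),
                           n_replicates: int = 1, dome_height: float = 0.5,
                           reference_protrusion: float = 1.0,
                           curvature_radius: float | None = None) -> pd.DataFrame:
    """Aspiration geometry series following a prescribed modulus.

    For each suction step the Laplace tension is computed from the patch
    curvature radius, the target strain is ``T / K_A`` plus Gaussian
    noise, and the protrusion length is solved so the conical-pipette
    area reproduces that strain against the zero-pressure reference row.

    Returns a DataFrame in the geometry-series schema (first row is the
    zero-pressure reference).
    """
    if true_K_A <= 0:
        raise InvalidInputError("true_K_A must be > 0")
    tip, dome = pipette if pipette is not None else DEFAULT_PIPETTE
    curvature = dome if curvature_radius is None else curvature_radius
    rng = np.random.default_rng(noise.seed)
    reference = PatchGeometry(tip, dome, reference_protrusion, dome_height,
                              curvature)
    a0 = aspirated_area(reference)
    rows = [{
        "pressure_mmHg": 0.0, "tip_radius_um": tip, "dome_radius_um": dome,
        "protrusion_um": reference_protrusion, "dome_height_um": dome_height,
        "curvature_um": curvature,
    }]
    for _ in range(n_replicates):
        for p in pressure_steps:
            tension = laplace_tension(abs(p), curvature)
            alpha = tension / true_K_A
            if noise.strain_noise_sd > 0:
                alpha += rng.normal(0.0, noise.strain_noise_sd)
            length = _solve_protrusion(tip, dome, dome_height,
                                       a0 * (1.0 + alpha))
            rows.append({
                "pressure_mmHg": float(p), "tip_radius_um": tip,
                "dome_radius_um": dome, "protrusion_um": length,
                "dome_height_um": dome_height, "curvature_um": curvature,
            })
    return pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)


def generate_slab_areas(true_K_A: float, tensions, A0: float, M: int, N: int,
                        noise: NoiseSpec = NoiseSpec(),
                        include_reference: bool = True):
    """Slab-area matrices whose means follow ``A0 (1 + tau / K_A)``.

    Returns a list of :class:`~mscmech.md_area.SlabAreaSeries`, the
    zero-tension reference first when ``include_reference``.
    """
    from .md_area import SlabAreaSeries

    if true_K_A <= 0 or A0 <= 0:
        raise InvalidInputError("true_K_A and A0 must be > 0")
    if M < 1 or N < 1:
        raise InvalidInputError("matrix dimensions must be >= 1")
    tensions = [float(t) for t in tensions]
    if any(t < 0 for t in tensions):
        raise InvalidInputError("applied tensions must be >= 0")
    rng = np.random.default_rng(noise.seed)
    out = []
    taus = ([0.0] if include_reference else []) + tensions
    for tau in taus:
        mean = A0 * (1.0 + tau / true_K_A)
        areas = mean * (1.0 + noise.area_noise_cv * rng.standard_normal((M, N)))
        out.append(SlabAreaSeries(applied_tension=tau, areas=areas))
    return out
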