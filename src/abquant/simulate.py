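"""Seeded synthetic-data generators for every input the pipeline consumes.

The in vivo recordings behind this analysis are not publicly deposited, so the
pipeline is exercised end-to-end on simulated data with known ground truth:

* calcium traces — 40 Hz frames, a minority of neurons firing at hyperactive
  rates (> 20 transients/min), Poisson event times with a short refractory gap,
  condition epochs (baseline / application / washout) that scale the rate,
  sinusoidal slow drift and additive Gaussian noise;
* glutamate traces — 120/200 Hz, stimulus trains at 20 ms inter-pulse spacing,
  optional supralinear "disease" gain for long trains;
* movies — multi-page stacks whose ROI pixel means reproduce the neuron traces;
* dose-response tables, Langmuir sensorgrams, SEC chromatograms and ThT
  aggregation curves for the biophysical calculations.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophys import Chromatogram, ThTCurve, langmuir_response
from .dose_response import mass_law
from .errors import InvalidConfigError
from .traces import Trace


@dataclass(frozen=True)
class ConditionEpoch:
    """One experimental condition: [start, end) seconds, multiplicative rate factor."""

    label: str
    start: float
    end: float
    rate_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidConfigError(f"epoch {self.label!r}: end must exceed start")
        if self.rate_factor < 0:
            raise InvalidConfigError(f"epoch {self.label!r}: rate factor must be >= 0")


DEFAULT_SCHEDULE = (ConditionEpoch("baseline", 0.0, 60.0, 1.0),)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the calcium-trace and session generators.

    Defaults encode the recording conditions of the emulated experiments:
    40 Hz full-frame calcium imaging, 60 s epochs, a ~12% hyperactive minority
    firing at 30/min against a 3/min background.  Transient kinetics (50 ms
    linear rise, 500 ms exponential decay, 0.4 df/f amplitude) are indicator-
    literature regimes, not measured values, and are fully config-exposed.
    """

    n_neurons: int = 40
    duration: float = 60.0
    frame_rate: float = 40.0
    fraction_hyperactive: float = 0.12
    rate_low: float = 3.0
    rate_high: float = 30.0
    amplitude: float = 0.4        # transient peak, df/f units
    rise_time: float = 0.05       # s, linear rise; also the refractory gap
    decay_time: float = 0.5       # s, exponential decay constant
    noise_sd: float = 0.04        # additive Gaussian, df/f units
    drift_amplitude: float = 0.05  # slow sinusoid, df/f units
    drift_period: float = 60.0    # s
    baseline_f: float = 100.0     # raw fluorescence offset, arbitrary units
    conditions: tuple[ConditionEpoch, ...] = DEFAULT_SCHEDULE
    condition_applies_to: str = "all"  # "all" | "hyperactive"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidConfigError("frame_rate must be > 0")
        if self.duration <= 0 or self.duration * self.frame_rate < 2:
            raise InvalidConfigError("duration must cover at least 2 samples")
        if not 0.0 <= self.fraction_hyperactive <= 1.0:
            raise InvalidConfigError("fraction_hyperactive must lie in [0, 1]")
        if self.rate_low < 0 or self.rate_high < 0:
            raise InvalidConfigError("rates must be >= 0")
        if self.condition_applies_to not in ("all", "hyperactive"):
            raise InvalidConfigError("condition_applies_to must be 'all' or 'hyperactive'")
        epochs = sorted(self.conditions, key=lambda e: e.start)
        for a, b in zip(epochs, epochs[1:]):
            if b.start < a.end:
                raise InvalidConfigError(
                    f"condition epochs {a.label!r} and {b.label!r} overlap"
                )

    @property
    def total_duration(self) -> float:
        return max([self.duration] + [e.end for e in self.conditions])


@dataclass
class GroundTruth:
    """True event times, rates and classes behind a simulated recording."""

    event_times_per_neuron: list[np.ndarray]
    true_rate_per_neuron: list[float]           # transients/min over the whole trace
    true_class_per_neuron: list[bool]           # hyperactive flag (configured class)
    condition_effects: dict[str, float]
    seed: int
    condition_rates: list[dict[str, float]] = field(default_factory=list)
    stim_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        for times in self.event_times_per_neuron:
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise InvalidConfigError("ground-truth event times must be strictly increasing")


@dataclass
class SimulatedSession:
    """A simulated paired recording: one continuous trace per neuron spanning
    the full condition schedule."""

    subject_id: str
    traces: list[Trace]
    conditions: tuple[ConditionEpoch, ...]
    config: SimulationConfig
    genotype: str = "APP23xPS45"
    treatment: str = "vehicle"


def _draw_event_times(
    rng: np.random.Generator, config: SimulationConfig, rate_per_min: float, scaled: bool
) -> np.ndarray:
    """Poisson event times over the condition schedule, refractory-thinned.

    ``scaled`` controls whether the epoch rate factors apply to this neuron.
    Thinning drops any event closer than one rise time to the previously
    accepted one, so kernels never stack during the rise.
    """
    times: list[np.ndarray] = []
    for epoch in sorted(config.conditions, key=lambda e: e.start):
        factor = epoch.rate_factor if scaled else 1.0
        lam = rate_per_min / 60.0 * factor * (epoch.end - epoch.start)
        count = rng.poisson(lam)
        times.append(np.sort(rng.uniform(epoch.start, epoch.end, size=count)))
    merged = np.concatenate(times) if times else np.empty(0)
    kept: list[float] = []
    for t in merged:
        if not kept or t - kept[-1] >= config.rise_time:
            kept.append(t)
    return np.asarray(kept)


def _event_signal(
    t: np.ndarray, event_times: np.ndarray, amplitude: float, rise: float, decay: float
) -> np.ndarray:
    """Sum of event kernels (linear rise then exponential decay), df/f units."""
    signal = np.zeros_like(t)
    for te in event_times:
        dt = t - te
        rising = (dt >= 0) & (dt < rise)
        signal[rising] += amplitude * dt[rising] / rise
        decaying = dt >= rise
        signal[decaying] += amplitude * np.exp(-(dt[decaying] - rise) / decay)
    return signal


def _epoch_rates(config: SimulationConfig, events: np.ndarray) -> dict[str, float]:
    out = {}
    for e in config.conditions:
        n = int(np.sum((events >= e.start) & (events < e.end)))
        out[e.label] = 60.0 * n / (e.end - e.start)
    return out


def generate_calcium_trace(
    config: SimulationConfig,
    rate: float,
    seed: int,
    scaled_by_conditions: bool = True,
    hyperactive: bool | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate one calcium trace at a nominal ``rate`` (transients/min).

    The raw trace is ``baseline_f * (1 + drift + events + noise)``: a constant
    offset plus sinusoidal drift, summed event kernels at thinned-Poisson times,
    and white Gaussian noise, all expressed relative to the baseline level.
    """
    if rate < 0:
        raise InvalidConfigError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    total = config.total_duration
    n = int(round(total * config.frame_rate))
    t = np.arange(n) / config.frame_rate

    events = _draw_event_times(rng, config, rate, scaled_by_conditions)
    signal = _event_signal(t, events, config.amplitude, config.rise_time, config.decay_time)
    drift = config.drift_amplitude * np.sin(2 * np.pi * t / config.drift_period)
    noise = config.noise_sd * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
    raw = config.baseline_f * (1.0 + drift + signal + noise)

    truth = GroundTruth(
        event_times_per_neuron=[events],
        true_rate_per_neuron=[60.0 * events.size / total],
        true_class_per_neuron=[bool(hyperactive) if hyperactive is not None
                               else rate > 20.0],
        condition_effects={e.label: e.rate_factor for e in config.conditions},
        seed=seed,
        condition_rates=[_epoch_rates(config, events)],
    )
    return Trace(raw, config.frame_rate, channel="calcium"), truth


def generate_session(
    config: SimulationConfig, seed: int, make_traces: bool = True
) -> tuple[SimulatedSession, GroundTruth]:
    """Simulate a paired multi-neuron session.

    Each neuron is hyperactive (rate_high) with probability
    ``fraction_hyperactive``, otherwise quiet (rate_low); identities are shared
    across conditions because each neuron is one continuous recording spanning
    the schedule.  ``make_traces=False`` draws event times and classes only,
    for oracle checks on the assignment process itself.
    """
    if config.n_neurons < 1:
        raise InvalidConfigError("n_neurons must be >= 1")
    if not config.conditions:
        raise InvalidConfigError("condition schedule must not be empty")
    rng = np.random.default_rng(seed)
    classes = rng.random(config.n_neurons) < config.fraction_hyperactive
    neuron_seeds = rng.integers(0, 2**31 - 1, size=config.n_neurons)

    traces: list[Trace] = []
    all_events: list[np.ndarray] = []
    rates: list[float] = []
    cond_rates: list[dict[str, float]] = []
    total = config.total_duration
    for i in range(config.n_neurons):
        nominal = config.rate_high if classes[i] else config.rate_low
        scaled = config.condition_applies_to == "all" or bool(classes[i])
        if make_traces:
            tr, gt = generate_calcium_trace(
                config, nominal, int(neuron_seeds[i]),
                scaled_by_conditions=scaled, hyperactive=bool(classes[i]),
            )
            tr.roi_label = i + 1
            traces.append(tr)
            events = gt.event_times_per_neuron[0]
        else:
            events = _draw_event_times(
                np.random.default_rng(int(neuron_seeds[i])), config, nominal, scaled
            )
        all_events.append(events)
        rates.append(60.0 * events.size / total)
        cond_rates.append(_epoch_rates(config, events))

    truth = GroundTruth(
        event_times_per_neuron=all_events,
        true_rate_per_neuron=rates,
        true_class_per_neuron=[bool(c) for c in classes],
        condition_effects={e.label: e.rate_factor for e in config.conditions},
        seed=seed,
        condition_rates=cond_rates,
    )
    session = SimulatedSession(
        subject_id=f"sim-{seed}", traces=traces, conditions=config.conditions, config=config
    )
    return session, truth


def generate_glutamate_trace(
    stim_times: np.ndarray | list[float],
    n_pulses: int,
    per_pulse_amplitude: float = 0.5,
    decay: float = 0.1,
    noise_sd: float = 0.0,
    frame_rate: float = 200.0,
    seed: int = 0,
    duration: float | None = None,
    inter_pulse: float = 0.02,
    rise_time: float | None = None,
    disease_gain: float = 1.0,
    gain_min_pulses: int = 5,
    baseline_f: float = 100.0,
) -> tuple[Trace, GroundTruth]:
    """Simulate a glutamate trace locked to stimulus trains.

    Each entry of ``stim_times`` starts a train of ``n_pulses`` pulses at
    ``inter_pulse`` (20 ms) spacing; the response is a linear superposition of
    per-pulse kernels.  ``disease_gain`` > 1 scales the response of trains with
    at least ``gain_min_pulses`` pulses, emulating the supralinear glutamate
    accumulation seen for long trains under disease conditions.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if n_pulses < 1:
        raise InvalidConfigError("n_pulses must be >= 1")
    if inter_pulse < 1.0 / frame_rate:
        raise InvalidConfigError(
            f"pulse spacing {inter_pulse} s is below the sampling interval "
            f"{1.0 / frame_rate} s"
        )
    if rise_time is None:
        rise_time = 1.0 / frame_rate
    train_len = (n_pulses - 1) * inter_pulse
    if duration is None:
        duration = float(stim_times.max() + train_len + 10 * decay) if stim_times.size else 1.0
    if stim_times.size and (stim_times.min() < 0 or stim_times.max() + train_len > duration):
        raise InvalidConfigError("stimulus trains must lie within the trace duration")

    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    amp = per_pulse_amplitude * (disease_gain if n_pulses >= gain_min_pulses else 1.0)
    pulse_times = np.sort(np.concatenate(
        [ts + np.arange(n_pulses) * inter_pulse for ts in stim_times]
    )) if stim_times.size else np.empty(0)
    signal = _event_signal(t, pulse_times, amp, rise_time, decay)
    noise = noise_sd * rng.standard_normal(n) if noise_sd > 0 else 0.0
    raw = baseline_f * (1.0 + signal + noise)

    truth = GroundTruth(
        event_times_per_neuron=[pulse_times],
        true_rate_per_neuron=[60.0 * pulse_times.size / duration],
        true_class_per_neuron=[False],
        condition_effects={},
        seed=seed,
        stim_times=stim_times,
    )
    return Trace(raw, frame_rate, channel="glutamate"), truth


def grid_roi_layout(
    n_rois: int, frame_shape: tuple[int, int] = (32, 32), roi_size: int = 3
) -> np.ndarray:
    """Non-overlapping square ROIs on a regular grid, as a label image."""
    h, w = frame_shape
    per_row = w // (roi_size + 1)
    if per_row == 0 or n_rois > per_row * (h // (roi_size + 1)):
        raise InvalidConfigError("frame too small for the requested ROI layout")
    labels = np.zeros(frame_shape, dtype=np.int32)
    for i in range(n_rois):
        r, c = divmod(i, per_row)
        y, x = r * (roi_size + 1), c * (roi_size + 1)
        labels[y:y + roi_size, x:x + roi_size] = i + 1
    return labels


def generate_movie(
    traces: list[Trace],
    rois: np.ndarray | None = None,
    frame_shape: tuple[int, int] = (32, 32),
    roi_size: int = 3,
    photon_noise: bool = False,
    background: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces into a movie stack plus ROI label image.

    Without photon noise, the pixel mean over each ROI reproduces its neuron's
    trace exactly; with ``photon_noise`` pixels are Poisson draws around the
    trace value.  Explicit ``rois`` label images are validated against the
    frame shape; labels must cover 1..len(traces).
    """
    if rois is None:
        rois = grid_roi_layout(len(traces), frame_shape, roi_size)
    rois = np.asarray(rois)
    if rois.shape != frame_shape:
        frame_shape = rois.shape
    labels = [int(l) for l in np.unique(rois) if l > 0]
    if labels != list(range(1, len(traces) + 1)):
        raise InvalidConfigError("ROI labels must be 1..n_traces, non-overlapping")
    n_frames = traces[0].values.size
    if any(tr.values.size != n_frames for tr in traces):
        raise InvalidConfigError("all traces must have the same length")

    movie = np.full((n_frames, *frame_shape), float(background))
    for label, tr in zip(labels, traces):
        mask = rois == label
        movie[:, mask] = tr.values[:, None]
    if photon_noise:
        rng = np.random.default_rng(seed)
        movie = rng.poisson(np.clip(movie, 0, None)).astype(float)
    return movie, rois


def generate_dose_response(
    ic50: float,
    doses: np.ndarray | list[float],
    noise_sd: float = 0.05,
    replicates: int = 5,
    seed: int = 0,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Per-dose mean +/- SEM of mass-law responses with Gaussian noise.

    response(c) = floor + (1 - floor) * ic50 / (ic50 + c) + N(0, noise_sd),
    averaged over ``replicates`` draws per dose.
    """
    doses = np.asarray(doses, dtype=float)
    if ic50 <= 0:
        raise InvalidConfigError("ic50 must be > 0")
    if np.any(doses <= 0):
        raise InvalidConfigError("doses must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in doses:
        resp = mass_law(c, ic50, floor) + noise_sd * rng.standard_normal(replicates)
        sem = float(resp.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0
        rows.append({"dose_nM": c, "mean": float(resp.mean()), "sem": sem,
                     "n_replicates": replicates})
    return pd.DataFrame(rows)


def generate_sensorgram(
    k_on: float,
    k_off: float,
    rmax: float,
    conc: float,
    t_assoc: float = 120.0,
    t_dissoc: float = 180.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Closed-form Langmuir 1:1 sensorgram (association then dissociation)."""
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = langmuir_response(t, k_on, k_off, rmax, conc, t_assoc)
    if noise_sd > 0:
        r = r + noise_sd * np.random.default_rng(seed).standard_normal(t.size)
    return pd.DataFrame({
        "time_s": t,
        "response_RU": r,
        "conc_M": conc,
        "phase": np.where(t <= t_assoc, "association", "dissociation"),
    })


def generate_chromatogram(
    peaks: list[tuple[float, float, float]],
    v0: float = 8.0,
    vt: float = 24.0,
    v_start: float = 6.0,
    v_end: float = 24.0,
    dv: float = 0.01,
    baseline_start: float = 2.0,
    baseline_slope: float = -0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Chromatogram:
    """Sum of Gaussian elution peaks (Ve, height, sigma) on a declining baseline."""
    v = np.arange(v_start, v_end + dv / 2, dv)
    signal = baseline_start + baseline_slope * (v - v_start)
    for ve, height, sigma in peaks:
        signal = signal + height * np.exp(-0.5 * ((v - ve) / sigma) ** 2)
    if noise_sd > 0:
        signal = signal + noise_sd * np.random.default_rng(seed).standard_normal(v.size)
    return Chromatogram(volumes=v, signal=signal, v0=v0, vt=vt)


def generate_tht_curve(
    mode: str = "free",
    t_max: float = 240.0,
    dt: float = 2.0,
    plateau: float = 1000.0,
    baseline: float = 20.0,
    t50: float = 45.0,
    tau: float = 12.0,
    scavenger_residual: float = 0.02,
    addition_time: float = 90.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ThTCurve:
    """Phenomenological logistic aggregation curve for the ThT assay.

    Modes: ``free`` (unhindered aggregation), ``co_incubation`` (stoichiometric
    scavenger present from t=0; the plateau collapses to ``scavenger_residual``
    of the free plateau), ``late_addition`` (scavenger added at
    ``addition_time``, after fibrils formed; fluorescence is not reduced, so
    the curve is that of free aggregation).
    """
    if mode not in ("free", "co_incubation", "late_addition"):
        raise InvalidConfigError(f"unknown ThT mode {mode!r}")
    t = np.arange(0.0, t_max + dt / 2, dt)
    amp = plateau * (scavenger_residual if mode == "co_incubation" else 1.0)
    f = baseline + amp / (1.0 + np.exp(-(t - t50) / tau))
    if noise_sd > 0:
        f = f + noise_sd * np.random.default_rng(seed).standard_normal(t.size)
    return ThTCurve(time=t, fluorescence=f, normalized=False, mode=mode)
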