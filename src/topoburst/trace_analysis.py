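"""Processing of in-vitro transcription-intensity traces into per-event
initiation rates.

The single-molecule assay monitors an ensemble of circular templates whose
aggregate fluorescence increment per frame is proportional to the number of
transcripts initiated in that frame.  The chain implemented here:

intensity trace -> cumulative transcript equivalents (cumulative sum divided
by the per-transcript intensity) -> "average transcription event" times (the
j-th is when every template has on average produced j transcripts) -> inverse
inter-event intervals as per-event initiation rates -> ordinary least squares
of rate against event number.  The line's y-intercept estimates the maximum
initiation rate ``a_o * max_rcoil`` and its x-intercept the transcription
capacity ``max_rcoil`` of a template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import invitro_simulate

__all__ = [
    "IntensityTrace",
    "EventSeries",
    "RateFit",
    "FixtureTrace",
    "cumulative_transcripts",
    "average_event_times",
    "initiation_rate_by_event",
    "linear_fit_rates",
    "generate_fixture_trace",
    "read_trace",
]

DEFAULT_UNIT_INTENSITY = 13.5e3  #: fluorescence per single transcript


@dataclass
class IntensityTrace:
    """Sampled fluorescence trace of an n-template ensemble."""

    times: np.ndarray           #: seconds, strictly increasing
    intensity: np.ndarray       #: arbitrary fluorescence units, >= 0
    n_templates: int
    unit_intensity: float = DEFAULT_UNIT_INTENSITY

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "intensity": self.intensity}).to_csv(
            path, sep="\t", index=False
        )


def read_trace(
    path, n_templates: int, unit_intensity: float = DEFAULT_UNIT_INTENSITY
) -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    return IntensityTrace(
        times=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        n_templates=n_templates,
        unit_intensity=unit_intensity,
    )


@dataclass
class EventSeries:
    """Times of average transcription events, indexed 1..E."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(1, self.times.size + 1)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"event_index": self.indices, "time_s": self.times}).to_csv(
            path, sep="\t", index=False
        )


def cumulative_transcripts(trace: IntensityTrace) -> np.ndarray:
    """Cumulative sum of the intensity in units of transcripts (non-decreasing)."""
    return np.cumsum(trace.intensity) / trace.unit_intensity


def average_event_times(
    times: np.ndarray, cumulative: np.ndarray, n_templates: int
) -> EventSeries:
    """Times at which the cumulative transcript count crosses j * n_templates.

    Crossings are located by linear interpolation between samples; the series
    ends at the last threshold the trace actually reaches.
    """
    times = np.asarray(times, dtype=float)
    cumulative = np.asarray(cumulative, dtype=float)
    if np.any(np.diff(cumulative) < 0):
        raise ValueError("cumulative must be non-decreasing")
    n_events = int(np.floor(cumulative[-1] / n_templates))
    out = np.empty(n_events)
    for j in range(1, n_events + 1):
        thr = j * float(n_templates)
        idx = int(np.searchsorted(cumulative, thr, side="left"))
        if idx == 0:
            out[j - 1] = times[0]
        else:
            c0, c1 = cumulative[idx - 1], cumulative[idx]
            t0, t1 = times[idx - 1], times[idx]
            out[j - 1] = t0 + (thr - c0) / (c1 - c0) * (t1 - t0)
    return EventSeries(times=out)


def initiation_rate_by_event(events: EventSeries) -> np.ndarray:
    """Per-event initiation rates 1/(t_j - t_{j-1}) with t_0 = 0."""
    if events.times.size < 1:
        raise ValueError("need at least one event")
    intervals = np.diff(np.concatenate([[0.0], events.times]))
    return 1.0 / intervals


@dataclass
class RateFit:
    """OLS fit of initiation rate against transcription event number."""

    slope: float
    slope_stderr: float
    y_intercept: float
    y_intercept_stderr: float
    x_intercept: float
    x_intercept_stderr: float
    r_squared: float
    n_points: int
    x_intercept_defined: bool = True
    residuals: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_stderr": self.slope_stderr,
            "y_intercept": self.y_intercept,
            "y_intercept_stderr": self.y_intercept_stderr,
            "x_intercept": self.x_intercept,
            "x_intercept_stderr": self.x_intercept_stderr,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "x_intercept_defined": self.x_intercept_defined,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def linear_fit_rates(rates: np.ndarray, event_index: np.ndarray | None = None) -> RateFit:
    """Ordinary least squares of rate vs event number.

    The y-intercept estimates the maximum initiation rate and the x-intercept
    (-intercept/slope) the number of events before stalling; the x-intercept
    standard error comes from first-order error propagation including the
    slope/intercept covariance.
    """
    rates = np.asarray(rates, dtype=float)
    if event_index is None:
        event_index = np.arange(1, rates.size + 1, dtype=float)
    x = np.asarray(event_index, dtype=float)
    if x.size != rates.size or x.size < 2:
        raise ValueError("need >= 2 (event, rate) points")
    res = stats.linregress(x, rates)
    pred = res.intercept + res.slope * x
    ss_res = float(np.sum((rates - pred) ** 2))
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if res.slope == 0:
        return RateFit(
            slope=0.0, slope_stderr=res.stderr, y_intercept=res.intercept,
            y_intercept_stderr=res.intercept_stderr, x_intercept=np.nan,
            x_intercept_stderr=np.nan, r_squared=r2, n_points=x.size,
            x_intercept_defined=False, residuals=rates - pred,
        )
    x_int = -res.intercept / res.slope
    # var(-a/b) to first order; cov(a, b) = -x_bar * var(b) for OLS
    var_a = res.intercept_stderr**2
    var_b = res.stderr**2
    cov_ab = -float(x.mean()) * var_b
    a, b = res.intercept, res.slope
    var_xint = var_a / b**2 + (a**2 / b**4) * var_b - 2.0 * (a / b**3) * cov_ab
    return RateFit(
        slope=float(res.slope), slope_stderr=float(res.stderr),
        y_intercept=float(res.intercept), y_intercept_stderr=float(res.intercept_stderr),
        x_intercept=float(x_int), x_intercept_stderr=float(np.sqrt(max(var_xint, 0.0))),
        r_squared=r2, n_points=int(x.size), residuals=rates - pred,
    )


@dataclass
class FixtureTrace:
    """Synthetic intensity trace plus the generator's ground truth.

    Stands in for the single-molecule assay data: the event times come from
    the in-vitro kinetic model, so the trace is a pipeline test article, not a
    reconstruction of the original experiment.
    """

    trace: IntensityTrace
    event_times: list[np.ndarray]   #: per-template transcription times
    total_events: int

    def true_average_event_times(self) -> np.ndarray:
        """Exact times at which the pooled event count reaches j*n_templates."""
        pooled = np.sort(np.concatenate(self.event_times))
        n = self.trace.n_templates
        n_avg = pooled.size // n
        return pooled[np.arange(1, n_avg + 1) * n - 1]


def generate_fixture_trace(
    a_o_total: float = 0.0032,
    max_rcoil: int = 13,
    n_templates: int = 160,
    unit_intensity: float = DEFAULT_UNIT_INTENSITY,
    noise_sd: float = 0.1 * DEFAULT_UNIT_INTENSITY,
    dt: float = 50.0,
    seed: int = 0,
    t_end: float | None = None,
) -> FixtureTrace:
    """Simulate the template ensemble and render it as a sampled intensity trace.

    Events are binned into ``dt``-second frames, scaled by the per-transcript
    intensity and perturbed with additive Gaussian noise (clipped at zero).
    The default noise is a tenth of one transcript per frame -- a mild
    instrument-noise stand-in; the real assay's noise model is unknown.
    """
    events = invitro_simulate(
        a_o_total=a_o_total, max_rcoil=max_rcoil, n_templates=n_templates,
        t_end=t_end, seed=seed,
    )
    pooled = np.concatenate(events)
    t_max = t_end if t_end is not None else (pooled.max() if pooled.size else dt)
    edges = np.arange(0.0, t_max + dt, dt)
    if edges.size < 2:
        edges = np.array([0.0, dt])
    counts, _ = np.histogram(pooled, bins=edges)
    intensity = counts.astype(float) * unit_intensity
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        intensity = np.clip(intensity + rng.normal(0.0, noise_sd, intensity.size), 0.0, None)
    trace = IntensityTrace(
        times=edges[1:], intensity=intensity, n_templates=n_templates,
        unit_intensity=unit_intensity,
    )
    return FixtureTrace(trace=trace, event_times=events, total_events=int(pooled.size))


def analyze_trace(trace: IntensityTrace) -> tuple[EventSeries, np.ndarray, RateFit]:
    """Full pipeline: trace -> event series -> per-event rates -> linear fit."""
    cum = cumulative_transcripts(trace)
    events = average_event_times(trace.times, cum, trace.n_templates)
    rates = initiation_rate_by_event(events)
    return events, rates, linear_fit_rates(rates)
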