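"""Synthetic single-channel gating records.

Simulates the statistical structure that the dwell-time analysis assumes:
open and closed sojourns drawn from mixtures of exponentials, rendered as a
telegraph current with Gaussian noise, low-pass Bessel filtering and uniform
sampling — i.e. what a patch-clamp amplifier delivers for a patch holding
one (or a few independent) channels.

Dwells are sampled phenomenologically from the mixture densities

    f(t) = sum_i (A_i / tau_i) exp(-t / tau_i)

(component chosen with probability ``A_i``, duration Exponential(tau_i)),
not from an underlying rate matrix: the mixture components are exactly what
the downstream fitting estimates, so ground truth is known by construction.

Two ready-made schemes mirror recombinant GABA_A receptor phenotypes at
near-saturating GABA: ``a1b3-like`` (binary alpha1/beta3 receptors — brief
openings dominate, low open probability, ~1.3 pA at -70 mV) and
``a1b3g2-like`` (gamma2-containing synaptic-type receptors — long openings
dominate, ~1.9 pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .events import CLOSED, OPEN, Event, EventList

__all__ = [
    "GatingScheme",
    "SweepRecord",
    "SCHEMES",
    "simulate_dwells",
    "render_trace",
    "simulate_record",
]


@dataclass(frozen=True)
class GatingScheme:
    """Mixture-of-exponentials gating description.

    ``open_components`` / ``closed_components`` are ``(tau_ms, area)`` pairs;
    areas within a class must sum to 1.
    """

    open_components: tuple[tuple[float, float], ...]
    closed_components: tuple[tuple[float, float], ...]
    unitary_current: float = 1.3  # pA
    n_channels: int = 1

    def __post_init__(self) -> None:
        for comps in (self.open_components, self.closed_components):
            if not comps:
                raise ValueError("each state class needs >=1 component")
            taus = [t for t, _ in comps]
            areas = [a for _, a in comps]
            if any(t <= 0 for t in taus):
                raise ValueError("all tau must be > 0")
            if any(a < 0 for a in areas) or abs(sum(areas) - 1.0) > 1e-9:
                raise ValueError("areas must be >= 0 and sum to 1")
        if self.n_channels < 1:
            raise ValueError("n_channels >= 1")

    def mean_dwell(self, state: str) -> float:
        comps = (
            self.open_components if state == OPEN else self.closed_components
        )
        return float(sum(a * t for t, a in comps))

    def equilibrium_po(self) -> float:
        """Analytic single-channel open probability of the alternating renewal
        process: mean_open / (mean_open + mean_closed)."""
        mo, mc = self.mean_dwell(OPEN), self.mean_dwell(CLOSED)
        return mo / (mo + mc)


#: Shipped gating schemes.  Open-time constants and areas follow the
#: single-channel phenotypes of alpha1beta3 (tau 0.65/4.3 ms, 17% long
#: openings, 1.3 pA) and alpha1beta3gamma2 (tau 0.78/4.8 ms, 61% long
#: openings, 1.9 pA) receptors at near-saturating GABA and -70 mV.  Closed
#: mixtures are chosen to give a low overall Po for the binary receptor and
#: a several-fold higher Po for the gamma2-containing one.
SCHEMES: dict[str, GatingScheme] = {
    "a1b3-like": GatingScheme(
        open_components=((0.65, 0.83), (4.3, 0.17)),
        closed_components=((0.5, 0.5), (30.0, 0.5)),
        unitary_current=1.3,
    ),
    "a1b3g2-like": GatingScheme(
        open_components=((0.78, 0.39), (4.8, 0.61)),
        closed_components=((0.5, 0.6), (10.0, 0.4)),
        unitary_current=1.9,
    ),
}


@dataclass
class SweepRecord:
    """A sampled current trace (pA) with its acquisition settings."""

    samples: np.ndarray
    sampling_rate: float = 20_000.0  # Hz
    filter_cutoff: float | None = 5_000.0  # Hz; None = unfiltered
    holding_potential: float = -70.0  # mV
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.filter_cutoff is not None and (
            self.sampling_rate <= 2.0 * self.filter_cutoff
        ):
            raise ValueError("sampling_rate must exceed 2 x filter_cutoff")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.times, "current_pA": self.samples}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "SweepRecord":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 20_000.0
        kwargs.setdefault("sampling_rate", float(round(fs)))
        kwargs.setdefault("filter_cutoff", None)
        return cls(samples=df["current_pA"].to_numpy(), **kwargs)


def _sample_mixture(rng: np.random.Generator,
                    comps: tuple[tuple[float, float], ...]) -> float:
    taus = np.array([t for t, _ in comps])
    areas = np.array([a for _, a in comps])
    i = rng.choice(len(taus), p=areas)
    return float(rng.exponential(taus[i]))


def simulate_dwells(
    scheme: GatingScheme,
    duration: float,
    seed: int | None = None,
    start_state: str = CLOSED,
) -> EventList:
    """Simulate an alternating dwell sequence of ``duration`` seconds.

    Each dwell picks a mixture component with probability equal to its area
    then draws an exponential duration with that component's tau.  The final
    dwell is truncated at the record end and flagged partial.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0 s")
    rng = np.random.default_rng(seed)
    total_ms = duration * 1e3
    events: list[Event] = []
    t = 0.0
    state = start_state
    while t < total_ms:
        comps = (
            scheme.open_components if state == OPEN else scheme.closed_components
        )
        d = _sample_mixture(rng, comps)
        truncated = t + d > total_ms
        if truncated:
            d = total_ms - t
        amp = scheme.unitary_current if state == OPEN else 0.0
        events.append(Event(state=state, duration=d, mean_amplitude=amp))
        t += d
        state = OPEN if state == CLOSED else CLOSED
    return EventList(
        events=events,
        dead_time=0.0,
        total_duration=duration,
        first_partial=True,
        last_partial=True,
        meta={"seed": seed, "scheme": scheme},
    )


def _telegraph(events: EventList, n_samples: int, fs: float) -> np.ndarray:
    bounds_ms = np.cumsum([e.duration for e in events.events])
    amps = np.array([e.mean_amplitude for e in events.events])
    t_ms = np.arange(n_samples) / fs * 1e3
    idx = np.searchsorted(bounds_ms, t_ms, side="right")
    idx = np.clip(idx, 0, len(amps) - 1)
    return amps[idx]


def bessel4_sos(cutoff: float, fs: float):
    """4-pole low-pass Bessel, digital (bilinear with prewarp), -3 dB at
    ``cutoff``; applied causally to mimic an analog recording filter."""
    return signal.bessel(4, cutoff, btype="low", norm="mag", fs=fs,
                         output="sos")


def render_trace(
    events: EventList | list[EventList],
    noise_sigma: float = 0.15,
    sampling_rate: float = 20_000.0,
    filter_cutoff: float | None = 5_000.0,
    seed: int | None = None,
    holding_potential: float = -70.0,
) -> SweepRecord:
    """Render event list(s) as a sampled, noisy, Bessel-filtered current.

    Multiple event lists (independent channels in one patch) are summed
    sample-wise, so simultaneous openings stack to multiples of the unitary
    current.  Gaussian noise is added before filtering; the 4-pole Bessel is
    applied forward-only (causal).
    """
    evls = events if isinstance(events, list) else [events]
    if not evls:
        raise ValueError("need at least one event list")
    dur = max(e.total_duration for e in evls)
    n = int(round(dur * sampling_rate))
    x = np.zeros(n)
    for ev in evls:
        x += _telegraph(ev, n, sampling_rate)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sigma, size=n)
    if filter_cutoff is not None:
        if sampling_rate <= 2.0 * filter_cutoff:
            raise ValueError("sampling_rate must exceed 2 x filter_cutoff")
        x = signal.sosfilt(bessel4_sos(filter_cutoff, sampling_rate), x)
    return SweepRecord(
        samples=x,
        sampling_rate=sampling_rate,
        filter_cutoff=filter_cutoff,
        holding_potential=holding_potential,
        seed=seed,
    )


def simulate_record(
    scheme: GatingScheme,
    duration: float,
    seed: int | None = None,
    noise_sigma: float = 0.15,
    sampling_rate: float = 20_000.0,
    filter_cutoff: float | None = 5_000.0,
) -> tuple[SweepRecord, list[EventList]]:
    """Simulate ``scheme.n_channels`` independent channels and render the
    summed trace.  Returns the trace and the per-channel ground truth."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(scheme.n_channels + 1)
    truths = [
        simulate_dwells(scheme, duration,
                        seed=int(c.generate_state(1)[0] % (2**31)))
        for c in child[:-1]
    ]
    trace = render_trace(
        truths,
        noise_sigma=noise_sigma,
        sampling_rate=sampling_rate,
        filter_cutoff=filter_cutoff,
        seed=int(child[-1].generate_state(1)[0] % (2**31)),
    )
    trace.meta["scheme"] = scheme
    return trace, truths
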