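"""Amplitude fitting, half-amplitude idealization and conductance.

Recovers the unitary current from the all-points amplitude histogram by
Gaussian mixture fitting, then idealizes the trace with the 50% threshold
rule: a transition is scored wherever the current crosses halfway between
the baseline and the open level, events shorter than the system dead time
(default 80 us) are merged into the flanking state, and censored first/last
events are flagged so they stay out of dwell statistics.

Multi-level detection uses thresholds at (k - 1/2) x unitary for k = 1, 2,
...; only level-1 occupancy defines open dwells, while time spent at level
>= 2 (channel stacking) is tracked per event for the patch-rejection rule:
a record is rejected when stacked openings exceed 2% of total open time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .events import CLOSED, OPEN, Event, EventList
from .gating_sim import SweepRecord

__all__ = [
    "AmplitudeFit",
    "fit_amplitudes",
    "idealize_threshold",
    "conductance",
    "stacking_check",
]


@dataclass(frozen=True)
class AmplitudeFit:
    """Gaussian components of the amplitude histogram.

    ``components`` are (mean pA, sd pA, area) sorted by mean; the baseline
    is the dominant (largest-area) component and the unitary current the
    separation to the next level above it.
    """

    components: tuple[tuple[float, float, float], ...]
    baseline_mean: float
    unitary_current: float


def fit_amplitudes(
    trace: SweepRecord,
    n_components: int = 2,
    seed: int | None = 0,
    max_samples: int = 200_000,
) -> AmplitudeFit:
    """Fit a Gaussian mixture to the sample-amplitude distribution.

    The baseline is taken as the largest-area component; the unitary current
    is the distance from the baseline to the nearest component above it.
    Raises ``ValueError`` when no component is resolvably separated from the
    baseline (e.g. an all-shut record).
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size < 1_000:
        raise ValueError("need >= 1000 samples for amplitude fitting")
    if n_components < 2:
        raise ValueError("n_components must be >= 2 (baseline + open level)")
    if x.size > max_samples:
        step = x.size // max_samples
        x = x[::step]
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=3,
        random_state=seed,
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    areas = gm.weights_.ravel()
    order = np.argsort(means)
    comps = tuple(
        (float(means[i]), float(sds[i]), float(areas[i])) for i in order
    )
    i_base = int(np.argmax([c[2] for c in comps]))
    baseline = comps[i_base][0]
    # nearest component separated from baseline by > 2x the summed sds
    best = None
    for j, (m, s, _a) in enumerate(comps):
        if j == i_base:
            continue
        sep = abs(m - baseline)
        if sep > 2.0 * (s + comps[i_base][1]) and (
            best is None or sep < best[0]
        ):
            best = (sep, m)
    if best is None:
        raise ValueError(
            "unitary current undefined: no open level resolved above baseline"
        )
    return AmplitudeFit(
        components=comps,
        baseline_mean=float(baseline),
        unitary_current=float(best[0]),
    )


def _merge_short_runs(levels: np.ndarray, min_len: int) -> np.ndarray:
    """Run-length representation of a binary state sequence with all interior
    runs shorter than ``min_len`` merged into the flanking state.

    Returns (value, length) pairs.  Merging is idempotent: flanking runs of a
    removed run share a state and coalesce, and the scan repeats until every
    interior run is >= min_len.
    """
    # run-length encode
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [levels.size])))
    vals = levels[starts].astype(int)
    runs = list(zip(vals, lengths.tolist()))
    if min_len <= 1:
        return np.array(runs, dtype=int)
    changed = True
    while changed:
        changed = False
        if len(runs) < 3:
            break
        # find shortest interior sub-resolution run
        interior = [
            (ln, i) for i, (_v, ln) in enumerate(runs)
            if 0 < i < len(runs) - 1 and ln < min_len
        ]
        if not interior:
            break
        _, i = min(interior)
        v_prev, l_prev = runs[i - 1]
        _v, l_mid = runs[i]
        v_next, l_next = runs[i + 1]
        # binary states: flanks agree; absorb all three into one run
        assert v_prev == v_next
        runs[i - 1: i + 2] = [(v_prev, l_prev + l_mid + l_next)]
        changed = True
    return np.array(runs, dtype=int)


def idealize_threshold(
    trace: SweepRecord,
    amp: AmplitudeFit,
    dead_time: float = 80.0,
) -> EventList:
    """Half-amplitude threshold idealization.

    Parameters
    ----------
    trace : SweepRecord
    amp : AmplitudeFit
        Supplies baseline and unitary current; thresholds sit at
        baseline + (k - 1/2) x unitary.
    dead_time : float
        System dead time in microseconds; interior events shorter than this
        are merged into the flanking state.
    """
    if amp.unitary_current <= 0:
        raise ValueError("unitary current must be positive")
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.sampling_rate
    dt_ms = 1e3 / fs
    # level occupancy via thresholds at (k - 0.5) * unitary
    rel = (x - amp.baseline_mean) / amp.unitary_current
    levels = np.maximum(np.floor(rel + 0.5).astype(int), 0)
    open_mask = (levels >= 1).astype(int)
    min_len = max(int(np.ceil(dead_time * 1e-6 * fs)), 1)
    runs = _merge_short_runs(open_mask, min_len)
    events: list[Event] = []
    pos = 0
    for v, ln in runs:
        seg = slice(pos, pos + ln)
        state = OPEN if v == 1 else CLOSED
        stacked = 0.0
        if state == OPEN:
            stacked = float(np.count_nonzero(levels[seg] >= 2)) * dt_ms
        events.append(
            Event(
                state=state,
                duration=ln * dt_ms,
                mean_amplitude=float(x[seg].mean()),
                stacked_time=stacked,
            )
        )
        pos += ln
    return EventList(
        events=events,
        dead_time=dead_time,
        total_duration=x.size / fs,
        first_partial=True,
        last_partial=True,
        meta={"threshold": amp.baseline_mean + 0.5 * amp.unitary_current},
    )


def conductance(
    unitary_current: float, v_hold: float, v_rev: float = 0.0
) -> float:
    """Chord conductance in pS from unitary current (pA) and driving force.

    gamma = 1000 * |i| / |V_hold - V_rev|  (pA/mV -> pS).
    """
    dv = abs(v_hold - v_rev)
    if dv == 0:
        raise ValueError("zero driving force: v_hold == v_rev")
    return 1000.0 * abs(unitary_current) / dv


def stacking_check(
    events: EventList, amp: AmplitudeFit | None = None
) -> tuple[bool, float]:
    """Patch-rejection rule for multi-channel contamination.

    Returns ``(accepted, stacked_fraction)`` where stacked_fraction is open
    time spent at >= 2x the unitary level over total open time.  A record is
    rejected only when the fraction strictly exceeds 2%.
    """
    open_time = events.open_time()
    if open_time == 0:
        return True, 0.0
    stacked = sum(e.stacked_time for e in events.events if e.state == OPEN)
    frac = stacked / open_time
    return frac <= 0.02, float(frac)
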