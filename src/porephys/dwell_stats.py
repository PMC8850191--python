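"""Dwell-time distributions, exponential-mixture fits, bursts and Po.

Open and closed dwell durations from an idealized single-channel record are
modelled as a mixture of exponentials with density

    y(t) = sum_i (A_i / tau_i) * exp(-t / tau_i),   sum_i A_i = 1

Two fitting routes are provided:

``mle``
    Maximum likelihood on the raw durations, left-truncated at the recording
    dead time.  Statistically preferred and the default.
``ls_histogram``
    Nonlinear least squares of the mixture to a log-binned dwell histogram
    (Sigworth-Sine binning, square-root ordinate available for display) —
    the classic Levenberg-Marquardt histogram route, kept for comparability
    with legacy analyses, and the route on which the F-test for the number
    of components is defined.

The number of components is chosen by a stepwise F-test on nested
least-squares fits (likelihood-ratio analogue for MLE fits).  Bursts are
delimited by a critical closed time tau_crit chosen so that equal *numbers*
of fast and slow closures are misclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .events import CLOSED, OPEN, EventList

__all__ = [
    "DwellDistribution",
    "ExpMixtureFit",
    "BurstSet",
    "log_bin_histogram",
    "fit_exp_mixture",
    "select_n_components",
    "tau_crit",
    "define_bursts",
    "open_probability",
    "long_open_fraction",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class DwellDistribution:
    """Log-binned dwell-duration histogram (one state class)."""

    durations: np.ndarray  # ms
    bin_edges: np.ndarray  # ms, log-spaced
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.durations.size)


@dataclass(frozen=True)
class ExpMixtureFit:
    """Fitted exponential mixture.

    ``components`` are (tau_ms, area) sorted by tau; ``objective`` is
    "log_likelihood" (maximized) or "ssr" (minimized); ``dof`` counts
    n_obs - (2k - 1) free parameters (areas sum to 1).
    """

    components: tuple[tuple[float, float], ...]
    objective: str
    objective_value: float
    n_obs: int
    method: str
    dead_time: float = 0.0  # ms

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for t, _ in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for _, a in self.components])

    @property
    def dof(self) -> int:
        return self.n_obs - (2 * self.n_components - 1)

    def mean(self) -> float:
        """Mixture mean, sum A_i tau_i (ms, untruncated)."""
        return float(np.sum(self.taus * self.areas))

    def density(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.areas[:, None] / self.taus[:, None]
            * np.exp(-t[None, :] / self.taus[:, None]),
            axis=0,
        )

    def survivor(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.areas[:, None] * np.exp(-t[None, :] / self.taus[:, None]),
            axis=0,
        )


@dataclass(frozen=True)
class BurstSet:
    tau_crit: float  # ms
    bursts: tuple[tuple[int, int], ...]  # event index ranges [i, j)
    per_burst_po: tuple[float, ...]

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)


# ---------------------------------------------------------------------------
# histogram


def log_bin_histogram(
    durations: np.ndarray, bins_per_decade: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Log10-spaced dwell histogram (Sigworth-Sine style binning).

    Returns (edges_ms, counts); edges span the data range.
    """
    d = np.asarray(durations, dtype=float)
    if np.any(d <= 0):
        raise ValueError("durations must be > 0")
    lo, hi = np.log10(d.min()), np.log10(d.max())
    if hi - lo < 1.0 / bins_per_decade:
        hi = lo + 1.0 / bins_per_decade
    n_bins = max(int(np.ceil((hi - lo) * bins_per_decade)), 1)
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[0] *= 1 - 1e-12  # guard rounding so min/max durations are binned
    edges[-1] *= 1 + 1e-12
    counts, _ = np.histogram(d, bins=edges)
    return edges, counts


def dwell_distribution(
    events: EventList, state: str, bins_per_decade: int = 25
) -> DwellDistribution:
    d = events.durations(state)
    edges, counts = log_bin_histogram(d, bins_per_decade)
    return DwellDistribution(durations=d, bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# mixture fitting


def _unpack(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    taus = np.exp(theta[:k])
    if k == 1:
        return taus, np.array([1.0])
    logits = np.concatenate((theta[k:], [0.0]))
    w = np.exp(logits - logits.max())
    return taus, w / w.sum()


def _neg_loglik(theta, t, k, t0):
    with np.errstate(over="ignore", invalid="ignore"):
        return _neg_loglik_raw(theta, t, k, t0)


def _neg_loglik_raw(theta, t, k, t0):
    if np.any(np.abs(theta) > 500):  # guard exp overflow in wild steps
        return 1e300
    taus, areas = _unpack(theta, k)
    dens = np.sum(
        areas[:, None] / taus[:, None] * np.exp(-t[None, :] / taus[:, None]),
        axis=0,
    )
    surv0 = np.sum(areas * np.exp(-t0 / taus))
    if surv0 <= 0 or np.any(dens <= 0):
        return 1e300
    return -(np.sum(np.log(dens)) - t.size * np.log(surv0))


def _bin_expected(taus, areas, edges, n, t0):
    surv = np.sum(
        areas[:, None] * np.exp(-edges[None, :] / taus[:, None]), axis=0
    )
    surv0 = np.sum(areas * np.exp(-t0 / taus)) if t0 > 0 else 1.0
    return n * (surv[:-1] - surv[1:]) / surv0


def _init_starts(t, k, n_starts, seed):
    """Seeded multi-start inits: log-tau spread log-uniformly over the data
    range, areas from a flat Dirichlet."""
    rng = np.random.default_rng(seed)
    lo, hi = np.log(t.min()), np.log(t.max())
    starts = []
    # deterministic first start: quantile-spread taus, equal areas
    qs = np.quantile(t, np.linspace(0.2, 0.9, k))
    starts.append(np.concatenate((np.log(qs), np.zeros(max(k - 1, 0)))))
    for _ in range(n_starts - 1):
        lt = np.sort(rng.uniform(lo, hi, size=k))
        logits = rng.normal(0.0, 1.0, size=max(k - 1, 0))
        starts.append(np.concatenate((lt, logits)))
    return starts


def fit_exp_mixture(
    durations: np.ndarray,
    n_components: int,
    method: str = "mle",
    dead_time: float = 0.0,
    bins_per_decade: int = 25,
    n_starts: int = 10,
    seed: int = 0,
) -> ExpMixtureFit:
    """Fit a k-component exponential mixture to dwell durations (ms).

    Parameters
    ----------
    durations : array
        Dwell times (ms) of one state class, all > dead_time.
    n_components : int
    method : {"mle", "ls_histogram"}
        MLE maximizes the left-truncated mixture likelihood; ls_histogram
        least-squares the expected bin counts of the log-binned histogram.
    dead_time : float
        Truncation point (ms); durations at or below it are discarded.
    n_starts : int
        Multi-start initializations (seeded); best objective wins.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t = np.asarray(durations, dtype=float)
    t = t[t > dead_time]
    k = n_components
    if t.size < 10 * (2 * k - 1):
        raise ValueError(
            f"need >= {10 * (2 * k - 1)} dwells for {k} components, have {t.size}"
        )
    if method not in ("mle", "ls_histogram"):
        raise ValueError(f"unknown method {method!r}")

    starts = _init_starts(t, k, n_starts, seed)

    if method == "mle":
        best = None
        for x0 in starts:
            res = optimize.minimize(
                _neg_loglik, x0, args=(t, k, dead_time), method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("mixture MLE failed to converge")
        taus, areas = _unpack(best.x, k)
        order = np.argsort(taus)
        return ExpMixtureFit(
            components=tuple(
                (float(taus[i]), float(areas[i])) for i in order
            ),
            objective="log_likelihood",
            objective_value=float(-best.fun),
            n_obs=int(t.size),
            method="mle",
            dead_time=dead_time,
        )

    edges, counts = log_bin_histogram(t, bins_per_decade)

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            if np.any(np.abs(theta) > 500):
                return np.full(counts.size, 1e150)
            taus, areas = _unpack(theta, k)
            out = _bin_expected(taus, areas, edges, t.size, dead_time) - counts
        return np.nan_to_num(out, nan=1e150, posinf=1e150, neginf=-1e150)

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(resid, x0, method="lm",
                                         max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("histogram least-squares failed to converge")
    taus, areas = _unpack(best.x, k)
    order = np.argsort(taus)
    ssr = float(np.sum(best.fun**2))
    return ExpMixtureFit(
        components=tuple((float(taus[i]), float(areas[i])) for i in order),
        objective="ssr",
        objective_value=ssr,
        n_obs=int(counts.size),
        method="ls_histogram",
        dead_time=dead_time,
    )


def select_n_components(
    fits: list[ExpMixtureFit], alpha: float = 0.05
) -> int:
    """Choose the number of exponential components by stepwise testing.

    ``fits`` must be nested fits of the same data/method ordered by
    increasing n_components.  For least-squares fits the classic F-test is
    applied to successive pairs:

        F = ((SSR_1 - SSR_2) / (df_1 - df_2)) / (SSR_2 / df_2)

    and the larger model is accepted iff p < alpha.  For MLE fits a
    likelihood-ratio chi-square test with 2 extra dof per component is used
    instead.  Returns the selected n_components.
    """
    if not fits:
        raise ValueError("no fits supplied")
    methods = {f.method for f in fits}
    if len(methods) != 1:
        raise ValueError("fits must share a method")
    ks = [f.n_components for f in fits]
    if ks != sorted(ks) or len(set(ks)) != len(ks):
        raise ValueError("fits must be strictly nested by n_components")
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("fits must share the data")
    method = methods.pop()
    current = fits[0]
    for bigger in fits[1:]:
        if method == "ls_histogram":
            ssr1, ssr2 = current.objective_value, bigger.objective_value
            df1, df2 = current.dof, bigger.dof
            if df2 <= 0:
                break
            if ssr2 >= ssr1:  # no improvement -> keep smaller model
                break
            f_stat = ((ssr1 - ssr2) / (df1 - df2)) / (ssr2 / df2)
            p = stats.f.sf(f_stat, df1 - df2, df2)
        else:
            lr = 2.0 * (bigger.objective_value - current.objective_value)
            extra = 2 * (bigger.n_components - current.n_components)
            p = stats.chi2.sf(max(lr, 0.0), extra)
        if p < alpha:
            current = bigger
        else:
            break
    return current.n_components


# ---------------------------------------------------------------------------
# bursts and open probability


def tau_crit(
    closed_fit: ExpMixtureFit,
    fast_index: int = 0,
    slow_index: int | None = None,
    criterion: str = "equal_numbers",
) -> float:
    """Critical closed time separating within-burst from between-burst gaps.

    ``equal_numbers`` (default) solves

        A_f * exp(-t/tau_f) = A_s * (1 - exp(-t/tau_s))

    so the expected number of fast closures misclassified as between-burst
    equals the expected number of slow closures misclassified as
    within-burst.  ``equal_proportions`` drops the areas.  Root bracketed in
    (tau_f, tau_s).
    """
    if closed_fit.n_components < 2:
        raise ValueError("need >= 2 closed components for tau_crit")
    if slow_index is None:
        slow_index = closed_fit.n_components - 1
    tf, af = closed_fit.components[fast_index]
    ts, as_ = closed_fit.components[slow_index]
    if not tf < ts:
        raise ValueError("fast tau must be < slow tau")

    if criterion == "equal_numbers":
        def g(t):
            return af * np.exp(-t / tf) - as_ * (1.0 - np.exp(-t / ts))
    elif criterion == "equal_proportions":
        def g(t):
            return np.exp(-t / tf) - (1.0 - np.exp(-t / ts))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    lo, hi = tf, ts
    if g(lo) <= 0 or g(hi) >= 0:
        raise ValueError("no tau_crit root bracketed in (tau_fast, tau_slow)")
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-12))


def define_bursts(events: EventList, tau_crit_ms: float) -> BurstSet:
    """Group events into bursts delimited by closures >= tau_crit.

    A burst is a maximal stretch of events containing at least one opening
    whose internal closed dwells are all < tau_crit.  Per-burst Po is open
    time over burst duration.
    """
    evs = events.events
    bursts: list[tuple[int, int]] = []
    pos = []
    start = None
    for i, e in enumerate(evs):
        long_gap = e.state == CLOSED and e.duration >= tau_crit_ms
        if long_gap:
            if start is not None:
                bursts.append((start, i))
                start = None
        else:
            if e.state == OPEN and start is None:
                start = i
    if start is not None:
        bursts.append((start, len(evs)))
    # trim trailing closed events inside each burst
    trimmed = []
    for a, b in bursts:
        while b > a and evs[b - 1].state == CLOSED:
            b -= 1
        if b > a:
            trimmed.append((a, b))
    for a, b in trimmed:
        dur = sum(e.duration for e in evs[a:b])
        op = sum(e.duration for e in evs[a:b] if e.state == OPEN)
        pos.append(op / dur if dur > 0 else 0.0)
    return BurstSet(
        tau_crit=float(tau_crit_ms),
        bursts=tuple(trimmed),
        per_burst_po=tuple(pos),
    )


def open_probability(events: EventList) -> float:
    """Whole-record open probability: total open time / record duration."""
    if events.total_duration <= 0:
        raise ValueError("total_duration must be > 0")
    return events.open_time() / (events.total_duration * 1e3)


def long_open_fraction(fit: ExpMixtureFit, long_index: int = -1) -> float:
    """Percentage of openings in the indexed (default slowest) component."""
    try:
        _tau, area = fit.components[long_index]
    except IndexError as exc:
        raise IndexError(
            f"component {long_index} out of range for "
            f"{fit.n_components}-component fit"
        ) from exc
    return 100.0 * float(area)
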