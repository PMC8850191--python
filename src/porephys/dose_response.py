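"""Whole-cell concentration-response analysis.

Activation data are fitted to the Hill equation

    I / I_max = A**n / (EC50**n + A**n)

and blocker data to its inhibition counterpart

    I / I_max = 1 - B**n / (IC50**n + B**n)

where A (B) is the agonist (blocker) concentration and n the Hill
coefficient.  Fits are performed per cell and summarized on the log scale
as pEC50 = -log10(EC50) +/- s.e.m., the convention for reporting potencies.
Helpers cover percentage inhibition, the probability of activation P_A
(maximal agonist current relative to the agonist + allosteric-potentiator
maximum), and EC_f back-calculation from a fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ConcentrationResponse",
    "HillFit",
    "fit_hill",
    "fit_hill_per_cell",
    "ec_fraction",
    "percent_inhibition",
    "activation_probability",
]


@dataclass(frozen=True)
class ConcentrationResponse:
    """Normalized responses (I/I_max) at a series of concentrations (M)."""

    concentrations: np.ndarray
    responses: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        if c.shape != r.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class HillFit:
    ec50_or_ic50: float  # M
    hill_n: float
    mode: str  # "activation" | "inhibition"
    rss: float
    n_points: int

    @property
    def p_value_log(self) -> float:
        """pEC50 or pIC50 = -log10 of the midpoint concentration."""
        return float(-np.log10(self.ec50_or_ic50))

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        occ = conc**self.hill_n / (
            self.ec50_or_ic50**self.hill_n + conc**self.hill_n
        )
        return occ if self.mode == "activation" else 1.0 - occ


def _hill_model(logc, p50, n, mode):
    occ = 1.0 / (1.0 + 10.0 ** (n * (p50 - logc)))
    return occ if mode == "activation" else 1.0 - occ


def fit_hill(data: ConcentrationResponse, mode: str = "activation") -> HillFit:
    """Least-squares fit of the two-parameter Hill/inhibition equation.

    Requires >= 4 concentrations spanning >= 1.5 decades.  The midpoint is
    fitted on the log10 scale for conditioning; the Hill coefficient is
    unconstrained positive.  Warns when the responses are not monotonic in
    the direction the mode implies.
    """
    if mode not in ("activation", "inhibition"):
        raise ValueError(f"unknown mode {mode!r}")
    c, r = data.concentrations, data.responses
    if c.size < 4:
        raise ValueError("need >= 4 concentrations")
    logc = np.log10(c)
    if logc.max() - logc.min() < 1.5:
        raise ValueError("concentrations must span >= 1.5 decades")
    order = np.argsort(c)
    diffs = np.diff(r[order])
    expected_sign = 1.0 if mode == "activation" else -1.0
    if np.sum(np.sign(diffs) == expected_sign) < diffs.size / 2:
        warnings.warn(
            f"responses are not predominantly "
            f"{'increasing' if mode == 'activation' else 'decreasing'} "
            f"with concentration; check mode", stacklevel=2,
        )
    p0 = (float(np.median(logc)), 1.0)
    popt, _ = optimize.curve_fit(
        lambda lc, p50, n: _hill_model(lc, p50, n, mode),
        logc, r, p0=p0, bounds=([logc.min() - 4, 0.05], [logc.max() + 4, 10]),
        maxfev=10_000,
    )
    p50, n = popt
    rss = float(np.sum((r - _hill_model(logc, p50, n, mode)) ** 2))
    return HillFit(
        ec50_or_ic50=float(10.0**p50),
        hill_n=float(n),
        mode=mode,
        rss=rss,
        n_points=int(c.size),
    )


def fit_hill_per_cell(
    df: pd.DataFrame, mode: str = "activation"
) -> pd.DataFrame:
    """Fit each cell separately and summarize pEC50/pIC50.

    ``df`` needs columns cell_id, concentration_M, response_fraction.
    Returns one row per cell plus a summary attribute frame with the mean
    pEC50, s.e.m. and the mean converted back to molar.
    """
    rows = []
    for cell, grp in df.groupby("cell_id"):
        fit = fit_hill(
            ConcentrationResponse(
                grp["concentration_M"].to_numpy(),
                grp["response_fraction"].to_numpy(),
                cell_id=str(cell),
            ),
            mode=mode,
        )
        rows.append(
            {
                "cell_id": cell,
                "midpoint_M": fit.ec50_or_ic50,
                "hill_n": fit.hill_n,
                "p_log": fit.p_value_log,
            }
        )
    out = pd.DataFrame(rows)
    p = out["p_log"].to_numpy()
    out.attrs["summary"] = {
        "mean_p": float(p.mean()),
        "sem_p": float(p.std(ddof=1) / np.sqrt(p.size)) if p.size > 1 else 0.0,
        "mean_midpoint_M": float(10.0 ** -p.mean()),
        "n_cells": int(p.size),
    }
    return out


def ec_fraction(fit: HillFit, fraction: float) -> float:
    """Concentration (M) giving a response fraction f: EC50*(f/(1-f))**(1/n)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return float(
        fit.ec50_or_ic50 * (fraction / (1.0 - fraction)) ** (1.0 / fit.hill_n)
    )


def percent_inhibition(control: float, with_blocker: float) -> float:
    """Percent inhibition, 100 * (1 - I_blocked / I_control)."""
    if control == 0:
        raise ValueError("control current must be nonzero")
    return 100.0 * (1.0 - with_blocker / control)


def activation_probability(
    i_agonist_max: float, i_agonist_plus_potentiator_max: float
) -> float:
    """Probability of activation P_A.

    Ratio of the maximal agonist response to the maximal response with a
    saturating positive allosteric modulator added; ~1 means the agonist
    alone already drives the channel to its ceiling open probability.
    """
    if i_agonist_plus_potentiator_max == 0:
        raise ValueError("denominator current must be nonzero")
    pa = i_agonist_max / i_agonist_plus_potentiator_max
    if abs(i_agonist_max) > abs(i_agonist_plus_potentiator_max):
        warnings.warn("agonist response exceeds potentiated maximum",
                      stacklevel=2)
    return pa
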