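"""Free metal-ion concentrations in chelator-buffered solutions.

Divalent cations such as Zn2+ bind common recording-solution components and
glassware at trace levels, so electrophysiologists control the *free* ion
concentration with a chelator (here tricine) in large excess over the total
metal.  With the chelator in excess, the free concentration follows the
linear relation

    [M]_free = alpha * K_d * [M]_total / [L]_total

where ``K_d`` is the metal-chelator dissociation constant and ``alpha``
corrects for protonation of the chelator at the working pH:

    alpha = 1 + [H+] / K_a,    [H+] = 10**(-pH)

An exact 1:1 binding solver (:func:`free_metal_exact`) is provided as a
cross-check; it converges to the linear formula when the chelator is in
large excess and diverges from it otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BufferSpec",
    "alpha_factor",
    "free_metal",
    "free_metal_exact",
    "free_metal_series",
]

#: Default tricine constants: dissociation constant for the Zn-tricine
#: complex and the proton constant entering the alpha factor (both molar).
TRICINE_KD = 10e-6
TRICINE_KA = 7.08e-9


@dataclass(frozen=True)
class BufferSpec:
    """Definition of one free-ion calculation.

    Parameters
    ----------
    total_metal : float
        Total metal concentration (M).
    chelator_total : float
        Total chelator concentration (M); must be positive.
    k_d : float
        Metal-chelator dissociation constant (M).
    k_a : float
        Proton constant of the chelator used in the alpha factor (M).
    pH : float
        Solution pH.
    alpha_override : float, optional
        Use this alpha instead of computing ``1 + [H+]/k_a``.  Useful to
        reproduce a published table computed with a slightly different
        rounding of alpha.
    """

    total_metal: float
    chelator_total: float = 10e-3
    k_d: float = TRICINE_KD
    k_a: float = TRICINE_KA
    pH: float = 7.4
    alpha_override: float | None = None

    def __post_init__(self) -> None:
        if self.total_metal < 0:
            raise ValueError("total_metal must be >= 0")
        if self.chelator_total <= 0:
            raise ValueError("chelator_total must be > 0")
        if self.k_d <= 0 or self.k_a <= 0:
            raise ValueError("k_d and k_a must be > 0")

    @property
    def alpha(self) -> float:
        if self.alpha_override is not None:
            return self.alpha_override
        return alpha_factor(self.pH, self.k_a)


def alpha_factor(pH: float, k_a: float) -> float:
    """Protonation correction ``alpha = 1 + 10**(-pH) / k_a``.

    Approaches 1 at high pH (fully deprotonated chelator) and 2 when
    ``[H+] == k_a``.
    """
    if k_a <= 0:
        raise ValueError("k_a must be > 0")
    return 1.0 + 10.0 ** (-pH) / k_a


def free_metal(spec: BufferSpec) -> float:
    """Free metal concentration (M) by the linearized excess-chelator formula.

    ``[M]_free = alpha * k_d * total_metal / chelator_total``.  Warns when the
    chelator is not in at least 10-fold excess over the metal, where the
    linearization degrades (see :func:`free_metal_exact`).
    """
    if spec.chelator_total < 10.0 * spec.total_metal:
        warnings.warn(
            "chelator not in >=10x excess over total metal; the linearized "
            "free-ion formula is inaccurate here (use free_metal_exact)",
            stacklevel=2,
        )
    return spec.alpha * spec.k_d * spec.total_metal / spec.chelator_total


def free_metal_exact(spec: BufferSpec) -> float:
    """Free metal (M) from the exact 1:1 equilibrium, proton-corrected.

    Solves M + L <=> ML with conditional dissociation constant
    ``K' = alpha * k_d`` under mass conservation for both species:

        [M]_free^2 + (K' + L_t - M_t) [M]_free - K' M_t = 0

    taking the positive root.  Agrees with :func:`free_metal` in the
    excess-chelator limit.
    """
    kc = spec.alpha * spec.k_d
    b = kc + spec.chelator_total - spec.total_metal
    c = -kc * spec.total_metal
    # positive root of x^2 + b x + c = 0; c <= 0 guarantees one
    return float((-b + np.sqrt(b * b - 4.0 * c)) / 2.0)


def free_metal_series(
    totals: "np.ndarray | list[float]",
    chelator_total: float = 10e-3,
    k_d: float = TRICINE_KD,
    k_a: float = TRICINE_KA,
    pH: float = 7.4,
    alpha_override: float | None = None,
) -> np.ndarray:
    """Vectorized :func:`free_metal` over a list of total concentrations (M)."""
    totals = np.asarray(totals, dtype=float)
    if np.any(totals < 0):
        raise ValueError("total concentrations must be >= 0")
    alpha = (
        alpha_override if alpha_override is not None else alpha_factor(pH, k_a)
    )
    return alpha * k_d * totals / chelator_total
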