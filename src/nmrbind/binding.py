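"""Two-state 1:1 binding thermodynamics and kinetic decomposition.

Shared by the relaxation, CPMG, and ITC stages.  Concentrations are uM,
rates s^-1, K_D uM; on-rates are reported in both uM^-1 s^-1 and M^-1 s^-1.

For A + B <-> AB with dissociation constant K_D the complex concentration is
the smaller root of the binding quadratic; the numerically stable
multiply-by-conjugate form is used so that tight binding (K_D much smaller
than the concentrations) does not lose precision to cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BindingParameters:
    """1:1 binding state: K_D, composition, and (optionally) kinetics."""

    kd: float                      # uM
    a_total: float                 # uM
    b_total: float                 # uM
    bound_fraction_a: float        # p_B, fraction of A in complex
    k_ex: float | None = None      # s^-1
    k_on: float | None = None      # uM^-1 s^-1
    k_off: float | None = None     # s^-1

    def __post_init__(self) -> None:
        complex_ = self.bound_fraction_a * self.a_total
        if complex_ > min(self.a_total, self.b_total) * (1 + 1e-9):
            raise ValueError("complex exceeds mass balance")
        if self.k_on is not None and self.k_off is not None:
            kd = self.k_off / self.k_on
            if abs(kd - self.kd) > 1e-6 * max(self.kd, 1e-30):
                raise ValueError("kd inconsistent with k_off/k_on")

    @property
    def k_on_per_molar(self) -> float | None:
        return None if self.k_on is None else self.k_on * 1e6


def complex_concentration(a_total, b_total, kd):
    """Equilibrium [AB] in uM for totals ``a_total``, ``b_total`` and ``kd``.

    Stable quadratic root: with s = a + b + kd,
    [AB] = (s - sqrt(s^2 - 4ab)) / 2 = 2ab / (s + sqrt(s^2 - 4ab)).
    Vectorizes over any argument.
    """
    a = np.asarray(a_total, dtype=float)
    b = np.asarray(b_total, dtype=float)
    kd = np.asarray(kd, dtype=float)
    s = a + b + kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * a * b, 0.0))
    denom = s + disc
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * a * b / np.where(denom > 0, denom, 1.0), 0.0)
    return c if c.shape else float(c)


def bound_fraction_exact(a_total, b_total, kd):
    """Fraction of A bound at equilibrium (exact 1:1 quadratic).

    ``kd = 0`` gives the stoichiometric limit min(1, b/a).  ``a_total = 0``
    is an error: the fraction is undefined.
    """
    a = np.asarray(a_total, dtype=float)
    if np.any(a <= 0):
        raise ValueError("a_total must be positive (bound fraction undefined)")
    f = complex_concentration(a_total, b_total, kd) / a
    return f if np.ndim(f) else float(f)


def kd_from_bound_fraction(p_b: float, a_total: float, b_total: float) -> float:
    """K_D (uM) from a measured bound fraction of A under 1:1 stoichiometry.

    With [AB] = p_b * a_total, K_D = [A]free [B]free / [AB].  Saturation
    (p_b -> b/a) gives K_D = 0; a bound population exceeding the available
    partner is a mass-balance violation.
    """
    if not 0 < p_b <= 1:
        raise ValueError("p_b must be in (0, 1]")
    complex_ = p_b * a_total
    if complex_ > b_total:
        raise ValueError(
            f"bound A ({complex_:.4g} uM) exceeds total partner ({b_total:.4g} uM)"
        )
    a_free = a_total - complex_
    b_free = b_total - complex_
    return a_free * b_free / complex_


def decompose_kinetics(
    k_ex: float, p_b: float, a_total: float, b_total: float
) -> tuple[float, float]:
    """Split the exchange rate k_ex = k_on [B]free + k_off into (k_on, k_off).

    Under two-state exchange the minor-state population obeys
    p_b = k_on [B]free / k_ex, hence ``k_off = (1 - p_b) k_ex`` and
    ``k_on = p_b k_ex / [B]free`` (uM^-1 s^-1).  The identity
    k_off / k_on = K_D from :func:`kd_from_bound_fraction` holds exactly.
    """
    if k_ex <= 0:
        raise ValueError("k_ex must be positive")
    complex_ = p_b * a_total
    b_free = b_total - complex_
    if b_free <= 0:
        raise ValueError("no free partner: cannot decompose kinetics")
    k_off = (1.0 - p_b) * k_ex
    k_on = p_b * k_ex / b_free
    return k_on, k_off


def binding_parameters(
    p_b: float, a_total: float, b_total: float, k_ex: float | None = None
) -> BindingParameters:
    """Bundle K_D (and kinetics when k_ex is given) derived from p_b."""
    kd = kd_from_bound_fraction(p_b, a_total, b_total)
    if k_ex is None:
        return BindingParameters(kd, a_total, b_total, p_b)
    k_on, k_off = decompose_kinetics(k_ex, p_b, a_total, b_total)
    return BindingParameters(kd, a_total, b_total, p_b, k_ex=k_ex, k_on=k_on, k_off=k_off)
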