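"""Single-site (1:1) isothermal titration calorimetry: forward model and fit.

The forward model is the standard perfect-mixing displaced-volume
bookkeeping of an injection-type calorimeter: each injection of volume v
into the cell of volume V0 dilutes the current cell contents by
(1 - v/V0) and adds syringe material at c_syr * v / V0.  At each
post-injection composition the complex concentration follows the exact 1:1
binding quadratic with the stoichiometry n folded into the binding-site
concentration n * [cell].  The heat of injection i is

    q_i = dh * V0 * ([AB]_i - [AB]_{i-1} * (1 - v_i/V0)) + offset

with dh in kcal/mol, volumes in uL, concentrations in uM and heats in ucal
(1 kcal = 1e9 ucal, so the unit constant is 1e-3 ucal per uL*uM*kcal/mol).

The shape of the isotherm is governed by the Wiseman parameter
c = n * [cell] / K_D; the fit warns outside c in [1, 1000] where K_D is
poorly determined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .binding import complex_concentration
from .core import ItcTable

logger = logging.getLogger("nmrbind")

#: ucal per (uL * uM * kcal/mol)
HEAT_UNIT = 1e-3


@dataclass(frozen=True)
class ItcFit:
    """1:1 ITC fit result: stoichiometry, affinity, enthalpy, baseline."""

    n: float                 # sites per cell molecule
    kd: float                # uM
    dh: float                # kcal/mol
    offset: float            # ucal per injection
    n_error: float
    kd_error: float
    dh_error: float
    offset_error: float
    chi2: float
    c_value: float           # n * cell_conc / kd

    def to_dict(self) -> dict:
        return {
            "n": self.n, "kd_uM": self.kd, "dh_kcal_mol": self.dh,
            "offset_ucal": self.offset, "n_error": self.n_error,
            "kd_error_uM": self.kd_error, "dh_error_kcal_mol": self.dh_error,
            "offset_error_ucal": self.offset_error, "chi2": self.chi2,
            "c_value": self.c_value,
        }


def _cell_composition(table: ItcTable):
    """Per-injection cell concentrations (uM) of macromolecule and titrant."""
    v0 = table.cell_volume_ul
    a = np.empty(table.n_injections)
    b = np.empty(table.n_injections)
    a_cur = table.cell_conc_um
    b_cur = 0.0
    for i, v in enumerate(table.volumes_ul):
        dil = 1.0 - v / v0
        a_cur = a_cur * dil
        b_cur = b_cur * dil + table.syringe_conc_um * v / v0
        a[i] = a_cur
        b[i] = b_cur
    return a, b


def simulate_injections(
    table: ItcTable, n: float, kd: float, dh: float, offset: float = 0.0
) -> np.ndarray:
    """Per-injection heats (ucal) of the 1:1 model for the table's design."""
    v0 = table.cell_volume_ul
    a, b = _cell_composition(table)
    sites = n * a
    complex_ = complex_concentration(sites, b, kd)
    heats = np.empty(table.n_injections)
    prev = 0.0
    for i, v in enumerate(table.volumes_ul):
        dil = 1.0 - v / v0
        heats[i] = dh * HEAT_UNIT * v0 * (complex_[i] - prev * dil) + offset
        prev = complex_[i]
    return heats


def molar_ratio(table: ItcTable) -> np.ndarray:
    """Titrant-to-macromolecule molar ratio in the cell after each injection."""
    a, b = _cell_composition(table)
    return b / a


def fit_itc(table: ItcTable, exclude_first: bool | None = None) -> ItcFit:
    """Nonlinear least-squares fit of (n, K_D, dh, offset) to injection heats.

    ``exclude_first`` defaults to the table's flag (customarily True).
    Requires >= 8 usable injections.  Non-convergence raises with residual
    diagnostics; a Wiseman c-value outside [1, 1000] logs a warning that the
    affinity is poorly determined.
    """
    if exclude_first is None:
        exclude_first = table.exclude_first
    heats = table.heats_ucal
    mask = np.ones(len(heats), dtype=bool)
    if exclude_first and len(heats) > 0:
        mask[0] = False
    if mask.sum() < 8:
        raise ValueError(f"only {int(mask.sum())} usable injections (need >= 8)")

    scale = max(np.abs(heats[mask]).max(), 1e-12)

    def resid(theta):
        n, log_kd, dh, offset = theta
        model = simulate_injections(table, n, np.exp(log_kd), dh, offset)
        return (heats[mask] - model[mask]) / scale

    # sign of dh from the early (near-saturating) injections
    dh0 = np.sign(heats[mask][:3].sum()) or 1.0
    theta0 = np.array([1.0, np.log(max(table.cell_conc_um, 1.0)), dh0 * 10.0, 0.0])
    lo = [1e-3, np.log(1e-6), -1e4, -np.inf]
    hi = [1e3, np.log(1e9), 1e4, np.inf]
    best = None
    for kd0 in (table.cell_conc_um / 10, table.cell_conc_um, table.cell_conc_um * 10):
        t0 = theta0.copy()
        t0[1] = np.log(kd0)
        res = least_squares(resid, t0, bounds=(lo, hi), method="trf")
        if best is None or res.cost < best.cost:
            best = res
    if not best.success and best.cost > 1e-6:
        raise RuntimeError(
            f"ITC fit did not converge (cost {best.cost:.3g}, "
            f"max residual {np.abs(best.fun).max():.3g})"
        )
    n, log_kd, dh, offset = best.x
    kd = float(np.exp(log_kd))

    dof = max(mask.sum() - 4, 1)
    chi2 = 2.0 * best.cost * scale**2
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * (2.0 * best.cost / dof)
        perr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        perr = np.full(4, np.nan)
    kd_err = kd * perr[1]  # delta method through log

    c_value = n * table.cell_conc_um / kd
    if not 1.0 <= c_value <= 1000.0:
        logger.warning(
            "Wiseman c = %.3g outside [1, 1000]: K_D poorly determined", c_value
        )
    return ItcFit(
        n=float(n), kd=kd, dh=float(dh), offset=float(offset),
        n_error=float(perr[0]), kd_error=float(kd_err),
        dh_error=float(perr[2]), offset_error=float(perr[3]),
        chi2=float(chi2), c_value=float(c_value),
    )
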