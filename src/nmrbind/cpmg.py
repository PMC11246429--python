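"""Constant-time CPMG relaxation dispersion: forward models and global fit.

Two-state exchange A (free, major) <-> B (bound, minor population p_b) with
total exchange rate k_ex = k_AB + k_BA, k_AB = p_b k_ex, k_BA = p_a k_ex.
The 15N chemical-shift difference dw between the states (ppm) converts to
rad/s through the 15N Larmor frequency, field_mhz * GAMMA_RATIO_N_H MHz.

Two forward models are provided:

* :func:`simulate_bm` — numerical propagation of the two-state transverse
  magnetization through the explicit (tau - 180 - 2tau - 180 - tau)^n pulse
  train (Bloch-McConnell), with ideal instantaneous 180 pulses modeled as
  complex conjugation.  Because conjugation is an antilinear involution, the
  propagator of one cycle is the *linear* operator
  E(tau) conj(E(2tau)) E(tau), which is raised to the n-th power.
* :func:`simulate_cr` — an exact Carver-Richards-type closed form (cycle
  eigenvalues plus mode amplitudes), used as the fast kernel of the global
  fit; it matches the numerical oracle to numerical precision.  The classic
  rate-only expression is available as :func:`carver_richards_rate`.

The global fit shares (k_ex, p_b) across all residues and fields, with a
field-independent |dw| (ppm) per residue and a baseline r2_0 per residue and
field, minimizing sum(((data - model)/error)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import binding
from .core import DispersionTable

#: gyromagnetic ratio of 15N relative to 1H (magnitude)
GAMMA_RATIO_N_H = 0.101329

#: study-design constant-time CPMG grid: cycle counts at t_relax = 32 ms
DEFAULT_CYCLES = (1, 2, 3, 4, 5, 6, 8, 10, 12, 16, 20, 24, 28, 32)
DEFAULT_T_RELAX = 0.032  # s


def nitrogen_omega(dw_ppm, field_mhz):
    """Convert a 15N shift difference in ppm to rad/s at the given 1H field."""
    return 2.0 * np.pi * field_mhz * GAMMA_RATIO_N_H * np.asarray(dw_ppm, dtype=float)


def cycle_count(nu_cpmg, t_relax):
    """Integer number of CPMG cycles: n = round(nu * t), required >= 1."""
    n = np.rint(np.asarray(nu_cpmg, dtype=float) * t_relax).astype(int)
    if np.any(n < 1):
        raise ValueError("nu_cpmg * t_relax must round to >= 1")
    return n


def r2eff_from_intensities(intensity, reference_intensity, t_relax):
    """Constant-time relation R2eff = -ln(I / I0) / t_relax.

    Non-positive intensities have no defined rate (peak broadened beyond
    detection) and raise; callers drop such points with a flag.
    """
    i = np.asarray(intensity, dtype=float)
    i0 = np.asarray(reference_intensity, dtype=float)
    if np.any(i <= 0) or np.any(i0 <= 0):
        raise ValueError("intensities must be positive to define R2eff")
    r = -np.log(i / i0) / t_relax
    return r if r.shape else float(r)


# ---------------------------------------------------------------------------
# numerical oracle: Bloch-McConnell propagation
# ---------------------------------------------------------------------------

def _expm2(a, b, c, d):
    """Vectorized matrix exponential of 2x2 complex matrices [[a, b], [c, d]]."""
    a, b, c, d = (np.asarray(x, dtype=complex) for x in (a, b, c, d))
    m = 0.5 * (a + d)
    q = np.sqrt(0.25 * (a - d) ** 2 + b * c)
    # e^m cosh(q) and e^m sinh(q)/q via exp(m +/- q): for relaxation matrices
    # Re(m) is strongly negative while Re(q) can be large, so the combined
    # exponents stay bounded where the bare cosh/sinh would overflow.
    ep = np.exp(m + q)
    en = np.exp(m - q)
    em_cosh = 0.5 * (ep + en)
    small = np.abs(q) < 1e-12
    qs = np.where(small, 1.0, q)
    em_sinhq = np.where(small, np.exp(m) * (1.0 + q**2 / 6.0), 0.5 * (ep - en) / qs)
    e11 = em_cosh + 0.5 * (a - d) * em_sinhq
    e12 = b * em_sinhq
    e21 = c * em_sinhq
    e22 = em_cosh - 0.5 * (a - d) * em_sinhq
    return e11, e12, e21, e22


def _matmul2(x, y):
    x11, x12, x21, x22 = x
    y11, y12, y21, y22 = y
    return (
        x11 * y11 + x12 * y21,
        x11 * y12 + x12 * y22,
        x21 * y11 + x22 * y21,
        x21 * y12 + x22 * y22,
    )


def simulate_bm(
    nu_cpmg,
    t_relax: float,
    field_mhz,
    dw_ppm,
    k_ex,
    p_b,
    r2_0,
    r2_0b=None,
):
    """R2eff from explicit Bloch-McConnell propagation (numerical oracle).

    All parameter arguments broadcast against ``nu_cpmg``.  ``r2_0b``
    defaults to ``r2_0`` (shared baseline for both states).

    Each of the n = round(nu * t) cycles is tau - 180 - 2tau - 180 - tau
    with tau = t / (4 n); the initial magnetization is population-weighted
    and the detected signal is the magnitude of the total transverse
    magnetization.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    shape = np.broadcast_shapes(
        nu.shape, np.shape(field_mhz), np.shape(dw_ppm), np.shape(k_ex),
        np.shape(p_b), np.shape(r2_0),
    )
    nu = np.broadcast_to(nu, shape)
    fm = np.broadcast_to(np.asarray(field_mhz, dtype=float), shape)
    dw = np.broadcast_to(np.asarray(dw_ppm, dtype=float), shape)
    kex = np.broadcast_to(np.asarray(k_ex, dtype=float), shape)
    pb = np.broadcast_to(np.asarray(p_b, dtype=float), shape)
    r2a = np.broadcast_to(np.asarray(r2_0, dtype=float), shape)
    r2b = r2a if r2_0b is None else np.broadcast_to(np.asarray(r2_0b, dtype=float), shape)

    n = cycle_count(nu, t_relax)
    pa = 1.0 - pb
    kab = pb * kex
    kba = pa * kex
    domega = nitrogen_omega(dw, fm)

    out = np.empty(shape, dtype=float)
    flat = out.reshape(-1)
    for idx, nn in enumerate(n.reshape(-1)):
        tau = t_relax / (4.0 * nn)
        i = np.unravel_index(idx, shape) if shape else ()
        A = (-r2a[i] - kab[i], kba[i], kab[i], -r2b[i] - kba[i] - 1j * domega[i])
        e_tau = _expm2(A[0] * tau, A[1] * tau, A[2] * tau, A[3] * tau)
        e_2tau = _expm2(A[0] * 2 * tau, A[1] * 2 * tau, A[2] * 2 * tau, A[3] * 2 * tau)
        e_2tau_c = tuple(np.conj(e) for e in e_2tau)
        cycle = _matmul2(e_tau, _matmul2(e_2tau_c, e_tau))
        ma, mb = complex(pa[i]), complex(pb[i])
        # even number of conjugations per cycle -> plain linear propagation
        for _ in range(int(nn)):
            ma, mb = cycle[0] * ma + cycle[1] * mb, cycle[2] * ma + cycle[3] * mb
        signal = abs(ma + mb)
        flat[idx] = -np.log(signal) / t_relax
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# closed-form kernel: Carver-Richards
# ---------------------------------------------------------------------------

def carver_richards_rate(
    nu_cpmg,
    t_relax: float,
    field_mhz,
    dw_ppm,
    k_ex,
    p_b,
    r2_0,
    r2_0b=None,
):
    """Classic Carver-Richards R2eff: the decay rate of the slowest mode.

    This is the familiar hyperbolic expression (Carver-Richards as
    formulated by Davis).  It omits the mode-amplitude contribution to the
    constant-time signal, so it deviates from :func:`simulate_cr` /
    :func:`simulate_bm` when the minor population is large and exchange is
    slow or shifts are small; in the fast-exchange regime it is excellent
    and underlies the R_ex = p_a p_b dw^2 / k_ex identity.

    Stable hyperbolic handling: for large eta the arccosh term is evaluated
    through its logarithmic asymptote so very fast exchange cannot overflow.
    ``nu_cpmg`` is snapped to the integer-cycle grid nu = round(nu t)/t.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    n = cycle_count(nu, t_relax)
    nu_eff = n / t_relax

    fm = np.asarray(field_mhz, dtype=float)
    dw = nitrogen_omega(np.asarray(dw_ppm, dtype=float), fm)
    kex = np.asarray(k_ex, dtype=float)
    pb = np.asarray(p_b, dtype=float)
    pa = 1.0 - pb
    r2a = np.asarray(r2_0, dtype=float)
    r2b = r2a if r2_0b is None else np.asarray(r2_0b, dtype=float)

    tau_cp = 1.0 / (2.0 * nu_eff)  # delay between successive 180 pulses
    x = r2a - r2b - pa * kex + pb * kex
    psi = x**2 - dw**2 + 4.0 * pa * pb * kex**2
    zeta = 2.0 * dw * x
    root = np.sqrt(psi**2 + zeta**2)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
    eta_plus = tau_cp / np.sqrt(2.0) * np.sqrt(np.maximum(psi + root, 0.0))
    eta_minus = tau_cp / np.sqrt(2.0) * np.sqrt(np.maximum(-psi + root, 0.0))

    big = eta_plus > 30.0
    eta_safe = np.where(big, 0.0, eta_plus)
    arg = d_plus * np.cosh(eta_safe) - d_minus * np.cos(eta_minus)
    acosh_term = np.where(
        big,
        eta_plus + np.log(np.maximum(d_plus, 1e-300)),
        np.arccosh(np.maximum(arg, 1.0)),
    )
    r2 = 0.5 * (r2a + r2b + kex - acosh_term / tau_cp)
    return r2 if np.ndim(r2) else float(r2)


def simulate_cr(
    nu_cpmg,
    t_relax: float,
    field_mhz,
    dw_ppm,
    k_ex,
    p_b,
    r2_0,
    r2_0b=None,
):
    """Exact closed-form R2eff of the two-state CPMG experiment (fit kernel).

    Carver-Richards-type closed form with the mode amplitudes retained: the
    one-cycle propagator P = E(tau) conj(E(2tau)) E(tau) is written out with
    scalar 2x2 exponential algebra, its eigenvalues come from the quadratic
    formula (the determinant has the closed form
    exp(-(r2a + r2b + k_ex) / nu)), and the population-weighted initial
    magnetization is decomposed onto the eigenmodes, so

        signal(n) = c+ lam+^n + c- lam-^n,
        R2eff = -ln|signal| / t_relax.

    Keeping c+/c- is what lets the expression track the numerical
    propagation to numerical precision even at large minor populations,
    where the rate-only :func:`carver_richards_rate` is biased.  Broadcasts
    like :func:`simulate_bm`.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    shape = np.broadcast_shapes(
        nu.shape, np.shape(field_mhz), np.shape(dw_ppm), np.shape(k_ex),
        np.shape(p_b), np.shape(r2_0),
    )
    nu = np.broadcast_to(nu, shape).astype(float)
    fm = np.broadcast_to(np.asarray(field_mhz, dtype=float), shape)
    dwp = np.broadcast_to(np.asarray(dw_ppm, dtype=float), shape)
    kex = np.broadcast_to(np.asarray(k_ex, dtype=float), shape)
    pb = np.broadcast_to(np.asarray(p_b, dtype=float), shape)
    r2a = np.broadcast_to(np.asarray(r2_0, dtype=float), shape)
    r2b = r2a if r2_0b is None else np.broadcast_to(np.asarray(r2_0b, dtype=float), shape)

    n = cycle_count(nu, t_relax)
    tau = t_relax / (4.0 * n)
    pa = 1.0 - pb
    kab = pb * kex
    kba = pa * kex
    dom = nitrogen_omega(dwp, fm)

    a11 = -r2a - kab
    a12 = kba + np.zeros(shape)
    a21 = kab + np.zeros(shape)
    a22 = -r2b - kba - 1j * dom
    e_tau = _expm2(a11 * tau, a12 * tau, a21 * tau, a22 * tau)
    e_2tau = _expm2(a11 * 2 * tau, a12 * 2 * tau, a21 * 2 * tau, a22 * 2 * tau)
    p11, p12, p21, p22 = _matmul2(
        e_tau, _matmul2(tuple(np.conj(e) for e in e_2tau), e_tau)
    )

    tr = p11 + p22
    det = np.exp(-4.0 * tau * (r2a + r2b + kex))  # |det E|^2 in closed form
    disc = np.sqrt(tr * tr - 4.0 * det)
    lam_p = 0.5 * (tr + disc)
    lam_m = 0.5 * (tr - disc)

    # project M0 = (pa, pb) onto the eigenmodes, detected through v = (1, 1)
    s0a = p11 * pa + p12 * pb
    s0b = p21 * pa + p22 * pb
    v_pm0 = s0a + s0b                      # v . P M0
    v_m0 = pa + pb + 0j                    # v . M0 (= 1)
    degenerate = np.abs(disc) < 1e-13 * np.maximum(np.abs(tr), 1e-300)
    disc_safe = np.where(degenerate, 1.0, disc)
    c_p = (v_pm0 - lam_m * v_m0) / disc_safe
    c_m = (lam_p * v_m0 - v_pm0) / disc_safe

    signal = np.where(
        degenerate,
        # defective/degenerate propagator: P^n M0 -> lam^n M0 + n lam^(n-1) (P - lam I) M0
        np.abs(lam_p**n * v_m0 + n * lam_p ** (n - 1) * (v_pm0 - lam_p * v_m0)),
        np.abs(c_p * lam_p**n + c_m * lam_m**n),
    )
    r2 = -np.log(np.maximum(signal, 1e-300)) / t_relax
    return r2 if np.ndim(r2) else float(r2)


def fast_exchange_rex(dw_rad_s, k_ex, p_b):
    """Fast-exchange limit of the exchange contribution: pa pb dw^2 / kex."""
    return (1.0 - p_b) * p_b * np.asarray(dw_rad_s, dtype=float) ** 2 / k_ex


# ---------------------------------------------------------------------------
# dispersion statistics
# ---------------------------------------------------------------------------

def delta_r2(
    profile: pd.DataFrame, nu_low: float = 31.35, nu_high: float = 1000.0,
    rel_tol: float = 0.25,
) -> tuple[float, float]:
    """Dispersion amplitude: R2eff at the low minus at the high CPMG frequency.

    The points nearest to ``nu_low`` and ``nu_high`` are used provided they
    lie within ``rel_tol`` of the requested frequency; otherwise the endpoint
    is considered missing and an error is raised.  The error of the
    difference is the sum of the two point errors.

    ``profile`` is one residue/field frame with columns ``nu_cpmg_hz, r2eff,
    error`` (see :meth:`DispersionTable.profile`).
    """
    if profile.empty:
        raise ValueError("empty dispersion profile")
    nus = profile["nu_cpmg_hz"].to_numpy()
    picks = []
    for target in (nu_low, nu_high):
        i = int(np.argmin(np.abs(nus - target)))
        if abs(nus[i] - target) > rel_tol * target:
            raise ValueError(f"no dispersion point near {target} Hz")
        picks.append(i)
    lo, hi = picks
    dr2 = float(profile["r2eff"].iloc[lo] - profile["r2eff"].iloc[hi])
    err = float(profile["error"].iloc[lo] + profile["error"].iloc[hi])
    return dr2, err


def detect_dispersion(
    profile: pd.DataFrame, k: float = 3.0,
    nu_low: float = 31.35, nu_high: float = 1000.0,
) -> tuple[str, float]:
    """Flag a residue as dispersing when dR2 exceeds k times its pooled error.

    Returns (flag, score) with flag in {dispersing, flat, undetermined} and
    score = dR2 / pooled error.  Fewer than 5 points -> undetermined.
    """
    if len(profile) < 5:
        return "undetermined", np.nan
    dr2, err = delta_r2(profile, nu_low, nu_high)
    score = dr2 / err
    return ("dispersing" if dr2 > k * err else "flat"), score


# ---------------------------------------------------------------------------
# global two-state fit
# ---------------------------------------------------------------------------

#: multi-start screening grid over the shared exchange parameters
START_KEX = (100.0, 300.0, 600.0, 1000.0, 2000.0)
START_PB = (0.02, 0.05, 0.1, 0.2)


@dataclass
class ExchangeFitResult:
    """Global two-state dispersion fit: shared exchange parameters plus
    per-residue shift differences and per-residue-per-field baselines."""

    k_ex: float
    k_ex_error: float
    p_b: float
    p_b_error: float
    dw_ppm: pd.Series                  # index: residue_number
    dw_ppm_error: pd.Series
    r2_0: pd.DataFrame                 # columns residue_number, field_mhz, r2_0
    chi2: float
    n_data: int
    n_params: int
    residuals: pd.DataFrame = field(repr=False)
    diagnostics: dict = field(default_factory=dict)

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_data - self.n_params, 1)
        return self.chi2 / dof

    def derive_binding(
        self, a_total: float, b_total: float
    ) -> binding.BindingParameters:
        """K_D / k_on / k_off from the fitted p_b and the sample composition."""
        return binding.binding_parameters(self.p_b, a_total, b_total, k_ex=self.k_ex)

    def to_dict(self) -> dict:
        return {
            "k_ex_s": self.k_ex,
            "k_ex_error_s": self.k_ex_error,
            "p_b": self.p_b,
            "p_b_error": self.p_b_error,
            "p_b_percent": 100.0 * self.p_b,
            "chi2": self.chi2,
            "reduced_chi2": self.reduced_chi2,
            "dw_ppm": {int(k): float(v) for k, v in self.dw_ppm.items()},
            "r2_0": self.r2_0.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
        }


def _pack_model(data: pd.DataFrame):
    """Index the flat dispersion frame for vectorized model evaluation."""
    residues = np.sort(data["residue_number"].unique())
    res_idx = {r: i for i, r in enumerate(residues)}
    pairs = (
        data[["residue_number", "field_mhz"]]
        .drop_duplicates()
        .sort_values(["residue_number", "field_mhz"])
        .reset_index(drop=True)
    )
    pair_idx = {
        (int(r), float(f)): i
        for i, (r, f) in enumerate(zip(pairs["residue_number"], pairs["field_mhz"]))
    }
    row_res = data["residue_number"].map(res_idx).to_numpy()
    row_pair = np.array(
        [pair_idx[(int(r), float(f))] for r, f in
         zip(data["residue_number"], data["field_mhz"])]
    )
    return residues, pairs, row_res, row_pair


def global_fit(
    table: DispersionTable,
    init_strategy: str = "grid",
    seed: int | None = None,
    n_mc: int = 0,
    max_screen_nfev: int = 30,
) -> ExchangeFitResult:
    """Global weighted least-squares fit of all dispersion profiles.

    Shared parameters (k_ex, p_b); per-residue |dw| in ppm (field-independent);
    per-(residue, field) baseline r2_0.  Initialization: a (k_ex, p_b) grid
    of cheap bounded-iteration fits is screened and the best start (ties
    broken by smaller k_ex) is polished to convergence.  Uncertainties come
    from the covariance at the optimum; ``n_mc > 0`` adds Monte-Carlo
    resampling of the data from their errors (seeded).

    Raises when no start converges.  ``p_b`` at its bounds and
    single-residue/single-field degeneracy are reported in ``diagnostics``.
    """
    data = table.frame
    if data.empty:
        raise ValueError("empty dispersion table")
    t_relax = float(data["t_relax_s"].iloc[0])
    if not np.allclose(data["t_relax_s"], t_relax):
        raise ValueError("mixed constant-time delays are not supported")

    residues, pairs, row_res, row_pair = _pack_model(data)
    n_res, n_pair = len(residues), len(pairs)
    nu = data["nu_cpmg_hz"].to_numpy()
    fm = data["field_mhz"].to_numpy()
    y = data["r2eff"].to_numpy()
    err = data["error"].to_numpy()

    def model(theta):
        kex, pb = theta[0], theta[1]
        dw = theta[2 : 2 + n_res]
        r2_0 = theta[2 + n_res :]
        return simulate_cr(nu, t_relax, fm, dw[row_res], kex, pb, r2_0[row_pair])

    def resid(theta):
        return (y - model(theta)) / err

    # data-driven starting values for the per-residue/field parameters
    r2_init = np.empty(n_pair)
    dr2_by_res = np.zeros(n_res)
    for i, (r, f) in enumerate(zip(pairs["residue_number"], pairs["field_mhz"])):
        prof = data[(data["residue_number"] == r) & (data["field_mhz"] == f)]
        prof = prof.sort_values("nu_cpmg_hz")
        r2_init[i] = prof["r2eff"].iloc[-1]
        j = int(np.flatnonzero(residues == r)[0])
        dr2_by_res[j] = max(
            dr2_by_res[j], prof["r2eff"].iloc[0] - prof["r2eff"].iloc[-1]
        )
    r2_init = np.maximum(r2_init, 0.1)
    mean_field = float(np.mean(pairs["field_mhz"]))

    lb = np.concatenate(([1e-3, 1e-4], np.zeros(n_res), np.full(n_pair, 1e-3)))
    ub = np.concatenate(([1e6, 0.5 - 1e-6], np.full(n_res, 20.0), np.full(n_pair, 1e3)))

    if init_strategy == "grid":
        starts = [(k, p) for k in START_KEX for p in START_PB]
    else:
        raise ValueError(f"unknown init_strategy {init_strategy!r}")

    def theta0_for(kex0, pb0):
        rex = np.maximum(dr2_by_res, 0.1)
        dw_rad = np.sqrt(rex * kex0 / ((1 - pb0) * pb0))
        dw0 = dw_rad / (2 * np.pi * mean_field * GAMMA_RATIO_N_H)
        return np.concatenate(([kex0, pb0], np.clip(dw0, 0.01, 15.0), r2_init))

    screened = []
    for kex0, pb0 in starts:
        try:
            res = least_squares(
                resid, theta0_for(kex0, pb0), bounds=(lb, ub),
                max_nfev=max_screen_nfev, method="trf",
            )
            screened.append((2.0 * res.cost, kex0, res.x))
        except Exception:
            continue
    if not screened:
        raise RuntimeError("global dispersion fit failed from every start")
    screened.sort(key=lambda t: (t[0], t[1]))

    best = None
    for chi2_scr, _, x0 in screened[:2]:
        res = least_squares(resid, x0, bounds=(lb, ub), method="trf")
        if best is None or res.cost < best.cost:
            best = res
    chi2 = 2.0 * best.cost
    theta = best.x

    # covariance at the optimum (scaled by reduced chi2)
    n_data, n_params = len(y), len(theta)
    dof = max(n_data - n_params, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * (chi2 / dof)
        perr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        perr = np.full(n_params, np.nan)

    if n_mc > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_mc):
            yk = y + rng.normal(0.0, err)

            def resid_k(th, yk=yk):
                return (yk - model(th)) / err

            rk = least_squares(resid_k, theta, bounds=(lb, ub), method="trf",
                               max_nfev=100)
            draws.append(rk.x[:2])
        draws = np.array(draws)
        perr[0] = np.std(draws[:, 0], ddof=1)
        perr[1] = np.std(draws[:, 1], ddof=1)

    diagnostics = {
        "n_starts": len(starts),
        "best_start_chi2": screened[0][0],
        "pb_at_bound": bool(theta[1] <= lb[1] * 1.01 or theta[1] >= 0.5 - 1e-5),
        "degenerate": bool(n_res == 1 and len(table.fields_mhz) == 1),
        "converged": bool(best.success),
    }

    resid_frame = data[["residue_number", "field_mhz", "nu_cpmg_hz"]].copy()
    resid_frame["r2eff"] = y
    resid_frame["model"] = model(theta)
    resid_frame["weighted_residual"] = resid(theta)

    return ExchangeFitResult(
        k_ex=float(theta[0]),
        k_ex_error=float(perr[0]),
        p_b=float(theta[1]),
        p_b_error=float(perr[1]),
        dw_ppm=pd.Series(theta[2 : 2 + n_res], index=residues, name="dw_ppm"),
        dw_ppm_error=pd.Series(perr[2 : 2 + n_res], index=residues, name="dw_ppm_error"),
        r2_0=pd.DataFrame(
            {
                "residue_number": pairs["residue_number"],
                "field_mhz": pairs["field_mhz"],
                "r2_0": theta[2 + n_res :],
            }
        ),
        chi2=float(chi2),
        n_data=n_data,
        n_params=n_params,
        residuals=resid_frame,
        diagnostics=diagnostics,
    )
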