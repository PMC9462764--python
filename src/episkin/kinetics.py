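"""Per-cell subcellular chemistry of adhesion degradation.

This module implements the dimensionless mass-action system describing
competitive inhibition of a corneodesmosome-cleaving protease (enzyme ``e``)
by its inhibitor (``i``), regulated by the vertical pH gradient of the
stratum corneum:

* a cubic pH profile over normalised corneum height ``xi`` in [0, 1],
* pH-dependent enzyme-inhibitor association/dissociation rates,
* the six-species ODE system for (e, s, i, c_s, c_i, p),
* quasi-equilibrium initial conditions,
* time-rescaling of rate constants for the coarse multiscale clock,
* a single-migrating-cell solver, and
* utilities to estimate molar reactant concentrations from tissue data.

Species are dimensionless fractions: ``e``, ``c_s``, ``c_i`` are fractions
of the total enzyme pool ``e_T``; ``s``, ``i``, ``p`` are fractions of the
initial substrate concentration ``s_0``. Rate constants carry units of
M^-1 hr^-1 (association) or hr^-1 (first order); all times are hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PHModel",
    "RateConstants",
    "ChemParams",
    "ChemState",
    "ScalingSpec",
    "DEFAULT_PH_MODEL",
    "SINGLE_CELL_RATES",
    "LITERATURE_CHEM",
    "EFFECTIVE_CHEM",
    "ph_at",
    "klk_lekti_rates",
    "scale_rates",
    "initial_chem_state",
    "chem_rhs",
    "integrate_chem",
    "simulate_single_cell",
    "integrate_chem_batch",
    "batch_chem_rhs",
    "estimate_enzyme_concentration",
    "estimate_cnd_concentration",
]

SPECIES = ("e", "s", "i", "c_s", "c_i", "p")

# Minimum pH at which the linear association-rate law is still non-negative.
PH_FLOOR = 3.75


@dataclass(frozen=True)
class PHModel:
    """Cubic pH profile over normalised corneum height ``xi``.

    pH(xi) = c0 + c1*xi + c2*xi**2 + c3*xi**3, with xi clamped to [0, 1]
    (xi = 1 above the corneum, xi = 0 below its base). The default
    coefficients give a profile that decreases monotonically from ~6.85
    at the corneum base to ~4.48 at the skin surface.
    """

    c0: float = 6.8482
    c1: float = -0.3765
    c2: float = -5.1663
    c3: float = 3.1792

    def __call__(self, xi):
        xi = np.clip(xi, 0.0, 1.0)
        return self.c0 + xi * (self.c1 + xi * (self.c2 + xi * self.c3))


DEFAULT_PH_MODEL = PHModel()


def ph_at(xi, model: PHModel = DEFAULT_PH_MODEL):
    """Evaluate the pH profile at normalised height ``xi`` (clamped to [0, 1]).

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    arr = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("xi must be finite")
    out = model(arr)
    return float(out) if np.isscalar(xi) or arr.ndim == 0 else out


@dataclass(frozen=True)
class RateConstants:
    """Kinetic rate constants of the degradation/inhibition network.

    ``k_plus1`` (M^-1 hr^-1), ``k_minus1`` (hr^-1, approximated as 0) and
    ``k_2`` (hr^-1) govern the enzyme-substrate reaction; they satisfy the
    Michaelis relation K_M = (k_minus1 + k_2) / k_plus1.

    The enzyme-inhibitor rates are pH dependent:
        k_plus3(pH)  = (a3 * pH - b3) * 1e7   [M^-1 hr^-1], floored at 0
        k_minus3(pH) = A3 * exp(-B3 * pH)     [hr^-1]
    """

    k_plus1: float = 4.97e7
    k_minus1: float = 0.0
    k_2: float = 2.29e3
    K_M: float = 4.60e-5
    a3: float = 5.2
    b3: float = 19.5
    A3: float = 2.3e6
    B3: float = 3.0

    def __post_init__(self):
        if min(self.k_plus1, self.k_2, self.A3) < 0 or self.k_minus1 < 0:
            raise ValueError("rate constants must be non-negative")
        if self.k_plus1 == 0:
            if self.k_minus1 + self.k_2 != 0:
                raise ValueError("k_plus1 = 0 requires k_minus1 + k_2 = 0")
            return
        km = (self.k_minus1 + self.k_2) / self.k_plus1
        if abs(km - self.K_M) > 0.005 * max(self.K_M, 1e-300):
            raise ValueError(
                f"Michaelis relation violated: (k_minus1 + k_2)/k_plus1 = {km:.4g} "
                f"but K_M = {self.K_M:.4g} (must agree within 0.5%)"
            )

    def k_plus3(self, pH):
        return np.maximum((self.a3 * np.asarray(pH, dtype=float) - self.b3) * 1e7, 0.0)

    def k_minus3(self, pH):
        return self.A3 * np.exp(-self.B3 * np.asarray(pH, dtype=float))


SINGLE_CELL_RATES = RateConstants()


def klk_lekti_rates(pH, rates: RateConstants = SINGLE_CELL_RATES):
    """Enzyme-inhibitor association/dissociation rates at a given pH.

    Returns ``(k_plus3, k_minus3)``. The linear association law is floored
    at zero below its root (pH = b3/a3, 3.75 for the defaults); physiological
    heights never reach that regime.
    """
    arr = np.asarray(pH, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("pH must be finite")
    if np.any(arr < 3.0) or np.any(arr > 8.5):
        raise ValueError("pH outside supported range [3, 8.5]")
    kp3 = rates.k_plus3(arr)
    km3 = rates.k_minus3(arr)
    if np.isscalar(pH) or arr.ndim == 0:
        return float(kp3), float(km3)
    return kp3, km3


@dataclass(frozen=True)
class ScalingSpec:
    """Time rescaling between the single-cell and multiscale clocks.

    The multiscale tissue uses a compressed migration time
    T_hat = tau_T / v_z; rate constants are multiplied by
    lam = T_M / T_hat so a cell traverses the (thinner, faster) simulated
    corneum with the same chemistry it would accumulate over the full
    physiological migration time T_M.
    """

    T_M: float = 480.0  # physiological single-cell migration time (hr)
    tau_T: float = 8.0  # target corneum thickness (CD)
    v_z: float = 0.05  # expected vertical velocity (CD/hr)

    @property
    def T_hat(self) -> float:
        return self.tau_T / self.v_z

    @property
    def lam(self) -> float:
        return self.T_M / self.T_hat

    def __post_init__(self):
        if self.tau_T <= 0 or self.v_z <= 0 or self.T_M <= 0:
            raise ValueError("ScalingSpec fields must be positive")


def scale_rates(rates: RateConstants, spec: ScalingSpec = ScalingSpec()) -> RateConstants:
    """Rescale rate constants for the multiscale clock.

    Every rate constant (k_plus1, k_2, the a3/b3 pair and A3) is multiplied
    by lam = T_M / T_hat. The pH sensitivity B3 and the Michaelis constant
    K_M are invariant under this scaling.
    """
    lam = spec.lam
    if lam <= 0:
        raise ValueError("scaling factor must be positive")
    return replace(
        rates,
        k_plus1=rates.k_plus1 * lam,
        k_minus1=rates.k_minus1 * lam,
        k_2=rates.k_2 * lam,
        a3=rates.a3 * lam,
        b3=rates.b3 * lam,
        A3=rates.A3 * lam,
    )


MULTISCALE_RATES = scale_rates(SINGLE_CELL_RATES)


@dataclass(frozen=True)
class ChemParams:
    """Reactant pool sizes: initial substrate s_0, total enzyme e_T and
    total inhibitor i_T (all molar), with 0 <= i_T <= e_T."""

    s_0: float = 1.0e-5
    e_T: float = 1.0e-10
    i_T: float = 1.0e-10

    def __post_init__(self):
        if self.s_0 <= 0:
            raise ValueError("s_0 must be positive")
        if self.e_T < 0:
            raise ValueError("e_T must be non-negative")
        if not (0.0 <= self.i_T <= self.e_T or self.e_T == 0 and self.i_T == 0):
            raise ValueError("require 0 <= i_T <= e_T")

    @property
    def eps(self) -> float:
        """Enzyme-to-substrate pool ratio e_T / s_0."""
        return self.e_T / self.s_0

    @property
    def inhibitor_fraction(self) -> float:
        return self.i_T / self.e_T if self.e_T > 0 else 0.0


# Unreduced literature concentrations for the single-cell system. The total
# enzyme level is the value consistent with the quoted effective parameter
# k_plus1 * e_T = 49.7 hr^-1 (1.0 uM); the tissue-extract estimate of
# ~0.72 uM is available through estimate_enzyme_concentration().
LITERATURE_CHEM = ChemParams(s_0=1.0e-5, e_T=1.0e-6, i_T=1.0e-6)

# "Effective" pool sizes emulating diffusion-limited enzyme access.
EFFECTIVE_CHEM = ChemParams(s_0=1.0e-5, e_T=1.0e-10, i_T=1.0e-10)


@dataclass
class ChemState:
    """Dimensionless reactant state of one cell at time ``t`` (hr)."""

    e: float
    s: float
    i: float
    c_s: float
    c_i: float
    p: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.e, self.s, self.i, self.c_s, self.c_i, self.p])

    @classmethod
    def from_array(cls, y, t: float = 0.0) -> "ChemState":
        return cls(*(float(v) for v in y), t=t)

    def conservation_residuals(self, params: ChemParams) -> tuple[float, float, float]:
        """(enzyme, substrate, inhibitor) conservation residuals.

        enzyme:    e + c_s + c_i - 1
        substrate: s + (e_T/s_0) c_s + p - 1
        inhibitor: i + (e_T/s_0) c_i - i_T/s_0
        """
        eps = params.eps
        return (
            self.e + self.c_s + self.c_i - 1.0,
            self.s + eps * self.c_s + self.p - 1.0,
            self.i + eps * self.c_i - params.i_T / params.s_0,
        )

    def check(self, params: ChemParams, tol: float = 1e-6) -> None:
        """Validate conservation. The substrate residual is allowed an extra
        e_T/s_0: the quasi-equilibrium initial condition starts with part of
        the enzyme already complexed, shifting the conserved substrate total
        from 1 to 1 + (e_T/s_0) c_s(0)."""
        if params.e_T == 0:
            if max(abs(self.e), abs(self.c_s), abs(self.c_i)) > tol:
                raise ValueError("degenerate (e_T = 0) state must have zero enzyme species")
        else:
            r = self.conservation_residuals(params)
            if abs(r[0]) > tol or abs(r[2]) > tol or abs(r[1]) > tol + params.eps:
                raise ValueError(f"conservation violated: residuals {r}")
        if min(self.e, self.s, self.i, self.c_s, self.c_i, self.p) < -1e-9:
            raise ValueError("negative species fraction")


def initial_chem_state(params: ChemParams, rates: RateConstants) -> ChemState:
    """Quasi-equilibrium initial conditions on entry to the corneum.

    All inhibitor starts in complex (c_i = i_T/e_T); the remaining enzyme is
    split between free enzyme and substrate complex assuming the
    enzyme-substrate reaction is instantaneously at equilibrium with s = 1:

        e(0) = k_2 / (k_plus1 * s_0 + k_2) * (1 - i_T/e_T)

    which avoids the stiff initial transient of the free-enzyme start.
    """
    if params.e_T == 0:
        warnings.warn("e_T = 0: degenerate chemistry (no enzyme present)", stacklevel=2)
        return ChemState(e=0.0, s=1.0, i=0.0, c_s=0.0, c_i=0.0, p=0.0)
    f = params.i_T / params.e_T
    e0 = (rates.k_minus1 + rates.k_2) / (rates.k_plus1 * params.s_0 + rates.k_minus1 + rates.k_2) * (1.0 - f)
    return ChemState(e=e0, s=1.0, i=0.0, c_s=1.0 - e0 - f, c_i=f, p=0.0)


def _rate_coeffs(params: ChemParams, rates: RateConstants, pH):
    """Pre-multiplied coefficients (a, b, q, m, eps, k2eff) of the RHS."""
    kp3, km3 = rates.k_plus3(pH), rates.k_minus3(pH)
    return (
        rates.k_plus1 * params.s_0,
        rates.k_minus1 + rates.k_2,
        kp3 * params.s_0,
        km3,
        params.eps,
        rates.k_2,
    )


def chem_rhs(state: ChemState, params: ChemParams, rates: RateConstants, pH) -> np.ndarray:
    """Time derivatives (de, ds, di, dc_s, dc_i, dp) of the six species.

    The enzyme, substrate and inhibitor conservation sums of the returned
    vector are zero algebraically.
    """
    a, b, q, m, eps, k2 = _rate_coeffs(params, rates, pH)
    e, s, i, cs, ci, _ = state.as_array()
    de = -a * e * s + b * cs - q * e * i + m * ci
    ds = eps * (-a * e * s + rates.k_minus1 * cs)
    di = eps * (-q * e * i + m * ci)
    dcs = a * e * s - b * cs
    dci = q * e * i - m * ci
    dp = eps * k2 * cs
    return np.array([de, ds, di, dcs, dci, dp])


def _rhs_vec(y, a, b, q, m, eps, k2, km1):
    e, s, i, cs, ci = y[0], y[1], y[2], y[3], y[4]
    es = a * e * s
    ei = q * e * i
    return np.array([
        -es + b * cs - ei + m * ci,
        eps * (-es + km1 * cs),
        eps * (-ei + m * ci),
        es - b * cs,
        ei - m * ci,
        eps * k2 * cs,
    ])


def integrate_chem(
    state: ChemState,
    params: ChemParams,
    rates: RateConstants,
    pH,
    dt: float,
    rtol: float = 1e-4,
    atol: float = 1e-6,
) -> ChemState:
    """Advance one cell's chemistry by ``dt`` hours at fixed pH.

    Uses a stiff adaptive integrator. On failure the step is retried with
    the interval halved (twice); persistent failure raises with the cell's
    chemical context.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.e_T == 0:
        return replace(state, t=state.t + dt)
    coeff = _rate_coeffs(params, rates, pH)
    a, b, q, m, eps, k2 = coeff
    km1 = rates.k_minus1

    def f(_t, y):
        return _rhs_vec(y, a, b, q, m, eps, k2, km1)

    y = state.as_array()
    t0 = state.t
    for n_pieces in (1, 2, 4):
        h = dt / n_pieces
        yk = y.copy()
        ok = True
        for _ in range(n_pieces):
            sol = solve_ivp(f, (0.0, h), yk, method="LSODA", rtol=rtol, atol=atol)
            if not sol.success:
                ok = False
                break
            yk = sol.y[:, -1]
        if ok:
            return ChemState.from_array(np.maximum(yk, 0.0), t=t0 + dt)
    raise RuntimeError(
        f"chemistry integration failed for state {state} at pH {pH} over dt={dt}"
    )


def simulate_single_cell(
    v_xi: float,
    duration: float,
    params: ChemParams = LITERATURE_CHEM,
    rates: RateConstants = SINGLE_CELL_RATES,
    ph_model: PHModel = DEFAULT_PH_MODEL,
    sample_dt: float = 0.25,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Solve the chemistry of one cell migrating up the pH gradient.

    ``v_xi`` is the normalised vertical velocity in day^-1, so the cell's
    height follows xi(t) = min(v_xi * t / 24, 1) with t in hours. Returns a
    pandas DataFrame with columns t_hr, xi, pH, e, s, i, c_s, c_i, p sampled
    every ``sample_dt`` hours.
    """
    import pandas as pd

    if v_xi < 0:
        raise ValueError("v_xi must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    v_hr = v_xi / 24.0
    state0 = initial_chem_state(params, rates) if params.e_T > 0 else ChemState(0, 1, 0, 0, 0, 0)
    eps, km1, k2 = params.eps, rates.k_minus1, rates.k_2
    a = rates.k_plus1 * params.s_0
    b = rates.k_minus1 + rates.k_2

    def f(t, y):
        pH = ph_model(min(v_hr * t, 1.0))
        q = max((rates.a3 * pH - rates.b3) * 1e7, 0.0) * params.s_0
        m = rates.A3 * math.exp(-rates.B3 * pH)
        return _rhs_vec(y, a, b, q, m, eps, k2, km1)

    t_eval = np.arange(0.0, duration + 1e-9, sample_dt)
    if t_eval[-1] < duration:
        t_eval = np.append(t_eval, duration)
    sol = solve_ivp(
        f, (0.0, duration), state0.as_array(),
        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"single-cell integration failed: {sol.message}")
    xi = np.minimum(v_hr * sol.t, 1.0)
    df = pd.DataFrame({
        "t_hr": sol.t,
        "xi": xi,
        "pH": ph_model(xi),
        "e": sol.y[0], "s": sol.y[1], "i": sol.y[2],
        "c_s": sol.y[3], "c_i": sol.y[4], "p": sol.y[5],
    })
    return df


# ---------------------------------------------------------------------------
# Batched integration for the tissue model
# ---------------------------------------------------------------------------

def batch_chem_rhs(Y, a, b, q, m, eps, k2, km1):
    """Vectorised RHS for ``Y`` of shape (n, 6); ``q`` and ``m`` may vary
    per cell (the per-cell pH enters through them)."""
    e, s, i, cs, ci = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3], Y[:, 4]
    es = a * e * s
    ei = q * e * i
    out = np.empty_like(Y)
    out[:, 0] = -es + b * cs - ei + m * ci
    out[:, 1] = eps * (-es + km1 * cs)
    out[:, 2] = eps * (-ei + m * ci)
    out[:, 3] = es - b * cs
    out[:, 4] = ei - m * ci
    out[:, 5] = eps * k2 * cs
    return out


def _batch_jacobian(Y, a, b, q, m, eps, k2, km1):
    """Analytic Jacobians, shape (n, 6, 6)."""
    n = Y.shape[0]
    e, s, i = Y[:, 0], Y[:, 1], Y[:, 2]
    q = np.broadcast_to(q, (n,))
    m = np.broadcast_to(m, (n,))
    J = np.zeros((n, 6, 6))
    ae, as_, qe, qi = a * e, a * s, q * e, q * i
    # de
    J[:, 0, 0] = -as_ - qi
    J[:, 0, 1] = -ae
    J[:, 0, 2] = -qe
    J[:, 0, 3] = b
    J[:, 0, 4] = m
    # ds
    J[:, 1, 0] = -eps * as_
    J[:, 1, 1] = -eps * ae
    J[:, 1, 3] = eps * km1
    # di
    J[:, 2, 0] = -eps * qi
    J[:, 2, 2] = -eps * qe
    J[:, 2, 4] = eps * m
    # dc_s
    J[:, 3, 0] = as_
    J[:, 3, 1] = ae
    J[:, 3, 3] = -b
    # dc_i
    J[:, 4, 0] = qi
    J[:, 4, 2] = qe
    J[:, 4, 4] = -m
    # dp
    J[:, 5, 3] = eps * k2
    return J


def integrate_chem_batch(
    Y: np.ndarray,
    params: ChemParams,
    rates: RateConstants,
    pH: np.ndarray,
    dt: float,
    n_sub: int = 2,
    newton_tol: float = 1e-8,
    max_newton: int = 8,
) -> np.ndarray:
    """Advance many cells' chemistry by ``dt`` with an L-stable implicit step.

    Backward-Euler with analytic-Jacobian Newton iteration, vectorised over
    cells; ``pH`` is a per-cell array held fixed over the step. The linear
    conservation sums are preserved exactly by the implicit step (up to the
    Newton tolerance). Substeps are doubled on Newton failure.

    Returns the updated array (a new array; the input is not modified).
    """
    if Y.size == 0:
        return Y.copy()
    if params.e_T == 0:
        return Y.copy()
    a = rates.k_plus1 * params.s_0
    b = rates.k_minus1 + rates.k_2
    kp3, km3 = rates.k_plus3(pH), rates.k_minus3(pH)
    q = kp3 * params.s_0
    m = km3
    eps, k2, km1 = params.eps, rates.k_2, rates.k_minus1
    eye = np.eye(6)

    for attempt in range(4):
        nsub = n_sub * (2 ** attempt)
        h = dt / nsub
        Yk = Y.copy()
        failed = False
        for _ in range(nsub):
            Yn = Yk
            Ynew = Yn + h * batch_chem_rhs(Yn, a, b, q, m, eps, k2, km1)  # explicit predictor
            converged = False
            for _ in range(max_newton):
                F = Ynew - Yn - h * batch_chem_rhs(Ynew, a, b, q, m, eps, k2, km1)
                J = eye[None, :, :] - h * _batch_jacobian(Ynew, a, b, q, m, eps, k2, km1)
                try:
                    delta = np.linalg.solve(J, F[:, :, None])[:, :, 0]
                except np.linalg.LinAlgError:
                    failed = True
                    break
                Ynew = Ynew - delta
                if np.max(np.abs(delta)) < newton_tol:
                    converged = True
                    break
            if failed or not converged:
                failed = True
                break
            Yk = Ynew
        if not failed:
            return np.maximum(Yk, 0.0)
    raise RuntimeError("batched chemistry integration failed to converge")


# ---------------------------------------------------------------------------
# Concentration estimation from tissue measurements
# ---------------------------------------------------------------------------

AVOGADRO = 6.02214076e23


def estimate_enzyme_concentration(
    dry_weight: float,
    mw: float,
    water_content: float,
    extracellular_fraction: float,
) -> float:
    """Molar enzyme concentration in extracellular corneum water.

    Parameters
    ----------
    dry_weight : enzyme mass per dry tissue mass (ng per mg dry tissue).
    mw : molecular weight (kDa).
    water_content : water mass per gram of *wet* tissue (g/g), so 0.5
        means equal water and dry masses.
    extracellular_fraction : fraction of tissue water that is extracellular.

    The enzyme (moles per mg dry tissue) is divided by the extracellular
    water volume per mg dry tissue, taking water density as 1 g/mL.
    """
    if min(dry_weight, mw, water_content) <= 0:
        raise ValueError("dry_weight, mw and water_content must be positive")
    if not 0.0 < extracellular_fraction <= 1.0:
        raise ValueError("extracellular_fraction must be in (0, 1]")
    if water_content >= 1.0:
        raise ValueError("water_content must be < 1 g per g wet tissue")
    moles_per_mg_dry = dry_weight * 1e-9 / (mw * 1e3)
    water_g_per_mg_dry = water_content / (1.0 - water_content) * 1e-3
    extracellular_litres = water_g_per_mg_dry * extracellular_fraction * 1e-3
    return moles_per_mg_dry / extracellular_litres


def estimate_cnd_concentration(
    peripheral_density: float,
    central_density: float,
    cell_width: float,
    cell_height: float,
    gap: float,
) -> float:
    """Molar adhesion-protein concentration in the extracellular gap.

    The cell is treated as a square slab (cell_width x cell_width x
    cell_height, um) carrying ``central_density`` proteins/um^2 on its top
    and bottom faces and ``peripheral_density`` proteins/um^2 on its side
    faces, each face sharing half the ``gap`` (um) with its neighbour. The
    concentration is the total protein count over the half-gap extracellular
    volume around the cell.

    Note: this first-principles geometry does not reproduce the published
    ~6.6 uM estimate; the default substrate pool s_0 is therefore a
    configuration constant rather than this function's output.
    """
    if min(peripheral_density, central_density) < 0:
        raise ValueError("densities must be non-negative")
    if min(cell_width, cell_height) <= 0:
        raise ValueError("cell dimensions must be positive")
    if gap <= 0:
        raise ValueError("gap must be positive")
    central_area = 2.0 * cell_width**2
    peripheral_area = 4.0 * cell_width * cell_height
    count = central_density * central_area + peripheral_density * peripheral_area
    volume_um3 = (central_area + peripheral_area) * (gap / 2.0)
    volume_litres = volume_um3 * 1e-15
    return count / (AVOGADRO * volume_litres)
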