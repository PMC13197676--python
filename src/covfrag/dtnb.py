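"""DTNB (Ellman's reagent) thiol-reactivity kinetics.

TNB²⁻, generated in situ by TCEP reduction of DTNB (each DTNB yields two
TNB²⁻), serves as a cysteine surrogate. Its 412 nm absorbance is read
every 5 min for 4 h; electrophile consumption of TNB²⁻ bleaches the
signal. The analysis is self-calibrating: the molar response
``epsilon_path`` (extinction coefficient times pathlength, AU/M) comes
from the first-time-point absorbance of a fragment-free well at the known
TNB²⁻ starting concentration.

With fragment A and TNB²⁻ B (``A0 != B0``), the integrated second-order
rate law is::

    A(t) = A0 (A0 - B0) e^((A0-B0) k2 t) / (A0 e^((A0-B0) k2 t) - B0)

degenerating to ``A(t) = A0 / (1 + A0 k2 t)`` as ``A0 -> B0``. The fit
leaves k2 unbounded: baseline drift in the compound-background wells can
produce small negative apparent rate constants, which are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "PlateKineticRun",
    "CalibratedRun",
    "SecondOrderFit",
    "CalibrationError",
    "tnb_from_dtnb",
    "calibrate_epsilon",
    "correct_and_convert",
    "second_order_model",
    "second_order_ode",
    "fit_second_order",
    "aggregate_replicates",
]

#: |A0 - B0| below this (molar) uses the equal-concentration branch.
EQUAL_CONC_TOL = 1e-9


class CalibrationError(ValueError):
    """Raised when the fragment-free calibration well is unusable."""


def tnb_from_dtnb(dtnb_conc: float) -> float:
    """TNB²⁻ concentration obtained by full reduction of DTNB.

    DTNB is a disulfide-linked dimer, so 25 µM DTNB yields 50 µM TNB²⁻.
    """
    return 2.0 * dtnb_conc


@dataclass(frozen=True)
class PlateKineticRun:
    """One compound's plate-reader time series (per-replicate columns).

    ``a412_reaction`` and ``a412_compound_background`` are shaped
    (n_replicates, n_times); the background wells contain compound but no
    DTNB and capture intrinsic compound absorbance at 412 nm.
    """

    times: np.ndarray  # seconds, strictly increasing from 0
    a412_reaction: np.ndarray
    a412_compound_background: np.ndarray
    a412_blank: np.ndarray  # fragment-free well, (n_times,)
    nominal_A0: float = 100e-6  # molar fragment
    nominal_B0: float = 50e-6  # molar TNB2-

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing from 0")
        rxn = np.atleast_2d(np.asarray(self.a412_reaction, dtype=float))
        bg = np.atleast_2d(np.asarray(self.a412_compound_background, dtype=float))
        if rxn.shape != bg.shape or rxn.shape[1] != t.size:
            raise ValueError("reaction/background shapes must match the time grid")
        if self.nominal_A0 <= 0 or self.nominal_B0 <= 0:
            raise ValueError("nominal concentrations must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a412_reaction", rxn)
        object.__setattr__(self, "a412_compound_background", bg)
        object.__setattr__(self, "a412_blank", np.asarray(self.a412_blank, dtype=float))


@dataclass(frozen=True)
class CalibratedRun:
    """Concentration-space view of a run (one replicate)."""

    times: np.ndarray  # seconds
    A_t: np.ndarray  # molar fragment remaining
    B_t: np.ndarray  # molar TNB2- remaining
    A0_effective: float
    B0_effective: float
    epsilon_path: float
    flagged: bool = False  # A_t dipped below -5% of A0


@dataclass(frozen=True)
class SecondOrderFit:
    k2: float  # M^-1 s^-1; negative values reported raw
    k2_sd: float
    converged: bool
    residual_rms: float  # molar
    n_replicates: int = 1


def calibrate_epsilon(run: PlateKineticRun) -> float:
    """Lumped molar response (AU/M) from the fragment-free well at t=0."""
    a0 = float(run.a412_blank[0])
    if a0 <= 0:
        raise CalibrationError("first-point blank absorbance must be positive")
    return a0 / run.nominal_B0


def correct_and_convert(run: PlateKineticRun, epsilon_path: float) -> list[CalibratedRun]:
    """Background-subtract and convert each replicate to concentrations.

    ``B_t`` is the corrected absorbance over the molar response, clipped
    at zero. The effective TNB²⁻ start is the converted value at the
    first time point; the effective fragment start adjusts the nominal
    load for any TNB²⁻ already consumed before the first read. Mass
    balance ``A0 - A(t) = B0 - B(t)`` then holds by construction.
    """
    out = []
    for rxn, bg in zip(run.a412_reaction, run.a412_compound_background):
        B_t = np.clip((rxn - bg) / epsilon_path, 0.0, None)
        B0_eff = float(B_t[0])
        A0_eff = run.nominal_A0 - (run.nominal_B0 - B0_eff)
        A_t = A0_eff - (B0_eff - B_t)
        flagged = bool(np.any(A_t < -0.05 * run.nominal_A0))
        out.append(
            CalibratedRun(
                times=run.times,
                A_t=A_t,
                B_t=B_t,
                A0_effective=A0_eff,
                B0_effective=B0_eff,
                epsilon_path=epsilon_path,
                flagged=flagged,
            )
        )
    return out


def second_order_model(A0, B0, k2, t):
    """Closed-form fragment concentration under mixed second-order kinetics.

    Evaluated in a numerically stable rearrangement: for ``d = A0 - B0``
    and ``x = d k2 t >= 0`` the expression is computed as
    ``A0 d / (A0 - B0 e^(-x))`` so the exponential never overflows; the
    mirrored form is used for ``x < 0``. ``|d| < 1e-9`` M switches to the
    equal-concentration closed form ``A0 / (1 + A0 k2 t)``.
    """
    t = np.asarray(t, dtype=float)
    d = A0 - B0
    if abs(d) < EQUAL_CONC_TOL:
        return A0 / (1.0 + A0 * k2 * t)
    x = d * k2 * t
    return np.where(
        x >= 0,
        A0 * d / (A0 - B0 * np.exp(np.clip(-x, -700, 0))),
        A0 * d * np.exp(np.clip(x, -700, 0))
        / (A0 * np.exp(np.clip(x, -700, 0)) - B0),
    )


def second_order_ode(A0, B0, k2, t):
    """Numerical integration of dA/dt = -k2 A B (independent reference)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))

    def rhs(_, y):
        a = y[0]
        b = B0 - (A0 - a)
        return [-k2 * a * b]

    if t[-1] == 0:
        return np.full_like(t, A0)
    sol = solve_ivp(
        rhs, (0.0, float(t[-1])), [A0], t_eval=t, rtol=1e-10, atol=1e-16,
        method="LSODA",
    )
    return sol.y[0]


def _initial_k2(run: CalibratedRun) -> float:
    """Two-point early-slope estimate ΔB / (A0 B0 Δt)."""
    dB = run.B_t[0] - run.B_t[1]
    dt = run.times[1] - run.times[0]
    denom = run.A0_effective * run.B0_effective * dt
    if denom <= 0:
        return 1e-3
    k0 = dB / denom
    return k0 if np.isfinite(k0) and k0 != 0 else 1e-3


def fit_second_order(calibrated: CalibratedRun) -> SecondOrderFit:
    """Nonlinear least-squares fit of k2 to the fragment decay.

    A0 and B0 are fixed at the run's effective values; only k2 floats,
    without bounds, so drift-induced negative rates remain representable.
    """
    if calibrated.times.size < 5:
        raise ValueError("need at least 5 time points")
    A0, B0 = calibrated.A0_effective, calibrated.B0_effective

    def model(t, k2):
        return second_order_model(A0, B0, k2, t)

    try:
        popt, pcov = curve_fit(
            model,
            calibrated.times,
            calibrated.A_t,
            p0=[_initial_k2(calibrated)],
            maxfev=10000,
        )
    except RuntimeError:
        return SecondOrderFit(np.nan, np.nan, converged=False, residual_rms=np.nan)
    k2 = float(popt[0])
    k2_sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    resid = calibrated.A_t - model(calibrated.times, k2)
    return SecondOrderFit(
        k2=k2,
        k2_sd=k2_sd,
        converged=True,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def aggregate_replicates(fits: list[SecondOrderFit]) -> SecondOrderFit:
    """Average converged replicate fits with propagated uncertainty.

    k2 is the plain mean; its SD is ``sqrt(sum sd_i^2)/n`` — the
    propagation of independent per-replicate uncertainties through the
    mean.
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged replicate fits to aggregate")
    n = len(good)
    k2 = float(np.mean([f.k2 for f in good]))
    k2_sd = float(np.sqrt(np.sum([f.k2_sd**2 for f in good])) / n)
    rms = float(np.mean([f.residual_rms for f in good]))
    return SecondOrderFit(k2=k2, k2_sd=k2_sd, converged=True, residual_rms=rms, n_replicates=n)
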