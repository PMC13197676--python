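"""Glutathione / PBS stability kinetics from HPLC peak areas.

Fragments (250 µM) are incubated with a 5 mM GSH excess (or plain PBS as
hydrolysis control) and sampled by HPLC-UV; the fragment peak area is
normalised to a co-injected internal standard (ketoprofen/ibuprofen) and
to the time-zero ratio, giving a relative AUC that decays as::

    r(t) = e^(-k t)                (pseudo-first-order)
    r(t) = (1 - c) e^(-k t) + c    (reversible/plateau variant)

with ``t_half = ln 2 / k``. The plateau variant covers compounds whose
relative AUC levels off well above zero (consistent with a reversible
thia-Michael adduct); the amplitude is tied to ``1 - c`` so that
``r(0) = 1`` holds for any plateau.

Compounds too fast for the sampling schedule are censored rather than
fitted: no detectable peak at time zero reports "<< 0.033 h", detectable
at zero but gone by the 20-minute sample reports "<< 0.33 h". Non-decaying
or unquantifiably slow series report "> 100 h". GSH rate constants are
deliberately *not* corrected for the parallel buffer-only degradation; the
PBS half-life is reported alongside instead, and a PBS half-life shorter
than the GSH one flags intrinsic buffer instability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Censoring",
    "AucSeries",
    "PseudoFirstFit",
    "StabilityVerdict",
    "UndetectableAtStart",
    "relative_auc",
    "fit_pseudo_first",
    "censor_short",
    "halflife",
    "flag_buffer_instability",
    "aggregate_fits",
]

LN2 = float(np.log(2.0))

#: Relative AUC below this (or a missing peak) counts as undetectable.
DEFAULT_DETECTION_LIMIT = 0.01

#: Fitted half-lives above this bound are censored to "> 100 h".
T_HALF_UPPER_NUMERIC = 1000.0


class Censoring(str, enum.Enum):
    NONE = "none"
    BELOW_0P033 = "below_0p033"  # "<< 0.033 h": gone before the first sample
    BELOW_0P33 = "below_0p33"  # "<< 0.33 h": gone by the 20-min sample
    ABOVE_100 = "above_100"  # "> 100 h": no quantifiable decay

    @property
    def display(self) -> str:
        return {
            Censoring.NONE: "",
            Censoring.BELOW_0P033: "<< 0.033 h",
            Censoring.BELOW_0P33: "<< 0.33 h",
            Censoring.ABOVE_100: "> 100 h",
        }[self]


class UndetectableAtStart(ValueError):
    """Fragment peak absent at t=0; only a censoring token can be emitted."""


@dataclass(frozen=True)
class AucSeries:
    """Raw HPLC peak-area time series for one compound/condition."""

    times: np.ndarray  # hours, increasing from 0
    fragment_auc: np.ndarray  # NaN = missing peak
    standard_auc: np.ndarray
    condition: str = "GSH"  # GSH or PBS
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fragment_auc, dtype=float)
        s = np.asarray(self.standard_auc, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be increasing from 0")
        if not (t.size == f.size == s.size):
            raise ValueError("times, fragment and standard series must align")
        if np.any(~np.isnan(s) & (s <= 0)):
            raise ValueError("standard_auc must be positive wherever present")
        if self.condition not in ("GSH", "PBS"):
            raise ValueError("condition must be GSH or PBS")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fragment_auc", f)
        object.__setattr__(self, "standard_auc", s)


@dataclass(frozen=True)
class PseudoFirstFit:
    k: float  # h^-1
    k_sd: float
    plateau_c: float  # 0 for the simple model
    t_half: float  # hours; NaN when censored
    censoring: Censoring
    model: str  # simple or plateau

    @property
    def t_half_display(self) -> str:
        if self.censoring is not Censoring.NONE:
            return self.censoring.display
        return f"{self.t_half:.3g} h"


@dataclass(frozen=True)
class StabilityVerdict:
    id: str
    t_half_gsh: float | Censoring
    t_half_pbs: float | Censoring
    buffer_unstable: bool


def _detectable(series: AucSeries, idx: int, baseline_ratio: float | None) -> bool:
    f, s = series.fragment_auc[idx], series.standard_auc[idx]
    if np.isnan(f) or np.isnan(s) or f <= 0:
        return False
    if baseline_ratio is None:  # t=0: any real peak counts
        return True
    return (f / s) / baseline_ratio >= series.detection_limit


def censor_short(series: AucSeries) -> Censoring:
    """Schedule-based censoring for fragments faster than the sampling.

    Missing/zero fragment peak at t=0 -> BELOW_0P033. A fragment present
    at t=0 but below the detection limit at the first post-zero sample is
    faster than the schedule resolves: absence at time u with relative
    detection limit d bounds the half-life by ln2·u/ln(1/d), and the
    "<< 0.33 h" token is emitted whenever that bound is at most 0.33 h
    (for the canonical 20-min sample at d = 0.01 the bound is 0.05 h).
    """
    if not _detectable(series, 0, None):
        return Censoring.BELOW_0P033
    if series.times.size < 2 or not 0 < series.detection_limit < 1:
        return Censoring.NONE
    baseline = series.fragment_auc[0] / series.standard_auc[0]
    u = series.times[1]
    implied_bound = LN2 * u / np.log(1.0 / series.detection_limit)
    if not _detectable(series, 1, baseline) and implied_bound <= 0.33:
        return Censoring.BELOW_0P33
    return Censoring.NONE


def relative_auc(series: AucSeries) -> np.ndarray:
    """Internal-standard-normalised AUC relative to time zero.

    ``r(t) = (fragment/standard)(t) / (fragment/standard)(0)``; the ratio
    cancels injection-to-injection drift of the chromatograph, and the
    time-zero normalisation forces ``r(0) = 1``.
    """
    if not _detectable(series, 0, None):
        raise UndetectableAtStart(
            "fragment undetectable at t=0; use censor_short for the token"
        )
    ratio = series.fragment_auc / series.standard_auc
    return ratio / ratio[0]


def _censor_slow(k: float, k_sd: float) -> bool:
    if k <= 0:
        return True
    if LN2 / k > T_HALF_UPPER_NUMERIC:
        return True
    if np.isfinite(k_sd) and k_sd / abs(k) > 1.0:
        return True
    return False


def fit_pseudo_first(
    times: np.ndarray, r: np.ndarray, model: str = "simple"
) -> PseudoFirstFit:
    """Fit the pseudo-first-order decay (optionally with a plateau).

    Slow/non-decaying series (k <= 0, fitted half-life above 1000 h, or
    relative standard error of k above 100%) are censored to "> 100 h"
    rather than reported numerically.
    """
    times = np.asarray(times, dtype=float)
    r = np.asarray(r, dtype=float)
    keep = np.isfinite(r)
    times, r = times[keep], r[keep]
    if times.size < 4:
        raise ValueError("need at least 4 points")

    if model == "simple":

        def f(t, k):
            return np.exp(-k * t)

        p0, bounds = [0.1], (-np.inf, np.inf)
    elif model == "plateau":

        def f(t, k, c):
            return (1.0 - c) * np.exp(-k * t) + c

        p0, bounds = [1.0, 0.3], ([-np.inf, 0.0], [np.inf, 1.0 - 1e-9])
    else:
        raise ValueError("model must be 'simple' or 'plateau'")

    try:
        popt, pcov = curve_fit(f, times, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        return PseudoFirstFit(np.nan, np.nan, 0.0, np.nan, Censoring.ABOVE_100, model)
    k = float(popt[0])
    k_sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    c = float(popt[1]) if model == "plateau" else 0.0
    if _censor_slow(k, k_sd):
        return PseudoFirstFit(k, k_sd, c, np.nan, Censoring.ABOVE_100, model)
    return PseudoFirstFit(k, k_sd, c, LN2 / k, Censoring.NONE, model)


def choose_model(times: np.ndarray, r: np.ndarray) -> str:
    """Auto model selection: plateau when the tail levels off above 0.2.

    Uses the last quarter of the series; "flat" means the tail slope is
    small relative to the overall decay.
    """
    times = np.asarray(times, dtype=float)
    r = np.asarray(r, dtype=float)
    if times.size < 4:
        return "simple"
    n_tail = max(3, times.size // 4)
    tail_t, tail_r = times[-n_tail:], r[-n_tail:]
    if np.mean(tail_r) <= 0.2:
        return "simple"
    slope = np.polyfit(tail_t, tail_r, 1)[0]
    span = times[-1] - times[0]
    if abs(slope) * span < 0.1 and np.mean(tail_r) < 0.9:
        return "plateau"
    return "simple"


def analyze_series(series: AucSeries, model: str = "auto") -> PseudoFirstFit:
    """Censor-aware entry point: censor fast compounds, else fit."""
    token = censor_short(series)
    if token is not Censoring.NONE:
        return PseudoFirstFit(np.nan, np.nan, 0.0, np.nan, token, "simple")
    r = relative_auc(series)
    if model == "auto":
        keep = np.isfinite(r)
        model = choose_model(series.times[keep], r[keep])
    return fit_pseudo_first(series.times, r, model)


def halflife(k: float) -> float | Censoring:
    """t_half = ln2/k for a decaying compound, else the slow-censor token."""
    if not np.isfinite(k) or k <= 0:
        return Censoring.ABOVE_100
    t = LN2 / k
    return t if t <= T_HALF_UPPER_NUMERIC else Censoring.ABOVE_100


def _bound(value: float | Censoring) -> float:
    """Comparable numeric bound for a (possibly censored) half-life."""
    if isinstance(value, Censoring):
        return {
            Censoring.BELOW_0P033: 0.033,
            Censoring.BELOW_0P33: 0.33,
            Censoring.ABOVE_100: np.inf,
            Censoring.NONE: np.nan,
        }[value]
    return float(value)


def flag_buffer_instability(
    gsh: PseudoFirstFit | float | Censoring,
    pbs: PseudoFirstFit | float | Censoring,
    id: str = "",
) -> StabilityVerdict:
    """Flag compounds degrading faster in plain buffer than with GSH.

    A strictly shorter PBS half-life indicates hydrolysis (or
    precipitation) rather than thiol reaction; censored values compare by
    their bounds, with "> 100 h" treated as +infinity.
    """

    def value(x):
        if isinstance(x, PseudoFirstFit):
            return x.censoring if x.censoring is not Censoring.NONE else x.t_half
        return x

    g, p = value(gsh), value(pbs)
    unstable = _bound(p) < _bound(g)
    return StabilityVerdict(id=id, t_half_gsh=g, t_half_pbs=p, buffer_unstable=bool(unstable))


def aggregate_fits(fits: list[PseudoFirstFit]) -> PseudoFirstFit:
    """Average uncensored replicate fits (mean k, quadrature SD over n)."""
    good = [f for f in fits if f.censoring is Censoring.NONE]
    if not good:
        tokens = [f.censoring for f in fits]
        return PseudoFirstFit(np.nan, np.nan, 0.0, np.nan, tokens[0], fits[0].model)
    n = len(good)
    k = float(np.mean([f.k for f in good]))
    k_sd = float(np.sqrt(np.sum([f.k_sd**2 for f in good])) / n)
    c = float(np.mean([f.plateau_c for f in good]))
    model = good[0].model
    if k <= 0:
        return PseudoFirstFit(k, k_sd, c, np.nan, Censoring.ABOVE_100, model)
    return PseudoFirstFit(k, k_sd, c, LN2 / k, Censoring.NONE, model)
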