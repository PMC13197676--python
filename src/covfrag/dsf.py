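"""Differential scanning fluorimetry (DSF) thermal-shift analysis.

A dye-reported melting curve F(T) is scanned from ~28 °C upward; the
melting temperature Tm is the temperature of the maximum of the first
derivative dF/dT. The derivative is estimated by local quadratic
(Savitzky–Golay) smoothing over a ~2 °C window, and a 1.5 °C edge band is
excluded from the argmax so baseline curvature at the scan limits cannot
masquerade as a transition. The discrete peak is refined by parabolic
interpolation, giving sub-grid Tm resolution.

Thermal shifts are ΔTm = Tm(protein+compound) − Tm(protein alone), with
replicate SDs combined in quadrature. The primary screen calls a hit when
any tested condition shifts by strictly more than 1 °C; dose/time
summaries use ΔTm ≥ 1 °C as the threshold for "stabilizing", as tabulated.

Specificity against the p53-Y220C target uses three constructs: the
Y220C mutant itself, its cysteine-light (CL) variant in which surface
cysteines other than Cys220 are mutated to serine, and the
pseudo-wild-type core domain lacking Cys220. A Cys220-specific binder
stabilizes both Y220C constructs but not the wild type; a Y220C shift
well above the CL shift indicates additional non-specific surface
arylation; stabilization seen only in the CL variant with wild-type
destabilization indicates a Cys220 effect masked by off-target arylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "MeltCurve",
    "MeltResult",
    "ScreenRow",
    "SpecificityCall",
    "NoTransitionError",
    "compute_tm",
    "delta_tm",
    "call_hit",
    "dose_time_summary",
    "classify_specificity",
    "aggregate_tm",
]

CONSTRUCTS = ("T-p53C", "T-p53C-Y220C", "T-p53C-Y220C-CL")

#: Hit threshold (°C): strictly greater in the primary screen,
#: greater-or-equal in dose/time summaries.
HIT_THRESHOLD = 1.0
#: |shift| below this counts as "minimal" in the specificity logic.
MINIMAL_SHIFT = 0.5
#: Shift at or below this counts as destabilizing.
DESTABILIZING = -1.0

SMOOTH_WINDOW_C = 2.0  # local-quadratic smoothing window, °C
EDGE_EXCLUSION_C = 1.5  # band excluded from the argmax at each scan edge


class NoTransitionError(ValueError):
    """Raised when a melt curve shows no resolvable unfolding transition."""


@dataclass(frozen=True)
class MeltCurve:
    temperatures: np.ndarray  # °C, strictly increasing
    fluorescence: np.ndarray
    construct: str = "T-p53C-Y220C"
    compound_id: str | None = None
    concentration: float = 0.0  # µM
    incubation: float = 0.0  # hours

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        F = np.asarray(self.fluorescence, dtype=float)
        if T.size != F.size:
            raise ValueError("temperature and fluorescence grids must align")
        if T.size < 20:
            raise ValueError("need at least 20 points across the transition")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "fluorescence", F)


@dataclass(frozen=True)
class MeltResult:
    tm: float  # °C
    tm_sd: float = 0.0
    delta_tm: float = np.nan
    delta_tm_sd: float = np.nan


@dataclass(frozen=True)
class ScreenRow:
    compound_id: str
    hit: bool
    min_stabilizing_conc: float | None  # µM
    first_stabilizing_time: float | None  # hours
    destabilizing_at_high_conc: bool


@dataclass(frozen=True)
class SpecificityCall:
    compound_id: str
    dt_y220c: float
    dt_cl: float
    dt_wt: float
    label: str


def _smoothed_derivative(curve: MeltCurve) -> tuple[np.ndarray, np.ndarray]:
    T, F = curve.temperatures, curve.fluorescence
    step = float(np.median(np.diff(T)))
    window = max(5, int(round(SMOOTH_WINDOW_C / step)) | 1)  # odd, >= 5
    window = min(window, T.size if T.size % 2 else T.size - 1)
    dF = savgol_filter(F, window_length=window, polyorder=2, deriv=1, delta=step)
    return T, dF


def compute_tm(curve: MeltCurve) -> float:
    """Tm as the interior maximum of the smoothed first derivative.

    Ties break toward lower temperature; the discrete argmax is refined by
    a parabola through its neighbours. Flat or monotonically decreasing
    curves (derivative peak at or below the noise floor) raise
    :class:`NoTransitionError`.
    """
    T, dF = _smoothed_derivative(curve)
    interior = (T >= T[0] + EDGE_EXCLUSION_C) & (T <= T[-1] - EDGE_EXCLUSION_C)
    idx_interior = np.flatnonzero(interior)
    if idx_interior.size < 3:
        raise NoTransitionError("scan range too narrow after edge exclusion")
    d_int = dF[idx_interior]
    peak = float(np.max(d_int))
    noise = 1.4826 * float(np.median(np.abs(d_int - np.median(d_int))))
    span = float(np.max(curve.fluorescence) - np.min(curve.fluorescence))
    floor = max(5.0 * noise, 1e-12, 1e-3 * span / max(T[-1] - T[0], 1.0))
    if peak <= floor:
        raise NoTransitionError("no transition: derivative maximum at noise floor")
    i = int(idx_interior[int(np.argmax(d_int))])  # first max -> lower T on ties
    # sub-grid refinement: quadratic vertex over a ±1 °C window at the peak
    near = np.flatnonzero(np.abs(T - T[i]) <= SMOOTH_WINDOW_C / 2)
    if near.size >= 3:
        a, b, _ = np.polyfit(T[near] - T[i], dF[near], 2)
        if a < 0:
            vertex = -b / (2 * a)
            half = SMOOTH_WINDOW_C / 2
            if -half <= vertex <= half:
                return float(T[i] + vertex)
    return float(T[i])


def delta_tm(sample: MeltResult, reference: MeltResult) -> tuple[float, float]:
    """Thermal shift and its quadrature-propagated SD."""
    shift = sample.tm - reference.tm
    sd = float(np.sqrt(sample.tm_sd**2 + reference.tm_sd**2))
    return float(shift), sd


def aggregate_tm(tms: list[float]) -> MeltResult:
    """Replicate Tm mean with standard deviation."""
    if not tms:
        raise ValueError("no Tm values")
    arr = np.asarray(tms, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return MeltResult(tm=float(np.mean(arr)), tm_sd=sd)


def call_hit(shifts: list[float]) -> bool:
    """Primary-screen hit: any condition's ΔTm strictly above 1 °C."""
    measured = [s for s in shifts if np.isfinite(s)]
    if not measured:
        raise ValueError("no measured conditions")
    return max(measured) > HIT_THRESHOLD


def dose_time_summary(
    compound_id: str,
    conc_series: list[tuple[float, float]],
    time_series: list[tuple[float, float]],
) -> ScreenRow:
    """Dose/time response summary for a confirmed hit.

    ``conc_series``: (concentration µM, ΔTm) pairs at fixed incubation;
    ``time_series``: (time h, ΔTm) pairs at fixed concentration. Reports
    the lowest stabilizing concentration and earliest stabilizing time
    (ΔTm ≥ 1 °C), plus whether the top concentration destabilizes
    (ΔTm ≤ −1 °C).
    """
    conc_sorted = sorted(conc_series)
    time_sorted = sorted(time_series)
    min_conc = next((c for c, s in conc_sorted if s >= HIT_THRESHOLD), None)
    first_time = next((t for t, s in time_sorted if s >= HIT_THRESHOLD), None)
    destab = bool(conc_sorted) and conc_sorted[-1][1] <= DESTABILIZING
    hit = any(s > HIT_THRESHOLD for _, s in conc_sorted + time_sorted)
    return ScreenRow(
        compound_id=compound_id,
        hit=hit,
        min_stabilizing_conc=min_conc,
        first_stabilizing_time=first_time,
        destabilizing_at_high_conc=destab,
    )


def classify_specificity(
    compound_id: str, dt_y220c: float, dt_cl: float, dt_wt: float
) -> SpecificityCall:
    """Three-construct specificity classification.

    Deterministic rule cascade (first match wins) on the shifts in the
    Y220C mutant, its cysteine-light variant, and the pseudo-wild type:

    1. ``cys220-selective`` — both Y220C constructs stabilized comparably
       (gap < 1 °C), wild-type shift minimal (|ΔTm| < 0.5 °C);
    2. ``cys220-plus-surface-arylation`` — both stabilized but the Y220C
       shift exceeds the CL shift by ≥ 1 °C (additive surface arylation);
    3. ``masked-stabilization`` — CL stabilized while Y220C is not and the
       wild type is destabilized (Cys220 effect masked by off-target
       arylation);
    4. ``nonspecific`` — wild-type stabilization ≥ 1 °C, or any remaining
       pattern of significant shifts not attributable to Cys220;
    5. ``inactive`` — all three |ΔTm| < 1 °C.
    """
    sig = HIT_THRESHOLD
    if dt_y220c >= sig and dt_cl >= sig and abs(dt_wt) < MINIMAL_SHIFT and dt_y220c - dt_cl < sig:
        label = "cys220-selective"
    elif dt_y220c >= sig and dt_cl >= sig and dt_y220c - dt_cl >= sig:
        label = "cys220-plus-surface-arylation"
    elif dt_cl >= sig and dt_y220c < sig and dt_wt <= DESTABILIZING:
        label = "masked-stabilization"
    elif dt_wt >= sig:
        label = "nonspecific"
    elif abs(dt_y220c) < sig and abs(dt_cl) < sig and abs(dt_wt) < sig:
        label = "inactive"
    else:
        label = "nonspecific"
    return SpecificityCall(compound_id, dt_y220c, dt_cl, dt_wt, label)
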