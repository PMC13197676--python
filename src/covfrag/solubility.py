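"""Turbidimetric kinetic solubility analysis.

A fragment dilution series (4/5 steps in DMSO, 5% final DMSO in PBS) is
monitored by extinction over 600–800 nm; light scattering above the blank
signals precipitation. Two summary values are reported per compound:

* **MIS** (minimal instant solubility) — the highest tested concentration
  up to which no scattering is observed at the *first* measurement cycle;
* **MFS** (minimal final solubility) — the same rule applied to the *last*
  cycle, capturing slow precipitation over the incubation.

Scattering at a given cycle is called when the mean extinction over the
600–800 nm window strictly exceeds the blank mean plus
``max(abs_threshold, 3 x blank SD)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DilutionSeries",
    "TurbidityTrace",
    "SolubilityRecord",
    "BELOW_LOWEST",
    "make_dilution_series",
    "detect_scattering",
    "call_mis_mfs",
]

#: Marker used when scattering is present even at the lowest tested
#: concentration, i.e. the solubility limit is below the tested range.
BELOW_LOWEST = "< lowest tested"

#: Default absolute scattering threshold above the blank mean (AU).
DEFAULT_ABS_THRESHOLD = 0.02


@dataclass(frozen=True)
class DilutionSeries:
    """Geometric dilution series: ``conc[i] = start * ratio**i``, in mM."""

    start_conc: float
    ratio: float
    n_steps: int
    concentrations: tuple[float, ...]

    def displayed(self) -> tuple[float, ...]:
        """Concentrations rounded to 3 significant figures for reporting."""
        return tuple(float(f"{c:.3g}") for c in self.concentrations)


@dataclass(frozen=True)
class TurbidityTrace:
    """Extinction matrix over (cycle, wavelength) for one concentration."""

    concentration: float  # mM
    cycle_times: tuple[float, ...]  # minutes
    wavelengths: tuple[float, ...]  # nm, 600-800
    extinction: np.ndarray  # (n_cycles, n_wavelengths), AU

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (len(self.cycle_times), len(self.wavelengths)):
            raise ValueError("extinction shape must be (n_cycles, n_wavelengths)")
        if not np.all(np.isfinite(ext)):
            raise ValueError("extinction values must be finite")
        object.__setattr__(self, "extinction", ext)


@dataclass(frozen=True)
class SolubilityRecord:
    id: str
    mis: float | str  # mM, or BELOW_LOWEST
    mfs: float | str


def make_dilution_series(start_conc: float, ratio: float, n_steps: int) -> DilutionSeries:
    """Build the geometric dilution series used for the solubility assay.

    ``make_dilution_series(5.0, 0.8, 12)`` reproduces the assay ladder
    5, 4, 3.2, ... 0.537, 0.429 mM.
    """
    if start_conc <= 0:
        raise ValueError("start_conc must be positive")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    concs = tuple(start_conc * ratio**i for i in range(n_steps))
    return DilutionSeries(start_conc, ratio, n_steps, concs)


def _window_mean_sd(trace: TurbidityTrace, cycle: int) -> tuple[float, float]:
    row = trace.extinction[cycle]
    return float(np.mean(row)), float(np.std(row))


def detect_scattering(
    trace: TurbidityTrace,
    blank: TurbidityTrace,
    cycle: int,
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
) -> bool:
    """True iff the trace scatters relative to the blank at the cycle.

    Decision rule: mean extinction over the wavelength window strictly
    exceeds ``blank mean + max(abs_threshold, 3 x blank SD)``. The strict
    inequality makes a trace sitting exactly at the threshold count as
    clear.
    """
    if trace.wavelengths != blank.wavelengths:
        raise ValueError("trace and blank must share the wavelength grid")
    mean, _ = _window_mean_sd(trace, cycle)
    blank_mean, blank_sd = _window_mean_sd(blank, cycle)
    return mean > blank_mean + max(abs_threshold, 3.0 * blank_sd)


def call_mis_mfs(
    traces: list[TurbidityTrace],
    blank: TurbidityTrace,
    id: str = "",
    abs_threshold: float = DEFAULT_ABS_THRESHOLD,
) -> SolubilityRecord:
    """Call MIS and MFS from the dilution-series traces.

    The reported value is the highest concentration *below the lowest
    scattering concentration* (so a clear well above a scattering one does
    not rescue it — non-monotone noise is treated conservatively). If even
    the lowest concentration scatters, :data:`BELOW_LOWEST` is reported.
    """
    if len(traces) < 1:
        raise ValueError("need at least one trace")
    ordered = sorted(traces, key=lambda t: t.concentration, reverse=True)

    def call_at(cycle: int) -> float | str:
        scattering = [
            t.concentration
            for t in ordered
            if detect_scattering(t, blank, cycle, abs_threshold)
        ]
        if not scattering:
            return ordered[0].concentration
        lowest_scatter = min(scattering)
        clear_below = [t.concentration for t in ordered if t.concentration < lowest_scatter]
        if not clear_below:
            return BELOW_LOWEST
        return max(clear_below)

    last = len(ordered[0].cycle_times) - 1
    return SolubilityRecord(id=id, mis=call_at(0), mfs=call_at(last))
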