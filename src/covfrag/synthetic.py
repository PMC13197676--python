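"""Seeded synthetic-data generators for every assay stage.

Each generator draws from its own ``numpy.random.Generator`` (never global
state), so identical arguments and seed give bit-identical outputs. Noise
models follow standard detector behaviour: additive Gaussian noise for
plate-reader absorbance and fluorescence, multiplicative lognormal noise
for chromatographic peak areas, additive Gaussian baseline noise for the
turbidity window. The noiseless output of each generator, fed to its
paired analysis stage, recovers the generating parameters — that round
trip is the core contract tested throughout the suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemlib import Structure
from .dtnb import PlateKineticRun, second_order_model
from .gsh import AucSeries
from .dsf import MeltCurve
from .solubility import DilutionSeries, TurbidityTrace

__all__ = [
    "SimConfig",
    "simulate_dtnb_run",
    "simulate_gsh_series",
    "simulate_melt_curve",
    "simulate_turbidity",
    "fixture_library",
]


@dataclass(frozen=True)
class SimConfig:
    """Default study conditions for the simulated assays.

    The values mirror the experimental protocols the analysis stages
    assume: 100 µM fragment vs 50 µM TNB²⁻ read every 5 min for 4 h
    (DTNB); 24 h hourly or 20-min fast HPLC schedules (GSH); 0.25 °C melt
    scans from 28 to 70 °C (DSF); the 4/5 dilution ladder from 5 mM
    (turbidity).
    """

    seed: int = 0
    absorbance_sd: float = 0.005  # AU
    auc_cv: float = 0.03
    fluorescence_cv: float = 0.01  # of curve amplitude
    turbidity_baseline_sd: float = 0.005  # AU
    k2: float = 0.1  # M^-1 s^-1
    k: float = 0.5  # h^-1
    plateau_c: float = 0.0
    tm: float = 46.0  # °C
    solubility_limit: float = 2.3  # mM
    dtnb_A0: float = 100e-6
    dtnb_B0: float = 50e-6
    epsilon_path: float = 14000.0  # AU/M
    gsh_schedule: str = "hourly24h"
    extra: dict = field(default_factory=dict)


def simulate_dtnb_run(
    k2_true: float,
    A0: float = 100e-6,
    B0: float = 50e-6,
    epsilon_path: float = 14000.0,
    background_level: float = 0.05,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    duration_s: float = 4 * 3600.0,
    interval_s: float = 300.0,
) -> PlateKineticRun:
    """Simulate a DTNB plate run from the closed-form rate law.

    ``drift`` is a linear AU/s trend added to the compound-background
    wells only (mimicking slow compound absorbance changes); with the
    background subtracted this produces a spurious apparent TNB²⁻ gain or
    loss, the mechanism behind small negative fitted k2 values.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + interval_s / 2, interval_s)
    A_t = second_order_model(A0, B0, k2_true, times)
    B_t = B0 - (A0 - A_t)
    signal = epsilon_path * B_t + background_level
    background = np.full_like(times, background_level) + drift * times
    rxn = np.vstack(
        [signal + rng.normal(0.0, noise_sd, times.size) for _ in range(n_replicates)]
    )
    bg = np.vstack(
        [background + rng.normal(0.0, noise_sd, times.size) for _ in range(n_replicates)]
    )
    blank = epsilon_path * B0 + rng.normal(0.0, noise_sd, times.size)
    return PlateKineticRun(
        times=times,
        a412_reaction=rxn,
        a412_compound_background=bg,
        a412_blank=blank,
        nominal_A0=A0,
        nominal_B0=B0,
    )


def simulate_gsh_series(
    k_true: float,
    plateau_c: float = 0.0,
    schedule: str = "hourly24h",
    cv: float = 0.0,
    seed: int = 0,
    condition: str = "GSH",
    fragment_scale: float = 1000.0,
    standard_scale: float = 800.0,
    detection_limit: float = 0.01,
) -> AucSeries:
    """Simulate an HPLC peak-area decay series.

    Truth: ``fragment = A ((1-c) e^(-k t) + c)`` with multiplicative
    lognormal noise of coefficient of variation ``cv`` on both fragment
    and internal-standard areas. Fragment areas decaying below the
    detection limit are reported as missing peaks (NaN), which exercises
    the censoring path for fast compounds.
    """
    rng = np.random.default_rng(seed)
    if schedule == "hourly24h":
        times = np.arange(0.0, 25.0, 1.0)
    elif schedule == "fast20min":
        times = np.arange(0.0, 4.0 + 1e-9, 1.0 / 3.0)
    else:
        raise ValueError("schedule must be 'hourly24h' or 'fast20min'")
    truth = (1.0 - plateau_c) * np.exp(-k_true * times) + plateau_c
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    frag = fragment_scale * truth * rng.lognormal(mu, sigma, times.size)
    std = standard_scale * rng.lognormal(mu, sigma, times.size)
    frag = np.where(truth < detection_limit, np.nan, frag)
    return AucSeries(
        times=times,
        fragment_auc=frag,
        standard_auc=std,
        condition=condition,
        detection_limit=detection_limit,
    )


def simulate_melt_curve(
    tm_true: float,
    steepness: float = 1.0,
    native_baseline: tuple[float, float] = (100.0, 0.0),
    unfolded_baseline: tuple[float, float] = (1000.0, 0.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    t_min: float = 28.0,
    t_max: float = 70.0,
    step: float = 0.25,
    construct: str = "T-p53C-Y220C",
    compound_id: str | None = None,
    concentration: float = 0.0,
    incubation: float = 0.0,
) -> MeltCurve:
    """Simulate a two-state melt curve with linear baselines.

    ``F(T) = bn(T) + (bu(T) - bn(T)) / (1 + exp((tm - T)/steepness))``
    where ``bn``/``bu`` are (offset, slope) pairs for the folded and
    unfolded baselines; Gaussian noise scales with the curve amplitude.
    """
    rng = np.random.default_rng(seed)
    T = np.arange(t_min, t_max + step / 2, step)
    bn = native_baseline[0] + native_baseline[1] * (T - t_min)
    bu = unfolded_baseline[0] + unfolded_baseline[1] * (T - t_min)
    frac = 1.0 / (1.0 + np.exp((tm_true - T) / steepness))
    F = bn + (bu - bn) * frac
    amplitude = abs(unfolded_baseline[0] - native_baseline[0])
    F = F + rng.normal(0.0, noise_cv * amplitude, T.size)
    return MeltCurve(
        temperatures=T,
        fluorescence=F,
        construct=construct,
        compound_id=compound_id,
        concentration=concentration,
        incubation=incubation,
    )


def simulate_turbidity(
    solubility_limit: float,
    series: DilutionSeries,
    onset_gain: float = 1.0,
    baseline_sd: float = 0.0,
    seed: int = 0,
    kinetic_rate: float = 0.0,
    cycle_times: tuple[float, ...] = (0.0, 57.0, 117.0),
    wavelengths: tuple[float, ...] = tuple(np.arange(600.0, 801.0, 10.0)),
    baseline: float = 0.04,
) -> tuple[list[TurbidityTrace], TurbidityTrace]:
    """Simulate turbidity traces over a dilution series, plus a blank.

    Extinction above the solubility limit grows as
    ``onset_gain * (conc - limit)``; ``kinetic_rate`` (per minute,
    relative) grows the onset term over the cycles so that slow
    precipitation lowers the final (MFS) call below the instant (MIS)
    one. Returns ``(traces, blank)``.
    """
    rng = np.random.default_rng(seed)
    n_w = len(wavelengths)
    traces = []
    for conc in series.concentrations:
        rows = []
        for t in cycle_times:
            onset = onset_gain * max(0.0, conc - solubility_limit / (1.0 + kinetic_rate * t))
            rows.append(baseline + onset + rng.normal(0.0, baseline_sd, n_w))
        traces.append(
            TurbidityTrace(
                concentration=conc,
                cycle_times=tuple(cycle_times),
                wavelengths=tuple(wavelengths),
                extinction=np.vstack(rows),
            )
        )
    blank_rows = np.vstack(
        [baseline + rng.normal(0.0, baseline_sd, n_w) for _ in cycle_times]
    )
    blank = TurbidityTrace(
        concentration=0.0,
        cycle_times=tuple(cycle_times),
        wavelengths=tuple(wavelengths),
        extinction=blank_rows,
    )
    return traces, blank


#: (id, SMILES, expected family, expected SN ring subtype)
_FIXTURE_MOLECULES: tuple[tuple[str, str, str, str], ...] = (
    ("aa-acrylamide", "C=CC(N)=O", "AA", "n/a"),
    ("aa-n-methyl", "C=CC(=O)NC", "AA", "n/a"),
    ("aa-n-phenyl", "C=CC(=O)Nc1ccccc1", "AA", "n/a"),
    ("aa-cinnamamide", "O=C(N)/C=C/c1ccccc1", "AA", "n/a"),
    ("ca-cyanoacrylamide", "C=C(C#N)C(N)=O", "CA", "n/a"),
    ("ca-ethyl-cyanoacrylate", "C=C(C#N)C(=O)OCC", "CA", "n/a"),
    ("ca-benzylidene", "N#C/C(=C\\c1ccccc1)C(N)=O", "CA", "n/a"),
    ("eo-propylene-oxide", "CC1CO1", "EO", "n/a"),
    ("eo-styrene-oxide", "c1ccccc1C1CO1", "EO", "n/a"),
    ("eo-glycidol", "OCC1CO1", "EO", "n/a"),
    ("vs-methyl-vinyl-sulfone", "C=CS(C)(=O)=O", "VS", "n/a"),
    ("vs-phenyl-vinyl-sulfone", "C=CS(=O)(=O)c1ccccc1", "VS", "n/a"),
    ("sn-24-dichloropyrimidine", "Clc1ccnc(Cl)n1", "SN", "six-membered"),
    ("sn-46-dichloropyrimidine", "Clc1cc(Cl)ncn1", "SN", "six-membered"),
    ("sn-2-chloro-5-nitropyridine", "Clc1ccc(cn1)[N+](=O)[O-]", "SN", "six-membered"),
    ("sn-chloropyrazine", "Clc1cnccn1", "SN", "six-membered"),
    ("sn-2-msyl-pyrimidine", "CS(=O)(=O)c1ncccn1", "SN", "six-membered"),
    ("sn-2-chlorothiazole", "Clc1nccs1", "SN", "five-membered"),
    ("sn-2-chloro-1-methylimidazole", "Cn1ccnc1Cl", "SN", "five-membered"),
    ("sn-4-bromopyrazole-ester", "CCOC(=O)c1ncn(C)c1Br", "SN", "five-membered"),
    ("sn-2-chlorobenzothiazole", "Clc1nc2ccccc2s1", "SN", "bicyclic"),
    ("sn-4-chloroquinazoline", "Clc1ncnc2ccccc12", "SN", "bicyclic"),
    ("neg-benzene", "c1ccccc1", "none", "n/a"),
    ("neg-acetamide", "CC(N)=O", "none", "n/a"),
    ("neg-chlorobenzene", "Clc1ccccc1", "none", "n/a"),
    ("neg-pyridine", "c1ccncc1", "none", "n/a"),
    ("neg-cyclohexene", "C1CCC=CC1", "none", "n/a"),
    # 34 heavy atoms: exercised by the size filter (fails the <=22 window)
    (
        "neg-afatinib",
        "CN(C)C/C=C/C(=O)Nc1cc2c(Nc3ccc(F)c(Cl)c3)ncnc2cc1OC1CCOC1",
        "AA",
        "n/a",
    ),
)


def fixture_library() -> list[tuple[Structure, str, str]]:
    """Bundled annotated mini-library spanning all five warhead classes.

    Returns ``(structure, expected_family, expected_sn_ring)`` triples;
    the annotations are the construction ground truth for classification
    round-trip tests.
    """
    return [
        (Structure(id=i, line_notation=smi, source="fixture"), fam, ring)
        for i, smi, fam, ring in _FIXTURE_MOLECULES
    ]
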