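"""Cross-assay integration of reactivity and screening results.

Joins the per-compound outputs of the solubility, DTNB, GSH and DSF
stages, applies the plotting/capping conventions, correlates the two
thiol-reactivity assays, and selects the mild-reactivity subset.

Capping conventions (used for plotting and the correlation):

* rate constants below 1e-4 (h⁻¹ for GSH, M⁻¹s⁻¹ for DTNB) or negative
  are set to 1e-4;
* half-lives above 1000 h or negative are capped at 1000 h; compounds
  undetectable at the first (0 min) or second (20 min) sample are
  assigned 0.01 h and 0.1 h respectively.

The GSH↔DTNB correlation is an ordinary least-squares regression of
log10(k2 DTNB) on log10(k pseudo-first GSH) with capped values included;
both the transform and the inclusion of capped points are configurable
because the headline R² is sensitive to them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gsh import LN2, Censoring

__all__ = [
    "ReactivityRecord",
    "CorrelationResult",
    "RATE_CAP",
    "cap_rate",
    "cap_halflife_for_plot",
    "correlate_gsh_dtnb",
    "select_mild",
    "build_report",
    "load_reactivity_table",
    "load_screen_table",
    "records_from_table",
]

RATE_CAP = 1e-4
HALFLIFE_CAP = 1000.0


@dataclass(frozen=True)
class ReactivityRecord:
    """One compound's row across solubility and reactivity assays.

    Half-lives may be numeric (hours) or a :class:`~covfrag.gsh.Censoring`
    token; ``None`` marks a value the assay could not produce (insoluble
    stock, not UV-quantifiable, ...).
    """

    id: str
    warhead: str = "none"
    t_half_gsh: float | Censoring | None = None
    t_half_pbs: float | Censoring | None = None
    k2_dtnb: float | None = None
    k2_sd: float | None = None
    mis: float | None = None  # mM
    mfs: float | None = None  # mM
    purity_ok: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    slope_sd: float
    intercept: float
    r_squared: float
    n_points: int
    capped_ids: tuple[str, ...]


def cap_rate(k: float) -> float:
    """Floor a rate constant at 1e-4 (negative and tiny values alike)."""
    return max(float(k), RATE_CAP)


def cap_halflife_for_plot(t_half: float | Censoring) -> float:
    """Numeric half-life under the plotting conventions (hours)."""
    if isinstance(t_half, Censoring):
        return {
            Censoring.BELOW_0P033: 0.01,
            Censoring.BELOW_0P33: 0.1,
            Censoring.ABOVE_100: HALFLIFE_CAP,
        }[t_half]
    t = float(t_half)
    if t < 0 or t > HALFLIFE_CAP:
        return HALFLIFE_CAP
    return t


def _k_pseudo_gsh(t_half: float | Censoring, above_100_hours: float | None) -> float:
    """GSH pseudo-first-order constant (h⁻¹) from a possibly censored t½."""
    if t_half is Censoring.ABOVE_100 and above_100_hours is None:
        return 0.0  # floored to the cap downstream
    if isinstance(t_half, Censoring) and t_half is Censoring.ABOVE_100:
        return LN2 / above_100_hours
    return LN2 / cap_halflife_for_plot(t_half)


def correlate_gsh_dtnb(
    records: list[ReactivityRecord],
    space: str = "log10",
    include_capped: bool = True,
    above_100_hours: float | None = 100.0,
) -> CorrelationResult:
    """OLS regression of DTNB k2 against the GSH pseudo-first-order rate.

    Records missing either assay, or failing purity, are excluded.
    Short-censored half-lives enter through their plotting bounds and
    slow-censored ("> 100 h") ones through ``above_100_hours`` (``None``
    sends them straight to the rate-cap floor); both axes are floored at
    1e-4 before the (default) log10 transform.
    """
    xs, ys, ids, capped = [], [], [], []
    for rec in records:
        if not rec.purity_ok or rec.t_half_gsh is None or rec.k2_dtnb is None:
            continue
        kg_raw = _k_pseudo_gsh(rec.t_half_gsh, above_100_hours)
        kd_raw = float(rec.k2_dtnb)
        kg, kd = cap_rate(kg_raw), cap_rate(kd_raw)
        was_capped = (kg != kg_raw) or (kd != kd_raw) or isinstance(rec.t_half_gsh, Censoring)
        if was_capped:
            capped.append(rec.id)
            if not include_capped:
                continue
        xs.append(kg)
        ys.append(kd)
        ids.append(rec.id)
    if len(xs) < 3:
        raise ValueError("need at least 3 compounds with both assays")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if space == "log10":
        x, y = np.log10(x), np.log10(y)
    elif space != "linear":
        raise ValueError("space must be 'log10' or 'linear'")
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        raise ValueError("zero variance on one axis")
    res = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        slope_sd=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(xs),
        capped_ids=tuple(capped),
    )


def select_mild(records: list[ReactivityRecord], lo: float = 1.0, hi: float = 10.0) -> list[str]:
    """Compounds with numeric GSH half-life in [lo, hi] hours (inclusive).

    Censored and unmeasured records are excluded: a bound is not a
    measurement of mildness.
    """
    out = []
    for rec in records:
        t = rec.t_half_gsh
        if not rec.purity_ok or t is None or isinstance(t, Censoring):
            continue
        if lo <= float(t) <= hi:
            out.append(rec.id)
    return sorted(out)


def build_report(
    records: list[ReactivityRecord],
    screen_rows: pd.DataFrame | None = None,
    specificity_calls: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join all stages into one per-compound table plus a summary block.

    ``screen_rows`` needs columns (compound_id, hit, min_stabilizing_conc,
    first_stabilizing_time); ``specificity_calls`` (compound_id, label).
    Compounds present in screening but missing from reactivity get rows
    with missing-value markers. Duplicate ids are an error.
    """
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dupes}")

    def show_t(t):
        if t is None:
            return ""
        if isinstance(t, Censoring):
            return t.display
        return f"{float(t):g}"

    rows = {
        r.id: {
            "compound_id": r.id,
            "warhead": r.warhead,
            "mis_mM": r.mis,
            "mfs_mM": r.mfs,
            "t_half_gsh": show_t(r.t_half_gsh),
            "t_half_pbs": show_t(r.t_half_pbs),
            "k2_dtnb": r.k2_dtnb,
            "k2_sd": r.k2_sd,
            "purity_ok": r.purity_ok,
        }
        for r in records
    }
    if screen_rows is not None:
        for _, s in screen_rows.iterrows():
            cid = s["compound_id"]
            row = rows.setdefault(cid, {"compound_id": cid})
            row["hit"] = bool(s.get("hit", True))
            row["min_stabilizing_conc_uM"] = s.get("min_stabilizing_conc")
            row["first_stabilizing_time_h"] = s.get("first_stabilizing_time")
    if specificity_calls is not None:
        for _, s in specificity_calls.iterrows():
            rows.setdefault(s["compound_id"], {"compound_id": s["compound_id"]})[
                "specificity"
            ] = s["label"]

    table = pd.DataFrame(sorted(rows.values(), key=lambda r: r["compound_id"]))
    mild = select_mild(records)
    low_sol = [
        r.id
        for r in records
        if (r.mis is not None and r.mis < 1.0) or (r.mfs is not None and r.mfs < 1.0)
    ]
    unstable = [
        r.id
        for r in records
        if r.t_half_gsh is not None
        and r.t_half_pbs is not None
        and _plot_bound(r.t_half_pbs) < _plot_bound(r.t_half_gsh)
    ]
    summary = {
        "n_compounds": len(table),
        "n_hits": int(sum(bool(h) for h in table["hit"] if pd.notna(h))) if "hit" in table else 0,
        "n_mild": len(mild),
        "mild_ids": mild,
        "n_low_solubility": len(low_sol),
        "low_solubility_ids": sorted(low_sol),
        "n_buffer_unstable": len(unstable),
        "buffer_unstable_ids": sorted(unstable),
    }
    return table, summary


def _plot_bound(t: float | Censoring) -> float:
    if isinstance(t, Censoring):
        return np.inf if t is Censoring.ABOVE_100 else cap_halflife_for_plot(t)
    return float(t)


# ---------------------------------------------------------------------------
# Bundled transcriptions of the published per-compound result tables


_TOKEN_MAP = {
    "<<0.033": Censoring.BELOW_0P033,
    "<<0.33": Censoring.BELOW_0P33,
    ">100": Censoring.ABOVE_100,
}


def _parse_halflife(value) -> float | Censoring | None:
    s = str(value).strip()
    if s in ("", "na", "nan"):
        return None
    if s in _TOKEN_MAP:
        return _TOKEN_MAP[s]
    return float(s)


def load_reactivity_table(path=None) -> pd.DataFrame:
    """Load the bundled solubility/reactivity table (or a same-format CSV)."""
    if path is None:
        path = importlib.resources.files("covfrag.data") / "tables_1_2.csv"
    return pd.read_csv(path, dtype={"note": str}, keep_default_na=False)


def load_screen_table(path=None) -> pd.DataFrame:
    """Load the bundled dose/time screening summary table."""
    if path is None:
        path = importlib.resources.files("covfrag.data") / "table_3.csv"
    return pd.read_csv(path, keep_default_na=False)


def records_from_table(
    table: pd.DataFrame, include_benchmarks: bool = False
) -> list[ReactivityRecord]:
    """Convert the bundled reactivity table into typed records."""
    records = []
    for _, row in table.iterrows():
        if not include_benchmarks and int(row.get("benchmark", 0)):
            continue

        def num(col):
            s = str(row.get(col, "")).strip()
            return None if s in ("", "na", "nan") else float(s)

        records.append(
            ReactivityRecord(
                id=row["compound_id"],
                warhead=row.get("warhead", "none"),
                t_half_gsh=_parse_halflife(row.get("t_half_gsh_h", "na")),
                t_half_pbs=_parse_halflife(row.get("t_half_pbs_h", "na")),
                k2_dtnb=num("k2_dtnb"),
                k2_sd=num("k2_dtnb_sd"),
                mis=num("mis_mM"),
                mfs=num("mfs_mM"),
                purity_ok=str(row.get("note", "")).strip() != "g",
            )
        )
    return records
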