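"""Gridded agricultural herbicide risk scoring (PEC/PNEC/RQ/RP).

Per grid cell and (crop, herbicide) pair:

* soil load            ``S = VDT * AR / 100``        (VDT = % soil coverage)
* decay integral       ``I = (1 - exp(-lambda*T))/lambda``, lambda = ln2/DT50
* predicted exposure   ``PEC = (S / 4500) * (I / 100)``
* no-effect threshold  ``PNEC = LC50 / 1000``        (assessment factor 1000)
* risk quotient        ``RQ = PEC / PNEC``
* risk point           ``RP = log10(sum RQ)`` over all pairs in the cell

The constants 4500 and 100 come verbatim from the source exposure indicator;
their units are opaque, so PEC and PNEC are treated as model units and only
the ratio RQ is interpreted.  Dissipation is modelled as single first-order
decay from DT50 (DT90 is carried but redundant under first-order kinetics).
RP classes: <= 0 negligible, (0, 1] low, (1, 3] medium, > 3 high; a cell with
sum RQ = 0 has undefined log and is negligible by convention (rp = -inf).

Soil (earthworm LC50) and water (fish LC50) compartments are both computed;
the default aggregation takes the larger RQ of the two per pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HerbicideProps",
    "residual_integral",
    "soil_load",
    "pec",
    "pnec",
    "classify_rp",
    "RP_CLASSES",
    "risk_point",
    "risk_map",
    "summarize_risk_map",
    "DEFAULT_HORIZON_DAYS",
]

DEFAULT_HORIZON_DAYS = 365.0

RP_CLASSES = ("negligible", "low", "medium", "high")

CELL_COLUMNS = ("cell_id", "region", "area_km2", "crop", "herbicide", "AR", "VDT")


@dataclass(frozen=True)
class HerbicideProps:
    """Environmental-fate and toxicity properties of one herbicide."""

    name: str
    dt50_days: float
    lc50_earthworm: float  # mass per soil mass
    lc50_fish: float       # mass per water volume
    dt90_days: float | None = None  # unused under first-order decay

    def __post_init__(self) -> None:
        if not self.dt50_days > 0:
            raise ValueError(f"DT50 must be > 0 for {self.name!r}")
        if not (self.lc50_earthworm > 0 and self.lc50_fish > 0):
            raise ValueError(f"LC50 values must be > 0 for {self.name!r}")


def residual_integral(dt50_days: float, horizon_days: float = DEFAULT_HORIZON_DAYS) -> float:
    """Time integral of the residual fraction over the horizon (days).

    First-order decay with rate ``lambda = ln2 / DT50``; closed form
    ``(1 - exp(-lambda*T)) / lambda``.  Approaches T for very persistent
    substances and 1/lambda for a long horizon.
    """
    if not (dt50_days > 0 and horizon_days > 0):
        raise ValueError("DT50 and horizon must be positive")
    lam = math.log(2.0) / dt50_days
    return -math.expm1(-lam * horizon_days) / lam


def soil_load(vdt_pct: float, ar: float) -> float:
    """Herbicide load reaching soil: ``S = VDT * AR / 100``."""
    if vdt_pct < 0 or ar < 0:
        raise ValueError("VDT and AR must be >= 0")
    return vdt_pct * ar / 100.0


def pec(s: float, integral: float) -> float:
    """Predicted environmental concentration ``(S/4500) * (integral/100)``."""
    if s < 0 or integral < 0:
        raise ValueError("inputs must be >= 0")
    return (s / 4500.0) * (integral / 100.0)


def pnec(lc50: float) -> float:
    """Predicted no-effect concentration ``LC50 / 1000``."""
    if not lc50 > 0:
        raise ValueError("LC50 must be > 0")
    return lc50 / 1000.0


def classify_rp(rp: float) -> str:
    """Four-class risk grade; boundaries at 0, 1 and 3 are inclusive below."""
    if math.isnan(rp):
        raise ValueError("risk point is NaN")
    if rp <= 0.0:  # includes -inf for sum RQ = 0
        return "negligible"
    if rp <= 1.0:
        return "low"
    if rp <= 3.0:
        return "medium"
    return "high"


def _pair_rq(ar: float, vdt: float, props: HerbicideProps,
             horizon_days: float, compartment: str) -> float:
    exposure = pec(soil_load(vdt, ar), residual_integral(props.dt50_days, horizon_days))
    rq_soil = exposure / pnec(props.lc50_earthworm)
    rq_water = exposure / pnec(props.lc50_fish)
    if compartment == "soil":
        return rq_soil
    if compartment == "water":
        return rq_water
    if compartment == "max":
        return max(rq_soil, rq_water)
    raise ValueError(f"unknown compartment {compartment!r}; use soil, water or max")


@dataclass
class RiskResult:
    """Risk point and class for one grid cell, with the per-pair breakdown."""

    cell_id: object
    sum_rq: float
    rp: float
    risk_class: str
    breakdown: pd.DataFrame


def risk_point(cell: pd.DataFrame, props: dict[str, HerbicideProps],
               horizon_days: float = DEFAULT_HORIZON_DAYS,
               compartment: str = "max") -> RiskResult:
    """Risk point of one cell from its (crop, herbicide, AR, VDT) rows."""
    cell_ids = cell["cell_id"].unique()
    if len(cell_ids) != 1:
        raise ValueError(f"risk_point expects one cell, got ids {cell_ids.tolist()}")
    rows = []
    for _, r in cell.iterrows():
        name = r["herbicide"]
        if name not in props:
            raise KeyError(
                f"no properties for herbicide {name!r} (cell {r['cell_id']!r}, crop {r['crop']!r})"
            )
        rq = _pair_rq(float(r["AR"]), float(r["VDT"]), props[name],
                      horizon_days, compartment)
        rows.append({"crop": r["crop"], "herbicide": name, "rq": rq})
    breakdown = pd.DataFrame(rows, columns=["crop", "herbicide", "rq"])
    sum_rq = float(breakdown["rq"].sum()) if not breakdown.empty else 0.0
    rp = math.log10(sum_rq) if sum_rq > 0 else float("-inf")
    return RiskResult(cell_ids[0], sum_rq, rp, classify_rp(rp), breakdown)


def risk_map(cells: pd.DataFrame, props: dict[str, HerbicideProps],
             horizon_days: float = DEFAULT_HORIZON_DAYS,
             compartment: str = "max") -> pd.DataFrame:
    """Risk point per cell over a long-format application table.

    ``cells`` columns: cell_id, region, area_km2, crop, herbicide, AR, VDT
    (one row per application).  Returns one row per cell with sum_RQ, RP and
    class.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns {missing}")
    unknown = sorted(set(cells["herbicide"]) - set(props))
    if unknown:
        raise KeyError(f"no properties for herbicides {unknown}")
    work = cells.copy()
    integrals = {name: residual_integral(p.dt50_days, horizon_days)
                 for name, p in props.items()}
    pnec_eff = {}
    for name, p in props.items():
        if compartment == "soil":
            pnec_eff[name] = pnec(p.lc50_earthworm)
        elif compartment == "water":
            pnec_eff[name] = pnec(p.lc50_fish)
        elif compartment == "max":
            pnec_eff[name] = min(pnec(p.lc50_earthworm), pnec(p.lc50_fish))
        else:
            raise ValueError(f"unknown compartment {compartment!r}")
    s = work["VDT"].to_numpy(float) * work["AR"].to_numpy(float) / 100.0
    integ = work["herbicide"].map(integrals).to_numpy(float)
    work["rq"] = (s / 4500.0) * (integ / 100.0) / work["herbicide"].map(pnec_eff).to_numpy(float)
    agg = work.groupby(["cell_id", "region", "area_km2"], sort=False, as_index=False)["rq"].sum()
    agg = agg.rename(columns={"rq": "sum_RQ"})
    with np.errstate(divide="ignore"):
        agg["RP"] = np.where(agg["sum_RQ"] > 0, np.log10(agg["sum_RQ"]), -np.inf)
    agg["class"] = [classify_rp(rp) for rp in agg["RP"]]
    return agg


def summarize_risk_map(results: pd.DataFrame, cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-region agricultural area and area fraction in each risk class.

    ``results`` is the output of :func:`risk_map` (or any table with cell_id,
    region, area_km2, class).  When ``cells`` is given, every result must join
    a cell in it; orphan results raise.  Zero-area cells are excluded from the
    fraction denominators.
    """
    if cells is not None:
        known = set(cells["cell_id"])
        orphans = sorted(set(results["cell_id"]) - known)
        if orphans:
            raise ValueError(f"results reference unknown cells {orphans[:5]}")
    work = results.loc[results["area_km2"] > 0]
    rows = []
    for region, grp in sorted(work.groupby("region"), key=lambda t: str(t[0])):
        total = float(grp["area_km2"].sum())
        row = {"region": region, "area_km2": total}
        for cls in RP_CLASSES:
            row[f"frac_{cls}"] = float(
                grp.loc[grp["class"] == cls, "area_km2"].sum()) / total
        rows.append(row)
    return pd.DataFrame(rows)
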