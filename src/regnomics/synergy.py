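"""Drug-combination synergy quantification.

Viability normalization against vehicle, four-parameter logistic (4PL)
dose-response fitting, closed-form ICx inversion, isobologram construction
at a fixed inhibition level (85% by default) and the Loewe combination
index CI = d1/IC_1 + d2/IC_2 (CI = 1 additivity, < 1 synergy,
> 1 antagonism).  Also the ellipsoid tumor-volume utility
(length x width x height / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponsePlate",
    "FourPLFit",
    "SynergyResult",
    "normalize_viability",
    "fit_4pl",
    "four_pl",
    "icx",
    "combination_index",
    "isobologram",
    "tumor_volume",
    "read_plate_csv",
]


@dataclass(frozen=True)
class FourPLFit:
    """4PL curve v(d) = bottom + (top - bottom) / (1 + (d/ec50)^hill)."""

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float

    def __post_init__(self) -> None:
        if self.bottom >= self.top:
            raise ValueError("bottom must be < top")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill == 0:
            raise ValueError("hill slope must be nonzero")

    def viability(self, dose):
        return four_pl(np.asarray(dose, dtype=float),
                       self.bottom, self.top, self.ec50, self.hill)


@dataclass(frozen=True)
class SynergyResult:
    """IC doses per single agent plus the combination isobologram points
    and their combination indices at the chosen inhibition level."""

    level: float
    ic_drug1: float
    ic_drug2: float
    points: pd.DataFrame  # columns: dose1, dose2, ci


@dataclass
class DoseResponsePlate:
    """Single-agent series plus an optional combination matrix.

    ``data`` holds columns drug1_dose, drug2_dose, viability_percent
    (relative to vehicle, 100 = untreated); rows with one zero dose are the
    other drug's single-agent series.
    """

    drug1: str
    drug2: str
    data: pd.DataFrame

    def single_agent(self, which: int) -> pd.DataFrame:
        d_self, d_other = ("drug1_dose", "drug2_dose") if which == 1 else (
            "drug2_dose", "drug1_dose")
        sub = self.data[(self.data[d_other] == 0) & (self.data[d_self] > 0)]
        return (sub.groupby(d_self, as_index=False)["viability_percent"]
                .mean().rename(columns={d_self: "dose"}))


def normalize_viability(readings: Sequence[float],
                        vehicle_readings: Sequence[float]) -> np.ndarray:
    """Percent viable cells relative to the vehicle-control mean."""
    vehicle = np.asarray(vehicle_readings, dtype=float)
    if vehicle.size == 0 or vehicle.mean() <= 0:
        raise ValueError("vehicle mean must be positive")
    return 100.0 * np.asarray(readings, dtype=float) / vehicle.mean()


def four_pl(dose, bottom, top, ec50, hill):
    """4PL response; defined as ``top`` at dose 0 for positive hill."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ec50, 0.0)
        term = np.where(dose > 0, ratio ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + term)


def fit_4pl(doses: Sequence[float], viabilities: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit with multi-start on the Hill-slope sign.

    Requires >= 5 distinct dose levels spanning the response range; flat
    data raise a fit-quality error with diagnostics.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.size != v.size:
        raise ValueError("doses and viabilities must have equal length")
    if np.unique(d).size < 5:
        raise ValueError("fit_4pl requires >= 5 distinct dose levels")
    if np.ptp(v) < 1e-9:
        raise ValueError(f"flat response (range {np.ptp(v):.3g}); cannot fit a dose-response curve")
    pos = d[d > 0]
    ec50_init = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    best = None
    for hill0 in (1.0, 2.0, -1.0, -2.0):
        p0 = [float(v.min()), float(v.max()), ec50_init, hill0]
        try:
            popt, _ = curve_fit(
                four_pl, d, v, p0=p0, maxfev=20000,
                bounds=([-np.inf, -np.inf, 1e-12, -50], [np.inf, np.inf, np.inf, 50]))
        except RuntimeError:
            continue
        rss = float(np.sum((four_pl(d, *popt) - v) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise ValueError("4PL fit failed to converge from all starts")
    (bottom, top, ec50, hill), rss = best
    if bottom > top:
        # flip parameterization to keep bottom < top
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(bottom=float(bottom), top=float(top), ec50=float(ec50),
                     hill=float(hill), rss=rss)


def icx(fit: FourPLFit, x: float = 85.0) -> float:
    """Dose producing x% inhibition: closed-form 4PL inversion at the
    target viability v* = 100 - x."""
    v_star = 100.0 - x
    if not (min(fit.bottom, fit.top) < v_star < max(fit.bottom, fit.top)):
        raise ValueError(
            f"target viability {v_star} outside the fitted asymptotes "
            f"({fit.bottom:.3g}, {fit.top:.3g})")
    return float(fit.ec50 * ((fit.top - v_star) / (v_star - fit.bottom))
                 ** (1.0 / fit.hill))


def combination_index(d1: float, d2: float, ic_1: float, ic_2: float) -> float:
    """Loewe combination index at a fixed effect level:
    CI = d1/IC_1 + d2/IC_2."""
    if ic_1 <= 0 or ic_2 <= 0:
        raise ValueError("reference IC doses must be positive")
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be nonnegative")
    return d1 / ic_1 + d2 / ic_2


def _interp_dose_at_level(doses: np.ndarray, viab: np.ndarray,
                          target_v: float) -> float | None:
    """Dose reaching the target viability by monotone linear interpolation
    in log-dose; None when the series never crosses the target."""
    order = np.argsort(doses)
    d, v = doses[order], viab[order]
    pos = d > 0
    d, v = d[pos], v[pos]
    if d.size < 2:
        return None
    crossings = np.nonzero((v[:-1] - target_v) * (v[1:] - target_v) <= 0)[0]
    if crossings.size == 0:
        return None
    i = int(crossings[0])
    if v[i] == v[i + 1]:
        return float(d[i])
    frac = (target_v - v[i]) / (v[i + 1] - v[i])
    return float(np.exp(np.log(d[i]) + frac * (np.log(d[i + 1]) - np.log(d[i]))))


def isobologram(plate: DoseResponsePlate, level: float = 85.0) -> SynergyResult:
    """Construct the fixed-level isobologram and per-point combination
    indices.

    Both single agents are 4PL-fitted and inverted for their IC at
    ``level``% inhibition.  For each fixed dose of the second drug, the
    first drug's dose achieving the level is interpolated along that series
    (log-dose linear, never extrapolated); each (d1, d2) point gets
    CI = d1/IC_1 + d2/IC_2.  Levels unreachable everywhere give an empty
    point set with a warning.
    """
    sa1 = plate.single_agent(1)
    sa2 = plate.single_agent(2)
    fit1 = fit_4pl(sa1["dose"], sa1["viability_percent"])
    fit2 = fit_4pl(sa2["dose"], sa2["viability_percent"])
    ic1 = icx(fit1, level)
    ic2 = icx(fit2, level)
    target_v = 100.0 - level

    points = []
    combo = plate.data[(plate.data["drug1_dose"] > 0)
                       & (plate.data["drug2_dose"] > 0)]
    for d2, series in combo.groupby("drug2_dose"):
        agg = (series.groupby("drug1_dose", as_index=False)["viability_percent"]
               .mean())
        d1_star = _interp_dose_at_level(agg["drug1_dose"].to_numpy(dtype=float),
                                        agg["viability_percent"].to_numpy(dtype=float),
                                        target_v)
        if d1_star is None:
            continue
        points.append({"dose1": d1_star, "dose2": float(d2),
                       "ci": combination_index(d1_star, float(d2), ic1, ic2)})
    if not points:
        warnings.warn(f"no combination series reaches {level}% inhibition")
    return SynergyResult(level=level, ic_drug1=ic1, ic_drug2=ic2,
                         points=pd.DataFrame(points, columns=["dose1", "dose2", "ci"]))


def tumor_volume(length: float, width: float, height: float) -> float:
    """Ellipsoid-approximation tumor volume: length x width x height / 2."""
    if length <= 0 or width <= 0 or height <= 0:
        raise ValueError("all dimensions must be positive")
    return length * width * height / 2.0


def read_plate_csv(source, drug1: str = "drug1", drug2: str = "drug2"
                   ) -> DoseResponsePlate:
    """Plate CSV with columns drug1_dose, drug2_dose, viability_percent
    (and optionally replicate)."""
    df = pd.read_csv(source)
    required = {"drug1_dose", "drug2_dose", "viability_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    return DoseResponsePlate(drug1=drug1, drug2=drug2, data=df)
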