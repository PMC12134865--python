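"""Quantitative calculators for in vitro and in vivo drug readouts.

Covers four-parameter-logistic (4PL) concentration-response fitting
with an explicit "ambiguous" status, control-relative normalization,
caspase-to-viability apoptosis fold change, the modified ellipsoidal
caliper tumor volume V = 1/2 * length * width^2, percent tumor-volume
reduction, and the Reagan-Shaw body-surface-area human-equivalent-dose
conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "DoseResponseFit",
    "TumorRecord",
    "fit_4pl",
    "four_pl",
    "relative_to_control",
    "caspase_fold",
    "tumor_volume",
    "percent_reduction",
    "reagan_shaw_human_dose",
]

#: standard body-surface-area Km factors (weight / surface area) and the
#: default adult body weight used for daily-dose conversion.
KM_MOUSE = 3.0
KM_HUMAN = 37.0
ADULT_WEIGHT_KG = 60.0

#: ambiguity threshold on the standard error of log10(IC50).
IC50_SE_LOG_MAX = 0.5


@dataclass
class DoseResponseFit:
    """Result of a 4PL concentration-response fit.

    ``status`` is "ok" or "ambiguous"; an ambiguous fit (no convergence,
    IC50 outside the tested concentration range, or log10-IC50 standard
    error above the threshold) reports no IC50.
    """

    bottom: float
    top: float
    hill: float
    ic50: float | None
    ic50_se_log: float
    status: str

    def summary(self) -> str:
        lines = ["4PL concentration-response fit", "-" * 32]
        if self.status == "ok":
            lines += [
                f"IC50          {self.ic50:.4g} umol/L",
                f"SE(log10 IC50) {self.ic50_se_log:.3f}",
                f"top / bottom  {self.top:.4g} / {self.bottom:.4g}",
                f"Hill slope    {self.hill:.3f}",
                "status        ok",
            ]
        else:
            lines += ["status        ambiguous (IC50 not determined)"]
        return "\n".join(lines)


@dataclass
class TumorRecord:
    """One caliper measurement; volume is the modified ellipsoid estimate."""

    animal_id: str
    group: str
    day: int
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.group not in ("control", "treated"):
            raise ValueError(f"group must be control/treated, got {self.group!r}")
        if self.width > self.length:
            raise ValueError(
                f"width ({self.width}) exceeds length ({self.length}); "
                "caliper convention puts the longer axis first"
            )

    @property
    def volume(self) -> float:
        return tumor_volume(self.length, self.width)


def four_pl(c, bottom: float, top: float, log_ic50: float, hill: float):
    """4PL inhibition model: response falls from top to bottom with dose."""
    return bottom + (top - bottom) / (1.0 + (np.asarray(c, dtype=float) / 10.0 ** log_ic50) ** hill)


def fit_4pl(concentrations, responses) -> DoseResponseFit:
    """Least-squares 4PL fit with an ambiguity rule.

    Requires at least 4 distinct positive concentrations. The fit is
    initialized from the data (top = max response, bottom = min,
    IC50 = geometric mid-range, Hill = 1) with the Hill slope bounded to
    [0.1, 10]. The fit is reported "ambiguous" — with no IC50 — when the
    optimizer fails, the IC50 lands outside the tested range, or the
    standard error of log10(IC50) exceeds 0.5.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.unique(c).size < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations, got {np.unique(c).size}"
        )
    span = float(np.ptp(r))
    if span == 0.0:
        return DoseResponseFit(float(r[0]), float(r[0]), np.nan, None, np.inf, "ambiguous")

    logc = np.log10(c)
    p0 = [float(r.min()), float(r.max()), float(logc.mean()), 1.0]
    lo = [-np.inf, -np.inf, logc.min() - 2.0, 0.1]
    hi = [np.inf, np.inf, logc.max() + 2.0, 10.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(
                four_pl, c, r, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except (RuntimeError, ValueError):
        return DoseResponseFit(np.nan, np.nan, np.nan, None, np.inf, "ambiguous")

    bottom, top, log_ic50, hill = (float(v) for v in popt)
    ic50 = 10.0 ** log_ic50
    se_log = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    ok = (
        np.isfinite(se_log)
        and se_log <= IC50_SE_LOG_MAX
        and c.min() <= ic50 <= c.max()
        and top > bottom
    )
    if not ok:
        return DoseResponseFit(bottom, top, hill, None, se_log, "ambiguous")
    return DoseResponseFit(bottom, top, hill, ic50, se_log, "ok")


def relative_to_control(measurements, control_measurements) -> np.ndarray | float:
    """Measurement(s) divided by the control mean.

    Serves colony counts, viability, confluence, and densitometry
    ratios alike; the control mean must be positive.
    """
    ctrl = float(np.mean(np.asarray(control_measurements, dtype=float)))
    if not ctrl > 0:
        raise ValueError(f"control mean must be > 0, got {ctrl}")
    out = np.asarray(measurements, dtype=float) / ctrl
    return float(out) if out.ndim == 0 else out


def caspase_fold(
    caspase_treated,
    viability_treated,
    caspase_control,
    viability_control,
) -> float:
    """Viability-normalized apoptosis fold change.

    ``(caspase / viability)_treated / (caspase / viability)_control``;
    normalizing to viability separates genuine caspase activation from
    mere loss of cells.
    """
    vt = float(np.mean(np.asarray(viability_treated, dtype=float)))
    vc = float(np.mean(np.asarray(viability_control, dtype=float)))
    if vt <= 0 or vc <= 0:
        raise ValueError("viability signals must be > 0")
    ct = float(np.mean(np.asarray(caspase_treated, dtype=float)))
    cc = float(np.mean(np.asarray(caspase_control, dtype=float)))
    if cc <= 0:
        raise ValueError("control caspase signal must be > 0")
    return (ct / vt) / (cc / vc)


def tumor_volume(length: float, width: float) -> float:
    """Modified ellipsoidal caliper volume, V = 1/2 * length * width^2 (mm^3)."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be >= 0")
    return 0.5 * length * width * width


def percent_reduction(mean_control: float, mean_treated: float) -> float:
    """Percent reduction of the treated mean relative to control.

    ``100 * (control - treated) / control``; report to one decimal.
    """
    if not mean_control > 0:
        raise ValueError(f"control mean must be > 0, got {mean_control}")
    return 100.0 * (mean_control - mean_treated) / mean_control


def reagan_shaw_human_dose(
    animal_dose: float,
    km_animal: float = KM_MOUSE,
    km_human: float = KM_HUMAN,
    human_weight: float = ADULT_WEIGHT_KG,
) -> tuple[float, int]:
    """Body-surface-area dose conversion to a human-equivalent dose.

    ``HED (mg/kg) = animal dose (mg/kg) * km_animal / km_human``; the
    daily dose is HED times body weight, rounded to the nearest mg.
    Defaults use the standard mouse (3) and human (37) Km factors and a
    60-kg adult.
    """
    if animal_dose < 0:
        raise ValueError("animal_dose must be >= 0")
    if km_animal <= 0 or km_human <= 0 or human_weight <= 0:
        raise ValueError("km factors and human_weight must be > 0")
    hed = animal_dose * km_animal / km_human
    return hed, int(round(hed * human_weight))


def tumor_growth_table(records: list[TumorRecord]) -> pd.DataFrame:
    """Tidy per-measurement table with computed volumes."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "day": [r.day for r in records],
            "length": [r.length for r in records],
            "width": [r.width for r in records],
            "volume": [r.volume for r in records],
        }
    )
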