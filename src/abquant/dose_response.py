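"""Mass-law dose-response fitting (IC50 estimation).

The inhibition curve is single-site occupancy (Hill coefficient fixed at 1):

    response(c) = floor + (1 - floor) * IC50 / (IC50 + c)

i.e. normalized activity 1 with no inhibitor, falling to ``floor`` at
saturation, half-way between the two at c = IC50.  Fitting is non-linear
least squares weighted by 1/SEM^2, multi-started over a geometric grid of
IC50 initializations because sparse dose designs can have local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .errors import FitConvergenceError, InvalidConfigError

#: Optional free Hill slope for sensitivity analysis only; the reported model
#: keeps the coefficient fixed at 1 (simple mass-action binding).
ALLOW_FREE_HILL = False


def mass_law(
    c: np.ndarray | float, ic50: float, floor: float = 0.0, hill: float = 1.0
) -> np.ndarray | float:
    """Normalized activity at inhibitor concentration ``c`` (same units as ic50)."""
    if ic50 <= 0:
        raise InvalidConfigError("ic50 must be > 0")
    if not 0.0 <= floor < 1.0:
        raise InvalidConfigError("floor must lie in [0, 1)")
    c = np.asarray(c, dtype=float) if np.ndim(c) else float(c)
    if np.any(np.asarray(c) < 0):
        raise InvalidConfigError("concentrations must be >= 0")
    occ = ic50**hill / (ic50**hill + np.asarray(c, dtype=float) ** hill)
    out = floor + (1.0 - floor) * occ
    return out if np.ndim(c) else float(out)


@dataclass
class DoseResponseFit:
    """Fitted mass-law curve with SEM-weighted diagnostics."""

    ic50: float
    floor: float
    ic50_stderr: float | None
    floor_stderr: float | None
    residuals: np.ndarray
    weighted_sse: float
    n_points: int
    floor_fixed: bool
    converged: bool
    wide_confidence: bool = False
    message: str = ""
    doses: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        return mass_law(c, self.ic50, self.floor)


def fit_mass_law(
    doses: np.ndarray | list[float],
    means: np.ndarray | list[float],
    sems: np.ndarray | list[float],
    fix_floor: float | None = None,
    n_starts: int = 8,
) -> DoseResponseFit:
    """SEM-weighted non-linear regression of the mass-law curve.

    ``fix_floor`` pins the residual activity at saturation (pass 0.0 for the
    pure-occupancy model); otherwise the floor is a free parameter in [0, 1).
    IC50 is initialized on a geometric grid spanning the dose range and the
    best weighted fit is kept.  Dose designs with fewer than 4 distinct doses
    or spanning under two decades are fit anyway but flagged wide-confidence.
    """
    doses = np.asarray(doses, dtype=float)
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    if not doses.size == means.size == sems.size:
        raise InvalidConfigError("doses, means and sems must have equal length")
    if np.any(doses <= 0):
        raise InvalidConfigError("doses must be > 0")
    if np.any(sems <= 0):
        raise InvalidConfigError("SEM weights require sems > 0")

    distinct = np.unique(doses)
    wide = distinct.size < 4 or distinct.max() / distinct.min() < 100.0
    if wide:
        warnings.warn(
            "dose design is sparse or spans < 2 decades; IC50 confidence is wide",
            stacklevel=2,
        )
    w = 1.0 / sems

    def residual(p: Parameters) -> np.ndarray:
        return (means - mass_law(doses, 10.0 ** p["log_ic50"].value, p["floor"].value)) * w

    best = None
    for ic50_init in np.geomspace(distinct.min(), distinct.max(), n_starts):
        params = Parameters()
        params.add("log_ic50", value=np.log10(ic50_init),
                   min=np.log10(distinct.min()) - 4, max=np.log10(distinct.max()) + 4)
        if fix_floor is None:
            params.add("floor", value=0.1, min=0.0, max=1.0 - 1e-9)
        else:
            if not 0.0 <= fix_floor < 1.0:
                raise InvalidConfigError("fixed floor must lie in [0, 1)")
            params.add("floor", value=fix_floor, vary=False)
        try:
            res = minimize(residual, params, method="leastsq",
                           xtol=1e-12, ftol=1e-12)
        except Exception:  # singular steps from a bad start: try the next one
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise FitConvergenceError("mass-law fit failed to converge from any start")

    ic50 = 10.0 ** best.params["log_ic50"].value
    log_err = best.params["log_ic50"].stderr
    floor_err = best.params["floor"].stderr if fix_floor is None else None
    return DoseResponseFit(
        ic50=float(ic50),
        floor=float(best.params["floor"].value),
        ic50_stderr=None if log_err is None else float(ic50 * np.log(10.0) * log_err),
        floor_stderr=None if floor_err is None else float(floor_err),
        residuals=np.asarray(best.residual, dtype=float),
        weighted_sse=float(best.chisqr),
        n_points=int(doses.size),
        floor_fixed=fix_floor is not None,
        converged=bool(best.success),
        wide_confidence=wide,
        message=str(best.message),
        doses=doses.copy(),
    )
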