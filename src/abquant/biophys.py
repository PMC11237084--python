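"""Supporting biophysical calculations: SEC calibration, Langmuir 1:1 SPR
kinetics, and ThT aggregation-curve normalization.

SEC: partition coefficients K_av = (Ve - V0)/(Vt - V0) of protein standards
define a log10(mass) vs K_av calibration line, inverted to interpolate the
apparent molecular mass of an unknown from its peak elution volume.

SPR: the 1:1 Langmuir model gives association
R(t) = Req * (1 - exp(-(k_on*C + k_off) t)) with Req = Rmax * C / (C + K_D)
and first-order dissociation; a global weighted fit across a concentration
series yields k_on, k_off, Rmax, and K_D = k_off / k_on (exact by construction).

ThT: fluorescence curves are normalized so the t=0 intensity is 0 and the
aggregation plateau is 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.ndimage import gaussian_filter1d

from .errors import IdentifiabilityError, InvalidConfigError, WindowError


# --------------------------------------------------------------------------- #
# Size-exclusion chromatography
# --------------------------------------------------------------------------- #

#: Calibration standards: (name, mass in kDa) of the column calibration set.
SEC_STANDARDS_KDA = (
    ("alcohol dehydrogenase", 150.0),
    ("bovine serum albumin", 66.0),
    ("ovalbumin", 43.0),
    ("carbonic anhydrase", 29.0),
    ("cytochrome c", 12.4),
    ("aprotinin", 6.5),
)


@dataclass
class Chromatogram:
    """An elution profile with known void (V0) and total (Vt) column volumes."""

    volumes: np.ndarray   # ml, strictly increasing
    signal: np.ndarray    # absorbance, arbitrary units
    v0: float
    vt: float

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.v0 >= self.vt:
            raise InvalidConfigError("V0 must be smaller than Vt")
        if self.volumes.size != self.signal.size:
            raise InvalidConfigError("volumes and signal must have equal length")
        if np.any(np.diff(self.volumes) <= 0):
            raise InvalidConfigError("elution volumes must be strictly increasing")


def kav(ve: float, v0: float, vt: float) -> float:
    """Partition coefficient K_av = (Ve - V0)/(Vt - V0)."""
    if v0 >= vt:
        raise InvalidConfigError("V0 must be smaller than Vt")
    tol = 1e-9 * (vt - v0)  # numerical slack for peaks picked exactly at V0
    if ve < v0 - tol:
        raise InvalidConfigError(
            f"elution volume {ve} ml precedes the void volume {v0} ml"
        )
    return max(0.0, (ve - v0) / (vt - v0))


@dataclass
class CalibrationCurve:
    """Least-squares line log10(mass/kDa) = slope * K_av + intercept."""

    slope: float
    intercept: float
    v0: float
    vt: float
    standards: list[tuple[str, float, float]]  # (name, mass_kda, ve_ml)
    kav_range: tuple[float, float]


@dataclass
class MassEstimate:
    mass_kda: float
    kav: float
    extrapolated: bool


def calibrate_sec(
    standards: list[tuple[str, float, float]] | list[tuple[float, float]],
    v0: float,
    vt: float,
) -> CalibrationCurve:
    """Fit the SEC calibration line from (name, mass kDa, Ve ml) standards.

    Two standards determine the line exactly; more are fit by least squares.
    The slope must come out negative (larger species elute earlier).
    """
    named = [s if len(s) == 3 else (f"standard-{i}", *s) for i, s in enumerate(standards)]
    if len(named) < 2:
        raise InvalidConfigError("SEC calibration needs at least 2 standards")
    kavs = np.array([kav(ve, v0, vt) for _, _, ve in named])
    if np.unique(kavs).size < 2:
        raise InvalidConfigError("standards must have distinct K_av values")
    log_mass = np.log10([m for _, m, _ in named])
    slope, intercept = np.polyfit(kavs, log_mass, 1)
    return CalibrationCurve(
        slope=float(slope), intercept=float(intercept), v0=v0, vt=vt,
        standards=named, kav_range=(float(kavs.min()), float(kavs.max())),
    )


def apparent_mass(ve: float, curve: CalibrationCurve) -> MassEstimate:
    """Invert the calibration line at elution volume ``ve`` (ml).

    Estimates outside the standards' K_av range are flagged as extrapolated.
    """
    k = kav(ve, curve.v0, curve.vt)
    mass = 10.0 ** (curve.slope * k + curve.intercept)
    lo, hi = curve.kav_range
    return MassEstimate(mass_kda=float(mass), kav=k, extrapolated=not lo <= k <= hi)


def peak_shift_mass(ve1: float, ve2: float, curve: CalibrationCurve) -> float:
    """Apparent-mass change (kDa) of a peak shifting from ``ve1`` to ``ve2`` ml."""
    return apparent_mass(ve2, curve).mass_kda - apparent_mass(ve1, curve).mass_kda


def find_peak_volume(
    chrom: Chromatogram,
    window: tuple[float, float] | None = None,
    smooth_sigma_ml: float = 0.05,
) -> float:
    """Elution volume of the maximum of the smoothed signal, optionally within
    a volume window."""
    v, s = chrom.volumes, chrom.signal
    if window is not None:
        sel = (v >= window[0]) & (v <= window[1])
        if not np.any(sel):
            raise WindowError("peak-picking window contains no samples")
        v, s = v[sel], s[sel]
    dv = float(np.median(np.diff(v)))
    if smooth_sigma_ml > 0:
        s = gaussian_filter1d(s, smooth_sigma_ml / dv)
    return float(v[np.argmax(s)])


# --------------------------------------------------------------------------- #
# Surface plasmon resonance, Langmuir 1:1
# --------------------------------------------------------------------------- #

def langmuir_response(
    t: np.ndarray, k_on: float, k_off: float, rmax: float, conc: float, t_assoc: float
) -> np.ndarray:
    """Closed-form 1:1 Langmuir sensorgram over association + dissociation."""
    if k_on <= 0 or k_off <= 0 or rmax <= 0:
        raise InvalidConfigError("k_on, k_off and Rmax must be positive")
    if conc < 0:
        raise InvalidConfigError("analyte concentration must be >= 0")
    t = np.asarray(t, dtype=float)
    kd = k_off / k_on
    req = rmax * conc / (conc + kd) if conc > 0 else 0.0
    kobs = k_on * conc + k_off
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-k_off * np.clip(t - t_assoc, 0.0, None))
    return np.where(t <= t_assoc, assoc, dissoc)


@dataclass
class KineticFit:
    """Globally fitted Langmuir 1:1 kinetics. K_D is k_off/k_on by definition."""

    k_on: float
    k_off: float
    rmax: float
    k_on_stderr: float | None = None
    k_off_stderr: float | None = None
    rmax_stderr: float | None = None
    weighted_sse: float = np.nan
    n_points: int = 0
    concentrations: list[float] = field(default_factory=list)

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on


def fit_langmuir(
    sensorgrams: list,
    t_assoc: float,
    weights: np.ndarray | None = None,
    k_on_init: float = 1e5,
    k_off_init: float = 1e-2,
) -> KineticFit:
    """Global weighted least-squares fit of a sensorgram concentration series.

    ``sensorgrams`` are DataFrames with columns ``time_s``, ``response_RU`` and
    ``conc_M``; k_on, k_off and Rmax are shared across all curves.  A single
    analyte concentration cannot separate k_on from Rmax, so at least two
    distinct concentrations are required (three or more recommended).
    """
    concs = [float(np.asarray(sg["conc_M"])[0]) for sg in sensorgrams]
    if len(set(concs)) < 2:
        raise IdentifiabilityError(
            "global Langmuir fit needs >= 2 distinct analyte concentrations"
        )
    rmax_init = max(float(np.max(sg["response_RU"])) for sg in sensorgrams)

    params = Parameters()
    params.add("log_k_on", value=np.log10(k_on_init), min=0, max=12)
    params.add("log_k_off", value=np.log10(k_off_init), min=-8, max=3)
    params.add("rmax", value=max(rmax_init, 1e-6), min=1e-9)

    def residual(p: Parameters) -> np.ndarray:
        k_on, k_off = 10.0 ** p["log_k_on"].value, 10.0 ** p["log_k_off"].value
        res = [
            np.asarray(sg["response_RU"], dtype=float)
            - langmuir_response(np.asarray(sg["time_s"], dtype=float),
                                k_on, k_off, p["rmax"].value, c, t_assoc)
            for sg, c in zip(sensorgrams, concs)
        ]
        out = np.concatenate(res)
        return out if weights is None else out * weights

    result = minimize(residual, params, method="leastsq")
    k_on = 10.0 ** result.params["log_k_on"].value
    k_off = 10.0 ** result.params["log_k_off"].value

    def back_err(name: str, value: float) -> float | None:
        err = result.params[name].stderr
        return None if err is None else float(value * np.log(10.0) * err)

    return KineticFit(
        k_on=float(k_on),
        k_off=float(k_off),
        rmax=float(result.params["rmax"].value),
        k_on_stderr=back_err("log_k_on", k_on),
        k_off_stderr=back_err("log_k_off", k_off),
        rmax_stderr=(None if result.params["rmax"].stderr is None
                     else float(result.params["rmax"].stderr)),
        weighted_sse=float(result.chisqr),
        n_points=int(result.ndata),
        concentrations=concs,
    )


# --------------------------------------------------------------------------- #
# Thioflavin T normalization
# --------------------------------------------------------------------------- #

@dataclass
class ThTCurve:
    """A ThT fluorescence time course (time in minutes)."""

    time: np.ndarray
    fluorescence: np.ndarray
    normalized: bool = False
    mode: str = "free"
    plateau_warning: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.size != self.fluorescence.size:
            raise InvalidConfigError("time and fluorescence must have equal length")


def normalize_tht(
    curve: ThTCurve,
    plateau_fraction: float = 0.1,
    asymptote: float | None = None,
    slope_tolerance: float = 0.02,
) -> ThTCurve:
    """Normalize a ThT curve to 0 at t=0 and 100% at the aggregation asymptote.

    The asymptote defaults to the mean of the final ``plateau_fraction`` of
    samples of this curve; pass ``asymptote`` explicitly to normalize a
    scavenger curve against the plateau of the unhindered reference.  If the
    final segment still trends (relative change above ``slope_tolerance``
    across the segment), the output carries a plateau warning flag.
    """
    f = curve.fluorescence
    f0 = float(f[0])
    n_tail = max(2, int(round(curve.time.size * plateau_fraction)))
    tail = f[-n_tail:]
    f_asym = float(tail.mean()) if asymptote is None else float(asymptote)
    if f_asym == f0:
        raise InvalidConfigError("asymptote equals the t=0 intensity; normalization undefined")

    t_tail = curve.time[-n_tail:]
    coef, cov = np.polyfit(t_tail, tail, 1, cov=True)
    slope, slope_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    span = abs(f_asym - f0)
    trend = abs(slope) * (curve.time[-1] - curve.time[0]) / span if span > 0 else np.inf
    # flag only a trend that is both material and statistically resolvable
    warning = trend > slope_tolerance and abs(slope) > 2.0 * slope_se

    return ThTCurve(
        time=curve.time.copy(),
        fluorescence=100.0 * (f - f0) / (f_asym - f0),
        normalized=True,
        mode=curve.mode,
        plateau_warning=warning,
    )
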