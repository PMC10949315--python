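"""Enzyme-assay analysis for L-asparaginase kinetics.

Covers the colorimetric (Nessler) absorbance-to-ammonia conversion, pH-activity
profiling, Michaelis-Menten and substrate-inhibition rate laws, parameter
fitting by the classical double-reciprocal (Lineweaver-Burk) linearisation and
by nonlinear least squares, and relative-activity tables for enzyme variants.

Units throughout: substrate and enzyme concentrations in mM, velocities in
mM s^-1, turnover numbers (kcat) in s^-1, absorbances dimensionless, molar
absorption coefficients in M^-1 cm^-1, path lengths in cm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticModel",
    "AssayCalibration",
    "KineticFit",
    "PhOptimum",
    "velocity",
    "absorbance_to_ammonia",
    "fit_lineweaver_burk",
    "fit_nonlinear",
    "relative_activity",
    "ph_optimum",
]


@dataclass(frozen=True)
class KineticModel:
    """Michaelis-Menten rate law with optional single-site substrate inhibition.

    v(S) = Vmax * S / (Km + S * (1 + S / Ki))

    ``Ki = inf`` recovers the standard hyperbolic Michaelis-Menten law.
    ``Vmax`` may be given directly, or derived as ``kcat * E0``.
    """

    Km: float                      # mM
    Vmax: float | None = None      # mM / s
    Ki: float = math.inf           # mM; inf = no substrate inhibition
    kcat: float | None = None      # 1 / s
    E0: float | None = None        # mM enzyme

    def __post_init__(self) -> None:
        if not self.Km > 0:
            raise ValueError(f"Km must be positive, got {self.Km}")
        if not self.Ki > 0:
            raise ValueError(f"Ki must be positive (or inf), got {self.Ki}")
        if self.Vmax is None and (self.kcat is None or self.E0 is None):
            raise ValueError("provide Vmax, or kcat together with E0")
        if self.vmax < 0:
            raise ValueError("Vmax must be non-negative")

    @property
    def vmax(self) -> float:
        """Maximal velocity in mM/s, derived from kcat*E0 when not given."""
        if self.Vmax is not None:
            return self.Vmax
        return self.kcat * self.E0


@dataclass(frozen=True)
class AssayCalibration:
    """Calibration of the nesslerisation readout (A480 -> ammonia)."""

    epsilon_480: float = 1302.0    # M^-1 cm^-1, Nessler product at 480 nm
    path_length: float = 1.0       # cm

    def __post_init__(self) -> None:
        if self.epsilon_480 <= 0:
            raise ValueError("epsilon_480 must be positive")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")


@dataclass
class KineticFit:
    """Result of a kinetic-parameter fit.

    ``excluded`` lists (row index, reason) for data points that did not enter
    the regression.  A failed fit keeps ``model=None`` and explains itself in
    ``message``.
    """

    model: KineticModel | None
    method: str                      # "LB" or "NLS"
    residual_rms: float
    excluded: list[tuple[int, str]] = field(default_factory=list)
    success: bool = True
    message: str = ""

    @property
    def Km(self) -> float:
        return self.model.Km

    @property
    def Vmax(self) -> float:
        return self.model.vmax

    @property
    def kcat(self) -> float | None:
        return self.model.kcat


@dataclass(frozen=True)
class PhOptimum:
    """pH of maximal mean activity with degeneracy flags."""

    pH: float
    tie: bool = False     # another grid point shares the maximum
    edge: bool = False    # the maximum sits on a grid boundary


def velocity(S, model: KineticModel):
    """Reaction velocity at substrate concentration(s) ``S`` (mM).

    Vectorised over ``S``; scalar in, scalar out.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("substrate concentrations must be non-negative")
    if math.isinf(model.Ki):
        v = model.vmax * S_arr / (model.Km + S_arr)
    else:
        v = model.vmax * S_arr / (model.Km + S_arr * (1.0 + S_arr / model.Ki))
    return float(v) if np.isscalar(S) else v


def absorbance_to_ammonia(A480, calib: AssayCalibration | None = None):
    """Convert Nessler absorbance at 480 nm to ammonia concentration in mM.

    c [mM] = 1000 * A480 / (epsilon_480 * path_length).
    """
    calib = calib or AssayCalibration()
    A = np.asarray(A480, dtype=float)
    if np.any(A < 0):
        raise ValueError("absorbance must be non-negative")
    c = 1000.0 * A / (calib.epsilon_480 * calib.path_length)
    return float(c) if np.isscalar(A480) else c


def _prepare(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not {"S_mM", "v"} <= set(dataset.columns):
        raise ValueError("dataset needs columns 'S_mM' and 'v'")
    S = dataset["S_mM"].to_numpy(dtype=float)
    v = dataset["v"].to_numpy(dtype=float)
    if "blank" in dataset.columns:
        v = v - dataset["blank"].to_numpy(dtype=float)
    return S, v, np.asarray(dataset.index)


def fit_lineweaver_burk(
    dataset: pd.DataFrame,
    S_max: float = 5.0,
    E0: float | None = None,
) -> KineticFit:
    """Fit Km and Vmax by ordinary least squares on the double-reciprocal plot.

    Points with S > ``S_max`` are excluded by default because substrate
    inhibition above that concentration breaks the linearity of 1/v vs 1/S;
    non-positive velocities are excluded with a warning.  Km = slope/intercept
    and Vmax = 1/intercept; kcat = Vmax/E0 when the enzyme concentration E0
    (mM) is known.
    """
    S, v, idx = _prepare(dataset)
    excluded: list[tuple[int, str]] = []
    keep = np.ones(len(S), dtype=bool)
    for i in range(len(S)):
        if S[i] > S_max:
            keep[i] = False
            excluded.append((int(idx[i]), f"S > {S_max} mM (substrate-inhibition range)"))
        elif v[i] <= 0:
            keep[i] = False
            excluded.append((int(idx[i]), "non-positive velocity"))
            warnings.warn(f"excluding point {idx[i]}: non-positive velocity")
    if keep.sum() < 3:
        return KineticFit(None, "LB", math.nan, excluded, success=False,
                          message="fewer than 3 usable points")
    x, y = 1.0 / S[keep], 1.0 / v[keep]
    res = stats.linregress(x, y)
    if res.intercept <= 0:
        return KineticFit(None, "LB", math.nan, excluded, success=False,
                          message="non-positive 1/Vmax intercept")
    Vmax = 1.0 / res.intercept
    Km = res.slope / res.intercept
    if Km <= 0:
        return KineticFit(None, "LB", math.nan, excluded, success=False,
                          message="non-positive Km")
    kcat = Vmax / E0 if E0 else None
    model = KineticModel(Km=Km, Vmax=Vmax, kcat=kcat, E0=E0)
    resid = y - (res.intercept + res.slope * x)
    return KineticFit(model, "LB", float(np.sqrt(np.mean(resid**2))), excluded)


def fit_nonlinear(
    dataset: pd.DataFrame,
    with_inhibition: bool = False,
    E0: float | None = None,
) -> KineticFit:
    """Nonlinear least-squares fit of the rate law to (S, v) data.

    Starting values: Vmax0 = 1.2*max(v), Km0 = S at half-maximal observed
    velocity, Ki0 = 10*max(S).  Parameters are constrained positive.  On
    non-convergence the best iterate is returned with ``success=False``.
    """
    S, v, idx = _prepare(dataset)
    excluded = [(int(i), "negative velocity") for i, vi in zip(idx, v) if vi < 0]
    keep = v >= 0
    S, v = S[keep], v[keep]
    n_min = 5 if with_inhibition else 4
    if len(S) < n_min:
        return KineticFit(None, "NLS", math.nan, excluded, success=False,
                          message=f"need at least {n_min} points")

    vmax0 = 1.2 * float(v.max()) if v.max() > 0 else 1.0
    half = np.abs(v - v.max() / 2.0)
    km0 = max(float(S[int(np.argmin(half))]), 1e-6)

    if with_inhibition:
        def f(s, vmax, km, ki):
            return vmax * s / (km + s * (1.0 + s / ki))
        p0 = [vmax0, km0, 10.0 * float(S.max())]
    else:
        def f(s, vmax, km):
            return vmax * s / (km + s)
        p0 = [vmax0, km0]

    try:
        popt, _ = optimize.curve_fit(
            f, S, v, p0=p0, bounds=(1e-12, np.inf),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        success, message = True, ""
    except RuntimeError as exc:       # max evaluations: keep best effort p0 path
        popt, success, message = np.asarray(p0), False, str(exc)

    ki = float(popt[2]) if with_inhibition else math.inf
    kcat = float(popt[0]) / E0 if E0 else None
    model = KineticModel(Km=float(popt[1]), Vmax=float(popt[0]), Ki=ki,
                         kcat=kcat, E0=E0)
    resid = v - f(S, *popt)
    return KineticFit(model, "NLS", float(np.sqrt(np.mean(resid**2))),
                      excluded, success=success, message=message)


def relative_activity(
    variant_rate: float,
    wt_rate: float,
    detection_floor_pct: float = 0.1,
) -> float:
    """Variant activity as a percentage of wild type.

    Values below ``detection_floor_pct`` (default 0.1%, i.e. a turnover three
    orders of magnitude below wild type) are reported as 0.0 -- such variants
    are deemed inactive.
    """
    if wt_rate <= 0:
        raise ValueError("wild-type rate must be positive")
    if variant_rate < 0:
        raise ValueError("rates must be non-negative")
    pct = 100.0 * variant_rate / wt_rate
    return 0.0 if pct < detection_floor_pct else pct


def ph_optimum(profile: pd.DataFrame) -> PhOptimum:
    """Grid point of maximal mean activity on a (pH, activity) table.

    Replicate rows at the same pH are averaged.  Ties are broken toward the
    lower pH and flagged; a maximum on the first or last grid point is flagged
    as an edge (the true optimum may lie outside the assayed range).
    """
    if not {"pH", "activity"} <= set(profile.columns):
        raise ValueError("profile needs columns 'pH' and 'activity'")
    if len(profile) < 2:
        raise ValueError("need at least 2 profile points")
    means = profile.groupby("pH")["activity"].mean().sort_index()
    best = means.max()
    winners = means.index[np.isclose(means.to_numpy(), best)]
    opt = float(winners.min())
    grid = means.index.to_numpy()
    return PhOptimum(
        pH=opt,
        tie=len(winners) > 1,
        edge=bool(np.isclose(opt, grid[0]) or np.isclose(opt, grid[-1])),
    )
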