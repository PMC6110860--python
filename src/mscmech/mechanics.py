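"""Membrane mechanics of aspirated patches.

Implements the quantitative core of the micropipette-aspiration (MA)
analysis of soft bacterial membranes:

* Laplace's law ``T = P * R_d / 2`` relating suction to membrane tension,
* the aspirated-membrane surface area of a conical pipette (lateral
  frustum surface plus spherical dome cap),
* the areal strain ``alpha = (A - A0) / A0``, and
* the areal elasticity (expansion) modulus ``K_A``, the slope of membrane
  tension versus areal strain.

The modulus fit is exposed as a scikit-learn style estimator
(:class:`ElasticityRegressor`); :func:`fit_elasticity` and
:func:`ma_pipeline` are thin wrappers over it.

Units: pressures in mmHg (magnitudes), lengths in um, tensions in mN/m,
areas in um^2 (any consistent area unit works for strains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateFitError, InvalidGeometryError, InvalidInputError
from .units import MMHG_TO_PA, NM_PER_M_TO_MN_PER_M, UM_TO_M

__all__ = [
    "PatchGeometry",
    "TensionStrainSeries",
    "ElasticityEstimate",
    "ElasticityRegressor",
    "laplace_tension",
    "aspirated_area",
    "areal_strain",
    "fit_elasticity",
    "ma_pipeline",
]


@dataclass(frozen=True)
class PatchGeometry:
    """Shape of an aspirated membrane patch in a conical pipette.

    Parameters
    ----------
    tip_radius : float
        Pipette radius ``r`` at the tip, um.
    dome_radius : float
        Pipette radius ``R`` at the dome, um.
    protrusion_length : float
        Length ``L`` of the membrane pulled into the pipette, um.
    dome_height : float
        Height ``h`` of the spherical dome cap, um.
    curvature_radius : float
        Radius of curvature ``R_d`` of the membrane patch, um.  Only
        required (> 0) when the geometry is used for tension.
    """

    tip_radius: float
    dome_radius: float
    protrusion_length: float = 0.0
    dome_height: float = 0.0
    curvature_radius: float = 0.0

    def __post_init__(self):
        for name in ("tip_radius", "dome_radius", "protrusion_length",
                     "dome_height", "curvature_radius"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidGeometryError(
                    f"{name} must be finite and >= 0, got {value!r}")
        if self.dome_height > 2.0 * self.dome_radius:
            raise InvalidGeometryError(
                "dome_height exceeds the sphere diameter "
                f"({self.dome_height} > 2*{self.dome_radius})")


@dataclass(frozen=True)
class TensionStrainSeries:
    """Paired (pressure, tension, area) points of one aspiration experiment.

    Strain is derived, not stored, so ``alpha = (A - A0)/A0`` holds exactly
    by construction.  Pressures keep the protocol's sign convention
    (suction negative); tensions are magnitudes.
    """

    pressure: np.ndarray       # mmHg, signed
    tension: np.ndarray        # mN/m
    area: np.ndarray           # um^2 (or nm^2; only ratios matter)
    reference_area: np.ndarray

    def __post_init__(self):
        arrays = {}
        for name in ("pressure", "tension", "area", "reference_area"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = len(arrays["pressure"])
        if any(len(a) != n for a in arrays.values()):
            raise InvalidInputError("all series columns must have equal length")
        if np.any(arrays["reference_area"] <= 0):
            raise InvalidInputError("reference_area must be > 0 for every point")
        if np.any(arrays["tension"] < 0):
            raise InvalidInputError("tension must be >= 0 (magnitudes)")

    @property
    def strain(self) -> np.ndarray:
        return (self.area - self.reference_area) / self.reference_area

    def __len__(self) -> int:
        return len(self.pressure)

    def to_records(self):
        """Points as a list of plain dicts (for JSON reports)."""
        return [
            {
                "pressure_mmHg": float(p),
                "tension_mN_per_m": float(t),
                "area": float(a),
                "strain": float(s),
            }
            for p, t, a, s in zip(self.pressure, self.tension, self.area, self.strain)
        ]


@dataclass(frozen=True)
class ElasticityEstimate:
    """Fitted areal elasticity modulus with its uncertainty."""

    K_A: float           # mN/m, slope of tension on strain
    intercept: float     # mN/m, tension at zero strain
    stderr_K_A: float    # mN/m
    n_points: int
    r_squared: float

    def __post_init__(self):
        if self.n_points < 2:
            raise InvalidInputError("an elasticity estimate needs >= 2 points")
        if self.stderr_K_A < 0:
            raise InvalidInputError("stderr_K_A must be >= 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidInputError("r_squared must lie in [0, 1]")


def laplace_tension(pressure_mmhg, curvature_radius_um):
    """Membrane tension from Laplace's law, ``T = P * R_d / 2``.

    Parameters
    ----------
    pressure_mmhg : float or array
        Magnitude of the applied suction, mmHg (>= 0).
    curvature_radius_um : float
        Radius of curvature of the membrane patch, um (> 0).

    Returns
    -------
    float or ndarray
        Tension in mN/m.  Linear in both arguments.
    """
    pressure = np.asarray(pressure_mmhg, dtype=float)
    if not np.all(np.isfinite(pressure)) or np.any(pressure < 0):
        raise InvalidInputError(
            "pressure must be a finite magnitude >= 0 (pass abs() of suction)")
    radius = float(curvature_radius_um)
    if not math.isfinite(radius) or radius <= 0:
        raise InvalidGeometryError(f"curvature radius must be > 0, got {radius!r}")
    tension_si = pressure * MMHG_TO_PA * (radius * UM_TO_M) / 2.0
    tension = tension_si * NM_PER_M_TO_MN_PER_M
    return float(tension) if np.isscalar(pressure_mmhg) else tension


def aspirated_area(geometry: PatchGeometry) -> float:
    """Surface area of the membrane aspirated into a conical pipette.

    Lateral surface of the conical frustum between tip radius ``r`` and
    dome radius ``R`` over protrusion length ``L``, plus the spherical cap
    of the dome, ``2 pi R h``::

        A = pi (r + R) sqrt((R - r)^2 + L^2) + 2 pi R h

    Returns the area in um^2.
    """
    r, R = geometry.tip_radius, geometry.dome_radius
    L, h = geometry.protrusion_length, geometry.dome_height
    frustum = math.pi * (r + R) * math.sqrt((R - r) ** 2 + L ** 2)
    cap = 2.0 * math.pi * R * h
    return frustum + cap


def areal_strain(area, reference_area):
    """Fractional area change ``alpha = (A - A0) / A0``."""
    a0 = np.asarray(reference_area, dtype=float)
    if np.any(a0 <= 0):
        raise InvalidInputError("reference area must be > 0")
    out = (np.asarray(area, dtype=float) - a0) / a0
    return float(out) if np.isscalar(area) and np.isscalar(reference_area) else out


class ElasticityRegressor(BaseEstimator, RegressorMixin):
    """Least-squares estimator of the areal elasticity modulus K_A.

    Fits the quasi-linear tension-strain relation ``T = K_A * alpha + T0``.

    Parameters
    ----------
    fit_intercept : bool, default True
        Whether to include the free intercept ``T0``.  The constrained
        (through-origin) variant is exposed because the noiseless law has
        no offset; the free intercept is the default so users can check
        that the fitted offset is near zero.
    method : {"ols", "inverse"}, default "ols"
        ``"ols"`` regresses tension on strain (the textbook slope
        definition).  ``"inverse"`` regresses strain on tension and
        reports ``K_A = 1/slope``: the calibration form appropriate when
        tension is the controlled variable and the measurement noise lives
        in the geometry-derived strain, which avoids errors-in-variables
        attenuation of the modulus.

    Attributes
    ----------
    modulus_ : float
        Fitted K_A, mN/m.
    intercept_ : float
        Tension offset at zero strain, mN/m.
    stderr_ : float
        Standard error of ``modulus_``, mN/m.
    r_squared_ : float
    n_points_ : int
    estimate_ : ElasticityEstimate
    """

    def __init__(self, fit_intercept: bool = True, method: str = "ols"):
        self.fit_intercept = fit_intercept
        self.method = method

    def fit(self, X, y):
        """Fit the modulus from strain (X) and tension (y)."""
        alpha = np.asarray(X, dtype=float).reshape(-1)
        tension = np.asarray(y, dtype=float).reshape(-1)
        if alpha.shape != tension.shape:
            raise InvalidInputError("strain and tension must have equal length")
        if self.method not in ("ols", "inverse"):
            raise InvalidInputError(f"unknown method {self.method!r}")
        x, resp = (alpha, tension) if self.method == "ols" else (tension, alpha)
        if len(np.unique(x)) < 2:
            raise DegenerateFitError(
                "need >= 2 distinct abscissa values to identify a slope")

        if self.fit_intercept:
            res = stats.linregress(x, resp)
            slope, intercept, stderr = res.slope, res.intercept, res.stderr
            r2 = float(res.rvalue ** 2)
        else:
            sxx = float(np.dot(x, x))
            slope = float(np.dot(x, resp)) / sxx
            resid = resp - slope * x
            dof = max(len(x) - 1, 1)
            stderr = math.sqrt(float(np.dot(resid, resid)) / dof / sxx)
            # uncentered R^2 keeps the value in [0, 1] for origin fits
            sst = float(np.dot(resp, resp))
            r2 = 1.0 - float(np.dot(resid, resid)) / sst if sst > 0 else 1.0
            intercept = 0.0

        if self.method == "ols":
            self.modulus_ = float(slope)
            self.intercept_ = float(intercept)
            self.stderr_ = float(stderr) if stderr is not None else 0.0
        else:
            if slope == 0:
                raise DegenerateFitError("zero strain-on-tension slope; K_A undefined")
            self.modulus_ = float(1.0 / slope)
            # tension at zero strain implied by the calibration line
            self.intercept_ = float(-intercept / slope)
            self.stderr_ = float(stderr / slope ** 2) if stderr is not None else 0.0
        self.r_squared_ = min(max(r2, 0.0), 1.0)
        self.n_points_ = int(len(alpha))
        self.estimate_ = ElasticityEstimate(
            K_A=self.modulus_, intercept=self.intercept_,
            stderr_K_A=self.stderr_, n_points=self.n_points_,
            r_squared=self.r_squared_)
        return self

    def predict(self, X):
        """Predicted tension (mN/m) at the given strains."""
        alpha = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.modulus_ * alpha


def fit_elasticity(series: TensionStrainSeries, fit_intercept: bool = True,
                   method: str = "ols") -> ElasticityEstimate:
    """Fit K_A from a tension-strain series (see :class:`ElasticityRegressor`)."""
    reg = ElasticityRegressor(fit_intercept=fit_intercept, method=method)
    reg.fit(series.strain, series.tension)
    return reg.estimate_


def ma_pipeline(pressure_steps, geometries, reference_geometry: PatchGeometry,
                fit_intercept: bool = True, method: str = "inverse"):
    """Full micropipette-aspiration analysis.

    Composes Laplace tension, aspirated area, areal strain and the
    elasticity fit.  ``method`` defaults to the inverse-calibration fit
    because the suction steps are controlled exactly while the geometry
    (hence strain) is the measured, noisy quantity.

    Parameters
    ----------
    pressure_steps : sequence of float
        Applied pressures, mmHg; suction is negative by convention and
        magnitudes are taken internally.
    geometries : sequence of PatchGeometry
        One measured geometry per pressure step.
    reference_geometry : PatchGeometry
        Geometry at zero pressure; its area is the reference area A0.

    Returns
    -------
    (TensionStrainSeries, ElasticityEstimate)
    """
    pressures = np.asarray(pressure_steps, dtype=float)
    geometries = list(geometries)
    if len(pressures) != len(geometries):
        raise InvalidInputError(
            f"{len(pressures)} pressures but {len(geometries)} geometries")
    a0 = aspirated_area(reference_geometry)
    tension = np.array([
        laplace_tension(abs(p), g.curvature_radius)
        for p, g in zip(pressures, geometries)
    ])
    area = np.array([aspirated_area(g) for g in geometries])
    series = TensionStrainSeries(
        pressure=pressures, tension=tension, area=area,
        reference_area=np.full(len(pressures), a0))
    estimate = fit_elasticity(series, fit_intercept=fit_intercept, method=method)
    return series, estimate
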