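"""Slab-averaged bilayer areas from stretched-bilayer simulations.

A stretched bilayer's cross-sectional area is not uniform along its
thickness, so the area observable is averaged over N slabs between the
phosphate planes and over M trajectories::

    A = sum_{m=1..M} sum_{i=1..N} A_i / (M * N)

The tension-strain response of the bilayer then yields the areal
elasticity modulus through the same strain definition and least-squares
slope used for the micropipette-aspiration analysis (areas in nm^2; the
strain is unit-free).  Slab areas are consumed as precomputed matrices;
extracting them from raw trajectories is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InvalidInputError
from .mechanics import ElasticityEstimate, TensionStrainSeries, areal_strain, fit_elasticity

__all__ = ["SlabAreaSeries", "mean_bilayer_area", "md_elasticity"]


@dataclass(frozen=True)
class SlabAreaSeries:
    """M trajectories x N slabs of bilayer cross-sectional areas at one tension.

    ``equilibration_exclusion`` drops that many leading trajectories
    before averaging, for runs whose first repeats are not yet steady
    after the tension is switched on.
    """

    applied_tension: float          # mN/m
    areas: np.ndarray               # (M, N), nm^2
    equilibration_exclusion: int = 0

    def __post_init__(self):
        areas = np.atleast_2d(np.asarray(self.areas, dtype=float))
        object.__setattr__(self, "areas", areas)
        if areas.size == 0:
            raise InvalidInputError("areas matrix must be non-empty")
        if np.any(~np.isfinite(areas)) or np.any(areas <= 0):
            raise InvalidInputError("all slab areas must be finite and > 0")
        if self.applied_tension < 0:
            raise InvalidInputError("applied tension must be >= 0")
        if not 0 <= self.equilibration_exclusion < areas.shape[0]:
            raise InvalidInputError(
                "equilibration_exclusion must leave at least one trajectory")

    @property
    def n_trajectories(self) -> int:
        return self.areas.shape[0]

    @property
    def n_slabs(self) -> int:
        return self.areas.shape[1]


def mean_bilayer_area(series: SlabAreaSeries) -> float:
    """Grand mean area over retained trajectories and all slabs, nm^2."""
    retained = series.areas[series.equilibration_exclusion:]
    if retained.size == 0:
        raise InvalidInputError("all trajectories excluded")
    return float(retained.mean())


def md_elasticity(series_per_tension, zero_tension_series: SlabAreaSeries,
                  fit_intercept: bool = True, method: str = "ols"):
    """Areal elasticity modulus from slab-area matrices.

    Strain at each applied tension is computed against the zero-tension
    reference mean area; the modulus is the free-intercept least-squares
    slope of tension on strain (the same fit applied to the experimental
    aspiration data, for comparability).

    Returns
    -------
    (TensionStrainSeries, ElasticityEstimate)
    """
    series_list = list(series_per_tension)
    if zero_tension_series is None:
        raise InvalidInputError("zero-tension reference series is required")
    if len(series_list) < 2:
        raise DegenerateFitError("need >= 2 applied tensions")
    a0 = mean_bilayer_area(zero_tension_series)
    tensions = np.array([s.applied_tension for s in series_list])
    areas = np.array([mean_bilayer_area(s) for s in series_list])
    ts_series = TensionStrainSeries(
        pressure=np.full(len(series_list), np.nan),
        tension=tensions, area=areas,
        reference_area=np.full(len(series_list), a0))
    estimate = fit_elasticity(ts_series, fit_intercept=fit_intercept, method=method)
    return ts_series, estimate
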