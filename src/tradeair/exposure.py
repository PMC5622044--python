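"""Gridded PM2.5 exposure: dispersion surrogate, change ratios, calibration.

The chemistry-transport step is represented by a linear source-receptor
surrogate (per-pollutant exponential-decay kernels from province centroids),
so counterfactual concentration fields are exact linear images of the
scenario emission vectors.  Modelled fields are never reported as exposure:
they enter only through the spatial change ratio

    A = 1 - C_m,scenario / C_m,baseline ,

which is applied to the satellite-calibrated total to split it into a
trade-attributable part ``C_TRE = C_sat * A`` and a counterfactual part
``C_noTRE = C_sat - C_TRE``.
"""

from __future__ import annotations

import logging

import numpy as np
import xarray as xr

from .scenarios import ScenarioEmissions
from .synthetic import DispersionKernelSet

logger = logging.getLogger(__name__)

#: floor (ug/m3) below which the baseline is treated as zero in change ratios
RATIO_FLOOR = 1e-6


class ExposureError(ValueError):
    """Raised for inconsistent gridded inputs."""


def _wrap(values: np.ndarray, like: xr.DataArray | None, name: str, units: str) -> xr.DataArray:
    if like is not None:
        return xr.DataArray(values, dims=like.dims, coords=like.coords,
                            name=name, attrs={"units": units})
    ny, nx = values.shape
    return xr.DataArray(values, dims=("y", "x"),
                        coords={"y": np.arange(ny), "x": np.arange(nx)},
                        name=name, attrs={"units": units})


def disperse(
    emissions: ScenarioEmissions | np.ndarray,
    kernels: DispersionKernelSet,
) -> xr.DataArray:
    """Map regional emissions (Mt) to a concentration field (ug/m3).

    field = background + sum_p beta_p * sum_r E[p, r] * weights[p, r, :, :].
    Deterministic and linear in the anthropogenic component.
    """
    E = emissions.values if isinstance(emissions, ScenarioEmissions) else np.asarray(emissions, float)
    P, R = kernels.weights.shape[:2]
    if E.shape != (P, R):
        raise ExposureError(
            f"emissions shape {E.shape} does not match kernels ({P} pollutants, {R} regions)"
        )
    beta = np.array([kernels.beta[p] for p in kernels.pollutants])
    field = kernels.background + np.einsum(
        "p,pr,pryx->yx", beta, E, kernels.weights
    )
    return _wrap(field, None, "pm25", "ug m-3")


def change_ratio(
    C_mtotal: xr.DataArray, C_mnoTRE: xr.DataArray, floor: float = RATIO_FLOOR
) -> xr.DataArray:
    """Spatial change ratio A = 1 - C_m,scenario / C_m,baseline.

    Cells whose baseline is below ``floor`` get A = 0 (count logged); an
    all-zero baseline is rejected.  A may be negative where the scenario
    raises the modelled concentration.
    """
    base = np.asarray(C_mtotal, float)
    scen = np.asarray(C_mnoTRE, float)
    if base.shape != scen.shape:
        raise ExposureError("grids of the two modelled fields differ")
    low = base <= floor
    if low.all():
        raise ExposureError("baseline modelled field is zero everywhere")
    if low.any():
        logger.warning("change_ratio: %d cells below floor set to A=0", int(low.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(low, 0.0, 1.0 - scen / np.where(low, 1.0, base))
    out = _wrap(A, C_mtotal if isinstance(C_mtotal, xr.DataArray) else None,
                "change_ratio", "1")
    return out


def upsample_ratio(A: xr.DataArray, target_shape: tuple[int, int]) -> xr.DataArray:
    """Nearest-cell replication of a coarse ratio field onto a finer grid.

    The target shape must be an integer multiple of the source shape in both
    dimensions (a coarse model grid mapped onto the satellite grid).
    """
    vals = np.asarray(A, float)
    ny, nx = vals.shape
    ty, tx = target_shape
    if ty % ny or tx % nx:
        raise ExposureError(
            f"target {target_shape} is not an integer refinement of {vals.shape}"
        )
    out = np.repeat(np.repeat(vals, ty // ny, axis=0), tx // nx, axis=1)
    return _wrap(out, None, "change_ratio", "1")


def decompose_exposure(
    C_sattotal: xr.DataArray, A: xr.DataArray
) -> tuple[xr.DataArray, xr.DataArray]:
    """Split the satellite total into (C_TRE, C_noTRE).

    C_TRE = C_sat * A (may be negative for relocation scenarios) and
    C_noTRE = C_sat - C_TRE, so additivity is exact by construction.  A
    coarser ratio grid is replicated onto the satellite grid first.
    """
    sat = np.asarray(C_sattotal, float)
    if A.shape != sat.shape:
        A = upsample_ratio(A, sat.shape)
    a = np.asarray(A, float)
    C_TRE = sat * a
    C_noTRE = sat - C_TRE
    like = C_sattotal if isinstance(C_sattotal, xr.DataArray) else None
    return (
        _wrap(C_TRE, like, "C_TRE", "ug m-3"),
        _wrap(C_noTRE, like, "C_noTRE", "ug m-3"),
    )


def population_weighted_mean(
    C: xr.DataArray, pop: xr.DataArray, mask: np.ndarray | None = None
) -> float:
    """Population-weighted mean concentration over the (masked) domain."""
    c = np.asarray(C, float)
    p = np.asarray(pop, float)
    if c.shape != p.shape:
        raise ExposureError("concentration and population grids differ")
    if mask is not None:
        m = np.asarray(mask, bool)
        c, p = c[m], p[m]
    tot = p.sum()
    if tot <= 0:
        raise ExposureError("zero total population in mask")
    return float((p * c).sum() / tot)


def regrid_population(pop_fine: xr.DataArray, factor: int) -> xr.DataArray:
    """Conservative sum-aggregation of population onto a coarser grid.

    ``factor`` must divide both grid dimensions; the national total is
    preserved exactly.
    """
    vals = np.asarray(pop_fine, float)
    if factor < 1 or int(factor) != factor:
        raise ExposureError("aggregation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return pop_fine.copy()
    ny, nx = vals.shape
    if ny % factor or nx % factor:
        raise ExposureError(
            f"factor {factor} does not divide grid shape {(ny, nx)}"
        )
    coarse = vals.reshape(ny // factor, factor, nx // factor, factor).sum(axis=(1, 3))
    return _wrap(coarse, None, "population", "persons per cell")
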