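"""Synthetic world generator: a desk-scale economy-emissions-exposure testbed.

Emulates, with known ground truth, the study system the pipeline is built
for: a set of domestic provinces (a low-emission-intensity, high-consumption
"coastal" half and a high-intensity, intermediate-exporting "interior" half)
linked to foreign regions through trade, pollutant emissions proportional to
sectoral output, a linear source-receptor dispersion surrogate on a lattice
grid (secondary-PM precursors travel farther than primary PM2.5), a noisy
satellite-like PM2.5 retrieval, heterogeneous population, and ensembles of
integrated exposure-response (IER) parameters for four mortality endpoints.

Everything is seed-reproducible; all defaults are chosen once to give
realistic magnitudes (provincial outputs of order 10^2-10^3 billion US$,
SO2 intensities of a few g/US$, PM2.5 of tens of ug/m3, national population
of order 2x10^8) and are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .mrio import LinkedMRIOTable, MRIOError, technical_coefficients

#: pollutants carried through the pipeline; SO2 and NOx are secondary-PM2.5
#: precursors and get longer dispersion decay lengths than primary PM2.5
POLLUTANTS = ["PM25", "SO2", "NOx"]

ENDPOINTS = ["IHD", "COPD", "stroke", "LC"]

_SECTOR_NAMES = ["heavy_industry", "manufacturing", "services",
                 "agriculture", "transport", "construction"]

# sectoral emission-intensity multipliers (heavy industry dirtiest)
_SECTOR_FACTORS = [3.0, 1.2, 0.3, 0.8, 1.5, 1.0]

# base intensities for domestic coastal regions, g pollutant per US$
_BASE_INTENSITY = {"PM25": 1.5, "SO2": 3.5, "NOx": 3.0}

# dispersion decay lengths, km (secondary precursors > primary)
_DECAY_KM = {"PM25": 60.0, "SO2": 150.0, "NOx": 120.0}

# transfer coefficients: ug/m3 at a cell per Mt emitted per unit kernel weight
# (secondary formation is less than unit-efficient)
_BETA = {"PM25": 4500.0, "SO2": 2200.0, "NOx": 1500.0}

# central IER parameters per endpoint: C0 (ug/m3), alpha, gamma, delta
_IER_CENTRAL = {
    "IHD": (6.9, 1.40, 0.035, 0.80),
    "COPD": (7.3, 0.60, 0.012, 0.85),
    "stroke": (7.5, 1.20, 0.028, 0.70),
    "LC": (7.2, 0.55, 0.015, 0.75),
}

# draw dispersion (lognormal coefficients of variation) per parameter
_IER_CV = {"C0": 0.15, "alpha": 0.25, "gamma": 0.30, "delta": 0.10}

# national baseline mortality incidence, deaths per person-year
_INCIDENCE = {"IHD": 0.00110, "COPD": 0.00090, "stroke": 0.00160, "LC": 0.00045}


class WorldGenerationError(RuntimeError):
    """Raised when a configuration cannot yield a valid world."""


@dataclass
class WorldConfig:
    """Knobs of the synthetic world.

    Parameters
    ----------
    n_domestic : int
        Number of provinces (>= 2); the first half is "coastal" (clean,
        consumption-heavy), the second half "interior" (dirty,
        intermediate-exporting).
    n_foreign : int
        Number of foreign trade partners.
    n_sectors : int
        Sectors per region.
    grid_shape : (int, int)
        Lattice rows x cols of the domestic domain.
    cell_km : float
        Cell edge length in km (default 10, matching a 10x10 km exposure grid).
    seed : int
        Master RNG seed; every generated artifact is bit-reproducible.
    intensity_gradient : float
        Ratio of interior to coastal emission intensity (>= 1 for the
        asymmetry the pipeline is designed to resolve).
    satellite_noise_cv : float
        Coefficient of variation of the multiplicative lognormal noise of the
        satellite-like retrieval.
    background : float
        Natural (non-anthropogenic) PM2.5, ug/m3.
    n_draws : int
        Size of the IER parameter ensemble (1000 by convention).
    """

    n_domestic: int = 6
    n_foreign: int = 3
    n_sectors: int = 3
    grid_shape: tuple[int, int] = (60, 60)
    cell_km: float = 10.0
    seed: int = 0
    intensity_gradient: float = 3.0
    satellite_noise_cv: float = 0.2
    background: float = 8.0
    n_draws: int = 1000
    pollutants: tuple[str, ...] = tuple(POLLUTANTS)

    def __post_init__(self) -> None:
        if self.n_domestic < 2:
            raise ValueError("need n_domestic >= 2: interprovincial trade must exist")
        if min(self.n_foreign, self.n_sectors, self.n_draws) < 1:
            raise ValueError("all counts must be >= 1")
        if self.satellite_noise_cv < 0:
            raise ValueError("satellite_noise_cv must be >= 0")
        if self.intensity_gradient < 1:
            raise ValueError("intensity_gradient must be >= 1")
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))

    @property
    def n_coastal(self) -> int:
        return self.n_domestic // 2

    @property
    def region_names(self) -> list[str]:
        dom = [f"coastal_{i+1}" for i in range(self.n_coastal)] + [
            f"interior_{i+1}" for i in range(self.n_domestic - self.n_coastal)
        ]
        return dom + [f"foreign_{i+1}" for i in range(self.n_foreign)]

    @property
    def sector_names(self) -> list[str]:
        names = list(_SECTOR_NAMES)
        while len(names) < self.n_sectors:
            names.append(f"sector_{len(names)+1}")
        return names[: self.n_sectors]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for a named sub-stream of the master seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(16)[stream])


@dataclass
class DispersionKernelSet:
    """Normalized source-receptor kernels plus the metadata to rebuild them.

    ``weights[p, r]`` is an (ny, nx) field summing to 1: the share of
    pollutant p emitted by domestic region r arriving at each cell.  The
    concentration contribution is ``beta[p] * emission_Mt * weights``.
    """

    pollutants: list[str]
    regions: list[str]  # domestic regions only
    weights: np.ndarray  # (P, R_dom, ny, nx)
    centroids: np.ndarray  # (R_dom, 2) in cell coordinates (row, col)
    decay_km: dict[str, float]
    beta: dict[str, float]
    background: float
    cell_km: float


@dataclass
class IERParameterDraws:
    """Ensemble of IER curve parameters; draw 0 is the central estimate."""

    table: pd.DataFrame  # columns: endpoint, draw, C0, alpha, gamma, delta

    @property
    def endpoints(self) -> list[str]:
        return list(dict.fromkeys(self.table["endpoint"]))

    @property
    def n_draws(self) -> int:
        return int(self.table["draw"].max()) + 1

    def params(self, endpoint: str, draw: int) -> tuple[float, float, float, float]:
        row = self.table[(self.table.endpoint == endpoint) & (self.table.draw == draw)]
        if row.empty:
            raise KeyError(f"no draw {draw} for endpoint {endpoint}")
        r = row.iloc[0]
        return float(r.C0), float(r.alpha), float(r.gamma), float(r.delta)

    def arrays(self, endpoint: str) -> np.ndarray:
        """(n_draws, 4) array of (C0, alpha, gamma, delta), ordered by draw."""
        sub = self.table[self.table.endpoint == endpoint].sort_values("draw")
        return sub[["C0", "alpha", "gamma", "delta"]].to_numpy(float)


@dataclass
class SyntheticWorld:
    """Complete generated world: every pipeline input plus labels."""

    config: WorldConfig
    economy: LinkedMRIOTable
    intensities: np.ndarray  # (P, R*S), Mt per billion US$
    production_emissions: np.ndarray  # (P, R*S), Mt
    population: xr.DataArray  # persons per cell
    region_map: xr.DataArray  # int province index per cell
    kernels: DispersionKernelSet
    satellite: xr.DataArray | None = None  # filled once the baseline field exists
    ier_draws: IERParameterDraws | None = None
    incidence: dict[str, float] = field(default_factory=dict)
    income: pd.DataFrame | None = None  # per-capita income, domestic regions

    @property
    def pollutants(self) -> list[str]:
        return list(self.config.pollutants)


# ---------------------------------------------------------------------------
# economy
# ---------------------------------------------------------------------------

def generate_economy(config: WorldConfig) -> LinkedMRIOTable:
    """Sample a balanced, productive linked economy.

    Technical-coefficient columns are Dirichlet compositions scaled to column
    sums <= 0.65, which bounds the spectral radius below 1 by construction;
    final demand is sampled so that coastal provinces and foreign partners
    are consumption-heavy while interior provinces supply intermediates.
    The returned table satisfies x = Z.1 + Y.1 exactly (x is defined as that
    row sum).
    """
    rng = config.rng(0)
    Rd, Rf, S = config.n_domestic, config.n_foreign, config.n_sectors
    R, n = Rd + Rf, (Rd + Rf) * S
    nc = config.n_coastal
    is_dom = np.arange(R) < Rd
    is_coastal = np.arange(R) < nc
    is_interior = is_dom & ~is_coastal

    region_of = np.repeat(np.arange(R), S)
    sector_of = np.tile(np.arange(S), R)

    # --- technical coefficients -------------------------------------------
    W = np.full((n, n), 0.4)
    same_region = region_of[:, None] == region_of[None, :]
    W[same_region] += 2.5
    W += 1.2 * (is_interior[region_of][:, None] & is_dom[region_of][None, :])
    W += 0.6 * (is_dom[region_of][:, None] & ~is_dom[region_of][None, :])
    W[sector_of == 0, :] += 0.5  # heavy industry supplies everyone

    col_sums = rng.uniform(0.35, 0.65, size=n)
    A = np.empty((n, n))
    for j in range(n):
        A[:, j] = rng.dirichlet(2.0 * W[:, j]) * col_sums[j]

    for _ in range(3):  # defensive: construction already bounds the radius
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        if rho < 0.95:
            break
        A *= 0.7 / rho
    else:
        raise WorldGenerationError(
            f"could not rescale coefficients to spectral radius < 1 (rho={rho:.3f})"
        )

    # --- final demand ------------------------------------------------------
    totals = np.where(
        is_coastal, rng.uniform(140.0, 200.0, R),
        np.where(is_dom, rng.uniform(40.0, 70.0, R), rng.uniform(80.0, 140.0, R)),
    )  # billion US$ per consuming region
    Y = np.empty((n, R))
    for c in range(R):
        w = np.full(n, 0.3)
        w[region_of == c] += 2.5  # home bias
        if is_coastal[c]:
            w[is_interior[region_of]] += 1.0  # coastal consumption pulls interior goods
            w[is_coastal[region_of]] += 0.8
            w[~is_dom[region_of]] += 0.3
        elif is_dom[c]:
            w[is_dom[region_of]] += 0.3
        else:  # foreign consumers import Chinese goods (exports)
            w[is_coastal[region_of]] += 1.1
            w[is_interior[region_of]] += 0.5
            w[~is_dom[region_of]] += 1.5
        Y[:, c] = totals[c] * rng.dirichlet(1.5 * w)

    x = np.linalg.solve(np.eye(n) - A, Y.sum(axis=1))
    Z = A * x[None, :]
    x_exact = Z.sum(axis=1) + Y.sum(axis=1)  # balance holds identically

    names = config.region_names
    table = LinkedMRIOTable(
        regions=names, n_domestic=Rd, sectors=config.sector_names, Z=Z, Y=Y, x=x_exact
    )
    table.validate()
    return table


def generate_emission_intensities(
    config: WorldConfig, economy: LinkedMRIOTable
) -> np.ndarray:
    """Emission intensities (Mt per billion US$) per pollutant x region-sector.

    Interior provinces are dirtier than coastal ones by
    ``config.intensity_gradient``; foreign regions are cleaner than coastal
    (advanced control technology); heavy industry is the dirtiest sector.
    1 g/US$ equals 1e-3 Mt per billion US$.
    """
    rng = config.rng(1)
    R, S = economy.n_regions, economy.n_sectors
    nc = config.n_coastal
    sector_f = np.array((_SECTOR_FACTORS * ((S // len(_SECTOR_FACTORS)) + 1))[:S])
    region_f = np.ones(R)
    region_f[nc : config.n_domestic] = config.intensity_gradient
    region_f[config.n_domestic :] = 0.4

    P = len(config.pollutants)
    F = np.empty((P, R * S))
    for p, pol in enumerate(config.pollutants):
        base = _BASE_INTENSITY.get(pol, 2.0) * 1e-3  # Mt per billion US$
        jitter = rng.uniform(0.9, 1.1, size=S)  # per-sector, shared by regions
        F[p] = (base * region_f[:, None] * (sector_f * jitter)[None, :]).ravel()
    return F


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def _centroids(config: WorldConfig) -> np.ndarray:
    """Province centroids: coastal in the east band, interior in the west."""
    ny, nx = config.grid_shape
    nc = config.n_coastal
    ni = config.n_domestic - nc
    pts = []
    for k in range(nc):
        pts.append(((k + 0.5) / nc * ny, 0.80 * nx))
    for k in range(ni):
        pts.append(((k + 0.5) / ni * ny, 0.28 * nx))
    return np.array(pts)


def generate_grid(
    config: WorldConfig,
) -> tuple[xr.DataArray, xr.DataArray, DispersionKernelSet]:
    """Population, province masks and dispersion kernels on the lattice.

    Provinces partition the grid by nearest centroid; population is a base
    density plus Gaussian agglomerations (denser around coastal centroids);
    kernels are isotropic exponential decays from each centroid, normalized
    to unit sum per (pollutant, region).
    """
    ny, nx = config.grid_shape
    nc, nd = config.n_coastal, config.n_domestic
    if ny * nx < nd or ny < max(nc, nd - nc) or nx < 2:
        raise WorldGenerationError(
            f"grid {config.grid_shape} too small for {nd} provinces"
        )
    rng = config.rng(2)
    cent = _centroids(config)
    rows, cols = np.mgrid[0:ny, 0:nx]
    d2 = (rows[None] - cent[:, 0, None, None]) ** 2 + (
        cols[None] - cent[:, 1, None, None]
    ) ** 2
    region_map = d2.argmin(axis=0)
    counts = np.bincount(region_map.ravel(), minlength=nd)
    if (counts == 0).any():
        raise WorldGenerationError("a province received no grid cell")

    sigma = max(ny, nx) / 10.0
    pop = np.full((ny, nx), 1.0e4)
    for r in range(nd):
        mass = 4.0e7 if r < nc else 1.5e7
        bump = np.exp(-d2[r] / (2 * sigma**2))
        pop += mass * bump / bump.sum()
    pop *= rng.uniform(0.8, 1.2, size=pop.shape)  # local heterogeneity

    dist_km = np.sqrt(d2) * config.cell_km
    P = len(config.pollutants)
    weights = np.empty((P, nd, ny, nx))
    for p, pol in enumerate(config.pollutants):
        lam = _DECAY_KM[pol] if pol in _DECAY_KM else 100.0
        k = np.exp(-dist_km / lam)
        weights[p] = k / k.sum(axis=(1, 2), keepdims=True)

    coords = {"y": np.arange(ny), "x": np.arange(nx)}
    pop_da = xr.DataArray(pop, dims=("y", "x"), coords=coords, name="population",
                          attrs={"units": "persons per cell"})
    mask_da = xr.DataArray(region_map, dims=("y", "x"), coords=coords,
                           name="region_index",
                           attrs={"regions": ",".join(config.region_names[:nd])})
    kernels = DispersionKernelSet(
        pollutants=list(config.pollutants),
        regions=config.region_names[:nd],
        weights=weights,
        centroids=cent,
        decay_km={p: _DECAY_KM.get(p, 100.0) for p in config.pollutants},
        beta={p: _BETA.get(p, 1500.0) for p in config.pollutants},
        background=config.background,
        cell_km=config.cell_km,
    )
    return pop_da, mask_da, kernels


def generate_satellite_field(
    baseline_model_field: xr.DataArray, config: WorldConfig
) -> xr.DataArray:
    """Satellite-like retrieval: model baseline times lognormal noise.

    The noise is multiplicative with mean 1 and coefficient of variation
    ``config.satellite_noise_cv`` (zero CV reproduces the model field
    exactly), keeping concentrations nonnegative.
    """
    cv = config.satellite_noise_cv
    base = np.asarray(baseline_model_field, dtype=float)
    if (base < 0).any():
        raise ValueError("baseline field must be nonnegative")
    if cv == 0:
        noisy = base.copy()
    else:
        rng = config.rng(3)
        s2 = np.log1p(cv**2)
        noise = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=base.shape)
        noisy = base * noise
    return xr.DataArray(
        noisy,
        dims=baseline_model_field.dims,
        coords=baseline_model_field.coords,
        name="satellite_pm25",
        attrs={"units": "ug m-3"},
    )


# ---------------------------------------------------------------------------
# health inputs
# ---------------------------------------------------------------------------

def generate_ier_parameters(config: WorldConfig) -> IERParameterDraws:
    """Ensemble of IER parameters: draw 0 central, others lognormal scatter.

    All parameters stay strictly positive, so every drawn curve is
    nondecreasing in concentration with plateau 1 + alpha.
    """
    rng = config.rng(4)
    rows = []
    for endpoint in ENDPOINTS:
        c0, alpha, gamma, delta = _IER_CENTRAL[endpoint]
        central = {"C0": c0, "alpha": alpha, "gamma": gamma, "delta": delta}
        for d in range(config.n_draws):
            row = {"endpoint": endpoint, "draw": d}
            for name, val in central.items():
                if d == 0:
                    row[name] = val
                else:
                    s2 = np.log1p(_IER_CV[name] ** 2)
                    row[name] = val * rng.lognormal(-s2 / 2, np.sqrt(s2))
            rows.append(row)
    return IERParameterDraws(table=pd.DataFrame(rows))


def generate_incidence() -> dict[str, float]:
    """National baseline mortality incidence per endpoint (per person-year)."""
    return dict(_INCIDENCE)


def generate_income(config: WorldConfig) -> pd.DataFrame:
    """Per-capita disposable income (RMB) per province, coastal >> interior."""
    rng = config.rng(5)
    names = config.region_names[: config.n_domestic]
    income = np.where(
        np.arange(config.n_domestic) < config.n_coastal,
        rng.normal(26000, 2500, config.n_domestic),
        rng.normal(9500, 1500, config.n_domestic),
    ).clip(min=3000)
    return pd.DataFrame({"region": names, "income_rmb": income})


# ---------------------------------------------------------------------------
# full world
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate every pipeline input for one seed.

    The satellite field is derived from the baseline (scenario 1) modelled
    concentration field, as the retrieval it emulates observes the real
    (all-emissions) atmosphere.
    """
    from .exposure import disperse  # local import: synthetic -> exposure only here

    economy = generate_economy(config)
    F = generate_emission_intensities(config, economy)
    production = F * economy.x[None, :]
    pop, region_map, kernels = generate_grid(config)

    nd, S = config.n_domestic, config.n_sectors
    prod_by_region = production.reshape(len(config.pollutants), -1, S).sum(axis=2)
    baseline = disperse(prod_by_region[:, :nd], kernels)
    satellite = generate_satellite_field(baseline, config)

    return SyntheticWorld(
        config=config,
        economy=economy,
        intensities=F,
        production_emissions=production,
        population=pop,
        region_map=region_map,
        kernels=kernels,
        satellite=satellite,
        ier_draws=generate_ier_parameters(config),
        incidence=generate_incidence(),
        income=generate_income(config),
    )
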