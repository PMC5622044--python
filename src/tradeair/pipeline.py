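"""End-to-end orchestration: generate -> account -> scenario -> expose -> health.

Every stage writes its artifacts to disk under the run's output directory so
any stage can be re-run or audited in isolation; conservation checks
(economy balance, account identities, scenario-3 national conservation,
exposure additivity) are evaluated at stage boundaries and abort the run if
violated.  All randomness flows from the single world seed, so a run is
idempotent: the same config produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import io as tio
from .exposure import change_ratio, decompose_exposure, disperse, population_weighted_mean
from .health import MortalityResult, RRAveragingConfig, monte_carlo_ci
from .mrio import accounts as mrio_accounts
from .mrio import embodied_emissions, technical_coefficients
from .scenarios import ScenarioSpec, build_scenario, default_scenarios
from .synthetic import SyntheticWorld, WorldConfig, generate_world

logger = logging.getLogger(__name__)

CONSERVATION_RTOL = 1e-9


class PipelineError(RuntimeError):
    """A stage failed or a conservation check was violated."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    scenarios: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    ci_scenarios: tuple[int, ...] = (2, 3)  # full-ensemble CI; others central only
    N: int = 1000  # increment-average sampling number
    outdir: Path = Path("tradeair_run")

    @classmethod
    def from_yaml(cls, path: Path, seed: int | None = None,
                  outdir: Path | None = None) -> "RunConfig":
        raw = tio.load_yaml(path)
        wc = WorldConfig(**raw.get("world", {}))
        if seed is not None:
            wc = dataclasses.replace(wc, seed=seed)
        return cls(
            world=wc,
            scenarios=tuple(raw.get("scenarios", (1, 2, 3, 4, 5, 6))),
            ci_scenarios=tuple(raw.get("ci_scenarios", (2, 3))),
            N=int(raw.get("N", 1000)),
            outdir=Path(outdir or raw.get("outdir", "tradeair_run")),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"]["grid_shape"] = list(self.world.grid_shape)
        d["world"]["pollutants"] = list(self.world.pollutants)
        d["scenarios"] = list(self.scenarios)
        d["ci_scenarios"] = list(self.ci_scenarios)
        d["outdir"] = str(self.outdir)
        return d

    @property
    def provenance(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # output location is not part of the scientific config
        blob = json.dumps(d, sort_keys=True)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return f"config_sha256={digest} seed={self.world.seed}"


@dataclass
class RunReport:
    """Collected per-scenario tables of a finished run."""

    config: RunConfig
    accounts_table: pd.DataFrame
    scenario_table: pd.DataFrame
    pwm_table: pd.DataFrame
    deaths_table: pd.DataFrame
    mortality: dict[int, MortalityResult]
    provenance: str


def _check(name: str, residual: float, tol: float = CONSERVATION_RTOL) -> None:
    logger.info("conservation check %s: residual %.3e", name, residual)
    if residual > tol:
        raise PipelineError(f"conservation check {name} failed: {residual:.3e} > {tol}")


def run(config: RunConfig, world: SyntheticWorld | None = None) -> RunReport:
    """Execute every stage; returns the report and leaves artifacts on disk."""
    out = Path(config.outdir)
    prov = config.provenance
    tio.dump_yaml(config.to_dict(), out / "config.yaml")

    # --- stage: generate --------------------------------------------------
    if world is None:
        world = generate_world(config.world)
    eco = world.economy
    inputs = out / "inputs"
    tio.write_economy(eco, inputs, prov)
    tio.write_intensities(world.intensities, world.pollutants, eco.regions,
                          eco.sectors, inputs / "intensities.csv", prov)
    tio.write_field(world.population, inputs / "population.nc", prov)
    tio.write_field(world.region_map, inputs / "region_masks.nc", prov)
    tio.write_field(world.satellite, inputs / "satellite_pm25.nc", prov)
    tio.write_kernels(world.kernels, inputs / "kernels.nc", prov)
    tio.write_ier_draws(world.ier_draws, inputs / "ier_draws.csv", prov)
    tio.write_incidence(world.incidence, inputs / "incidence.csv", prov)
    tio.write_csv(world.income, inputs / "income.csv", prov)

    # --- stage: account ----------------------------------------------------
    coeff = technical_coefficients(eco)
    tensor = embodied_emissions(world.intensities, coeff, eco, world.pollutants)
    acc = mrio_accounts(tensor)
    totals = acc.E_p.sum(axis=1)
    _check("global E_p vs E_c", float(
        np.abs(totals - acc.E_c.sum(axis=1)).max() / max(totals.max(), 1e-30)))
    _check("E_p decomposition", float(np.abs(
        acc.E_p - (acc.local + acc.domestic_out + acc.foreign_out)).max()
        / max(totals.max(), 1e-30)))
    accdir = out / "account"
    tio.write_csv(tensor.to_frame(), accdir / "embodied_long.csv", prov)
    tio.write_csv(acc.to_frame(), accdir / "accounts.csv", prov)

    # --- stage: scenario ----------------------------------------------------
    specs = {s.scenario_id: s for s in default_scenarios(eco.regions[eco.n_domestic:])}
    missing = [s for s in config.scenarios if s not in specs]
    if missing:
        raise PipelineError(f"scenarios {missing} not constructible "
                            f"({len(eco.regions) - eco.n_domestic} foreign regions)")
    scen_emissions = {
        sid: build_scenario(tensor, acc, specs[sid]) for sid in config.scenarios
    }
    if 3 in scen_emissions:
        nat1 = acc.E_p[:, : eco.n_domestic].sum(axis=1)
        nat3 = scen_emissions[3].values.sum(axis=1)
        _check("scenario-3 national conservation",
               float(np.abs(nat1 - nat3).max() / max(nat1.max(), 1e-30)))
    scen_table = pd.concat([s.to_frame() for s in scen_emissions.values()],
                           ignore_index=True)
    tio.write_csv(scen_table, out / "scenario" / "scenario_emissions.csv", prov)

    # --- stage: expose ------------------------------------------------------
    baseline_field = disperse(scen_emissions[1].values if 1 in scen_emissions
                              else build_scenario(tensor, acc, specs[1]).values,
                              world.kernels)
    pop = world.population
    sat = world.satellite
    pwm_rows = []
    fields: dict[int, tuple[xr.DataArray, xr.DataArray]] = {}
    expdir = out / "exposure"
    pwm_sat = population_weighted_mean(sat, pop)
    for sid, scen in scen_emissions.items():
        model_field = disperse(scen.values, world.kernels)
        A = change_ratio(baseline_field, model_field)
        C_TRE, C_noTRE = decompose_exposure(sat, A)
        resid = float(np.abs(np.asarray(C_TRE) + np.asarray(C_noTRE)
                             - np.asarray(sat)).max())
        _check(f"scenario-{sid} exposure additivity", resid, 1e-9 * max(pwm_sat, 1.0))
        fields[sid] = (C_TRE, C_noTRE)
        pwm_no = population_weighted_mean(C_noTRE, pop)
        pwm_rows.append({
            "scenario": sid,
            "pwm_satellite": pwm_sat,
            "pwm_noTRE": pwm_no,
            "pwm_delta_trade": pwm_sat - pwm_no,
        })
        for name, da in (("C_TRE", C_TRE), ("C_noTRE", C_noTRE), ("A", A),
                         ("C_model", model_field)):
            tio.write_field(da, expdir / f"scenario_{sid}_{name}.nc", prov)
    pwm_table = pd.DataFrame(pwm_rows)
    tio.write_csv(pwm_table, expdir / "pwm.csv", prov)

    # --- stage: health ------------------------------------------------------
    cfg_rr = RRAveragingConfig(N=config.N)
    region_names = eco.regions[: eco.n_domestic]
    mortality: dict[int, MortalityResult] = {}
    hdir = out / "health"
    for sid, (C_TRE, C_noTRE) in fields.items():
        full_ci = sid in config.ci_scenarios
        draw_slice = None if full_ci else slice(0, 2)
        res = monte_carlo_ci(
            np.asarray(C_TRE), np.asarray(C_noTRE), np.asarray(pop),
            np.asarray(world.region_map), region_names,
            world.ier_draws, world.incidence, cfg_rr, draw_slice=draw_slice,
        )
        if not full_ci:  # CI from two draws is meaningless: report central only
            res.lower95 = np.full_like(res.central, np.nan)
            res.upper95 = np.full_like(res.central, np.nan)
        mortality[sid] = res
        density = xr.DataArray(res.cell_central, dims=("y", "x"),
                               name="deaths_per_cell")
        tio.write_field(density, hdir / f"scenario_{sid}_death_density.nc", prov)
    deaths_table = pd.concat(
        [m.to_frame().assign(scenario=sid) for sid, m in mortality.items()],
        ignore_index=True,
    )
    tio.write_csv(deaths_table, hdir / "deaths.csv", prov)

    # --- stage: report ------------------------------------------------------
    report = RunReport(
        config=config,
        accounts_table=acc.to_frame(),
        scenario_table=scen_table,
        pwm_table=pwm_table,
        deaths_table=deaths_table,
        mortality=mortality,
        provenance=prov,
    )
    summary = {
        "provenance": prov,
        "scenarios": {
            str(sid): {
                "national_deaths_central": m.total_central,
                "national_deaths_lo95": (m.total_lower95
                                         if sid in config.ci_scenarios else None),
                "national_deaths_hi95": (m.total_upper95
                                         if sid in config.ci_scenarios else None),
            }
            for sid, m in mortality.items()
        },
    }
    (out / "report").mkdir(parents=True, exist_ok=True)
    (out / "report" / "report.json").write_text(json.dumps(summary, indent=2))
    if world.income is not None and 3 in mortality:
        pops, _ = _region_population(world)
        grad = income_gradient_table(
            mortality[3].central.sum(axis=1), pops, world.income)
        tio.write_csv(grad, out / "report" / "income_gradient.csv", prov)
    return report


def _region_population(world: SyntheticWorld) -> tuple[np.ndarray, float]:
    rmap = np.asarray(world.region_map, int).ravel()
    pop = np.asarray(world.population, float).ravel()
    per = np.bincount(rmap, weights=pop, minlength=world.config.n_domestic)
    return per, float(pop.sum())


def income_gradient_table(
    deaths_per_region: np.ndarray,
    population_per_region: np.ndarray,
    income: pd.DataFrame,
) -> pd.DataFrame:
    """Mortality-risk change (deaths per million residents) versus income.

    Positive values are added deaths from trade, negative avoided; sorted by
    per-capita income so the equity gradient is read top-to-bottom.
    """
    regions = list(income["region"])
    if len(regions) != len(deaths_per_region):
        raise PipelineError("income table does not cover every domestic region")
    df = pd.DataFrame(
        {
            "region": regions,
            "income_rmb": income["income_rmb"].to_numpy(float),
            "deaths": np.asarray(deaths_per_region, float),
            "population": np.asarray(population_per_region, float),
        }
    )
    df["deaths_per_million"] = df["deaths"] / df["population"] * 1e6
    return df.sort_values("income_rmb", ignore_index=True)
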