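"""Readers and writers for the pipeline's on-disk stage artifacts.

Economy tables, intensities, tensors and health outputs travel as CSV;
gridded fields as NetCDF (classic format via the SciPy backend) with named
dimensions and units attributes.  Every writer accepts a provenance string
that is embedded as a ``#``-prefixed header comment (CSV) or a global
attribute (NetCDF).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .mrio import LinkedMRIOTable
from .synthetic import DispersionKernelSet, IERParameterDraws

_NC = dict(engine="scipy")


def _flat_labels(regions, sectors) -> list[str]:
    return [f"{r}|{s}" for r in regions for s in sectors]


def write_csv(df: pd.DataFrame, path: Path, provenance: str = "",
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=index)


def read_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


# -- economy ----------------------------------------------------------------

def write_economy(table: LinkedMRIOTable, outdir: Path, provenance: str = "") -> None:
    outdir = Path(outdir)
    labels = _flat_labels(table.regions, table.sectors)
    write_csv(pd.DataFrame(table.Z, index=labels, columns=labels),
              outdir / "flows.csv", provenance, index=True)
    write_csv(pd.DataFrame(table.Y, index=labels, columns=table.regions),
              outdir / "final_demand.csv", provenance, index=True)
    write_csv(pd.DataFrame({"region_sector": labels, "output": table.x}),
              outdir / "output.csv", provenance)
    meta = {
        "regions": table.regions,
        "n_domestic": table.n_domestic,
        "sectors": table.sectors,
        "index_convention": "region-major, sector-minor",
        "currency": "billion US$",
    }
    (outdir / "economy_meta.json").write_text(json.dumps(meta, indent=2))


def read_economy(outdir: Path) -> LinkedMRIOTable:
    outdir = Path(outdir)
    meta = json.loads((outdir / "economy_meta.json").read_text())
    Z = read_csv(outdir / "flows.csv", index_col=0).to_numpy(float)
    Y = read_csv(outdir / "final_demand.csv", index_col=0).to_numpy(float)
    x = read_csv(outdir / "output.csv")["output"].to_numpy(float)
    table = LinkedMRIOTable(
        regions=meta["regions"], n_domestic=meta["n_domestic"],
        sectors=meta["sectors"], Z=Z, Y=Y, x=x,
    )
    table.validate()
    return table


# -- intensities / emissions -----------------------------------------------

def write_intensities(F: np.ndarray, pollutants, regions, sectors,
                      path: Path, provenance: str = "") -> None:
    labels = _flat_labels(regions, sectors)
    df = pd.DataFrame(F.T, index=labels, columns=pollutants)
    write_csv(df, Path(path), provenance, index=True)


def read_intensities(path: Path) -> tuple[np.ndarray, list[str]]:
    df = read_csv(path, index_col=0)
    return df.to_numpy(float).T, list(df.columns)


# -- gridded fields ---------------------------------------------------------

def write_field(da: xr.DataArray, path: Path, provenance: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = da.to_dataset(name=da.name or "field")
    if provenance:
        ds.attrs["provenance"] = provenance
    ds.to_netcdf(path, **_NC)


def read_field(path: Path, name: str | None = None) -> xr.DataArray:
    with xr.open_dataset(path, **_NC) as ds:
        var = name or list(ds.data_vars)[0]
        return ds[var].load()


def write_kernels(k: DispersionKernelSet, path: Path, provenance: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ny, nx = k.weights.shape[2:]
    ds = xr.Dataset(
        {
            "weights": (("pollutant", "region", "y", "x"), k.weights),
            "centroid": (("region", "rc"), k.centroids),
        },
        coords={
            "pollutant": k.pollutants,
            "region": k.regions,
            "y": np.arange(ny),
            "x": np.arange(nx),
            "rc": ["row", "col"],
        },
        attrs={
            "decay_km": json.dumps(k.decay_km),
            "beta": json.dumps(k.beta),
            "background": k.background,
            "cell_km": k.cell_km,
            "provenance": provenance,
        },
    )
    ds.to_netcdf(path, **_NC)


def read_kernels(path: Path) -> DispersionKernelSet:
    with xr.open_dataset(path, **_NC) as ds:
        return DispersionKernelSet(
            pollutants=[str(p) for p in ds.pollutant.values],
            regions=[str(r) for r in ds.region.values],
            weights=ds["weights"].values.copy(),
            centroids=ds["centroid"].values.copy(),
            decay_km=json.loads(ds.attrs["decay_km"]),
            beta=json.loads(ds.attrs["beta"]),
            background=float(ds.attrs["background"]),
            cell_km=float(ds.attrs["cell_km"]),
        )


# -- health inputs ----------------------------------------------------------

def write_ier_draws(draws: IERParameterDraws, path: Path, provenance: str = "") -> None:
    write_csv(draws.table, Path(path), provenance)


def read_ier_draws(path: Path) -> IERParameterDraws:
    return IERParameterDraws(table=read_csv(path))


def write_incidence(incidence: dict[str, float], path: Path, provenance: str = "") -> None:
    df = pd.DataFrame(
        {"endpoint": list(incidence), "rate_per_person_year": list(incidence.values())}
    )
    write_csv(df, Path(path), provenance)


def read_incidence(path: Path) -> dict[str, float]:
    df = read_csv(path)
    return dict(zip(df.endpoint, df.rate_per_person_year))


# -- config -----------------------------------------------------------------

def load_yaml(path: Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_yaml(obj: dict, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
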