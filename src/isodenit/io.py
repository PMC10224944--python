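"""NetCDF serialization of grid fields, N-input sets and ESM bundles.

Files are NETCDF3_CLASSIC written through xarray's scipy backend, with
"lat"/"lon" cell-center coordinates in degrees.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .budget import ESMBundle
from .isotope import NInputSet

_NC = {"engine": "scipy", "format": "NETCDF3_CLASSIC"}


def save_fields(fields: Mapping[str, xr.DataArray], path, attrs: dict | None = None) -> None:
    ds = xr.Dataset({k: v for k, v in fields.items()}, attrs=attrs or {})
    ds.to_netcdf(path, **_NC)


def load_fields(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def save_ninput_set(inputs: NInputSet, path) -> None:
    save_fields(
        {
            "i_dep": inputs.i_dep,
            "i_bnf": inputs.i_bnf,
            "i_rock": inputs.i_rock,
            "delta_rock": inputs.delta_rock_field(),
        },
        path,
        attrs={
            "delta_dep": float(inputs.delta_dep),
            "delta_bnf": float(inputs.delta_bnf),
            "name": inputs.name,
        },
    )


def load_ninput_set(path) -> NInputSet:
    ds = load_fields(path)
    return NInputSet(
        i_dep=ds["i_dep"],
        i_bnf=ds["i_bnf"],
        i_rock=ds["i_rock"],
        delta_rock=ds["delta_rock"],
        delta_dep=float(ds.attrs.get("delta_dep", 0.0)),
        delta_bnf=float(ds.attrs.get("delta_bnf", -2.0)),
        name=str(ds.attrs.get("name", "ninput")),
    )


def save_esm_bundle(bundle: ESMBundle, path) -> None:
    ds = xr.Dataset(
        {
            "denit_flux": bundle.denit_flux,
            "leach_flux": bundle.leach_flux,
            "n_stock": ("year", bundle.n_stock_series.to_numpy(float)),
            "npp": ("year", np.asarray(bundle.npp, float)),
            "t": ("year", np.asarray(bundle.t, float)),
            "p": ("year", np.asarray(bundle.p, float)),
            "co2": ("year", np.asarray(bundle.co2, float)),
        },
        coords={"year": np.asarray(bundle.years, np.int32)},
        attrs={"model_id": bundle.model_id},
    )
    ds.to_netcdf(path, **_NC)


def load_esm_bundle(path) -> ESMBundle:
    ds = load_fields(path)
    years = np.asarray(ds["year"], int)
    return ESMBundle(
        model_id=str(ds.attrs.get("model_id", "ESM")),
        denit_flux=ds["denit_flux"],
        leach_flux=ds["leach_flux"],
        n_stock_series=pd.Series(np.asarray(ds["n_stock"], float), index=years),
        years=years,
        npp=np.asarray(ds["npp"], float),
        t=np.asarray(ds["t"], float),
        p=np.asarray(ds["p"], float),
        co2=np.asarray(ds["co2"], float),
    )
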