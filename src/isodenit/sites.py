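"""Quality filtering and gridding of site-level soil delta15N records.

Raw compilations of topsoil d15N mix natural mineral-soil samples with
deep profiles, litter, organic horizons, coastal sites and managed land.
Only natural topsoil (<= 30 cm, mineral) carries the steady-state loss
signal the isotope balance needs, so records are screened by eight rules
(a-h), depth-averaged per site weighting by N content, and aggregated to
grid-cell means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec

MANAGED_LANDCOVERS = frozenset({"pasture", "drystock", "dairy", "industrial"})

CSV_COLUMNS = [
    "site_id", "lat", "lon", "depth_top_cm", "depth_bottom_cm",
    "delta15n_permil", "n_conc_mg_g", "c_conc_mg_g", "cn_ratio",
    "horizon", "landcover", "coastal_flag",
]


@dataclass
class SiteRecord:
    """One soil d15N measurement with its depth interval and provenance.

    Optional fields are ``None`` when the source did not report them;
    missing metadata never triggers an exclusion.
    """

    site_id: str
    lat: float
    lon: float
    delta15n: float
    depth_top_cm: float | None = None
    depth_bottom_cm: float | None = None
    n_conc: float | None = None       # mg N per g soil
    c_conc: float | None = None       # mg C per g soil
    cn_ratio: float | None = None     # gC / gN
    horizon: str | None = None        # mineral | organic | litter
    landcover: str | None = None      # natural | cropland | pasture | ...
    coastal_flag: bool | None = None

    def __post_init__(self) -> None:
        if (
            self.depth_top_cm is not None
            and self.depth_bottom_cm is not None
            and self.depth_top_cm > self.depth_bottom_cm
        ):
            raise ValueError(f"{self.site_id}: depth_top_cm > depth_bottom_cm")
        for name in ("n_conc", "c_conc", "cn_ratio"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.site_id}: {name} must be >= 0")


@dataclass
class FilterReport:
    kept: list[SiteRecord]
    excluded_by_rule: dict[str, int]
    excluded: list[tuple[SiteRecord, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded_by_rule.values())

    def to_text(self) -> str:
        lines = [f"kept: {len(self.kept)}"]
        lines += [f"rule {r}: {n}" for r, n in sorted(self.excluded_by_rule.items())]
        return "\n".join(lines) + "\n"


def _true(x) -> bool:
    """Predicate helper: missing values never trigger an exclusion."""
    return x is not None and bool(x)


def violated_rule(rec: SiteRecord) -> str | None:
    """First exclusion rule (a-h) the record violates, or None if clean.

    (a) sample deeper than 30 cm; (b) C:N < 1 gC/gN; (c) N concentration
    < 0.02 mg/g; (d) organic horizon only, or C concentration > 610 mg/g
    (not a mineral soil); (e) litter layer; (f) adjacent to a marine
    ecosystem; (g) cropland; (h) pasture/drystock/dairy/industrial.
    """
    if _true(rec.depth_bottom_cm is not None and rec.depth_bottom_cm > 30):
        return "a"
    if _true(rec.cn_ratio is not None and rec.cn_ratio < 1):
        return "b"
    if _true(rec.n_conc is not None and rec.n_conc < 0.02):
        return "c"
    if rec.horizon == "organic" or _true(rec.c_conc is not None and rec.c_conc > 610):
        return "d"
    if rec.horizon == "litter":
        return "e"
    if _true(rec.coastal_flag):
        return "f"
    if rec.landcover == "cropland":
        return "g"
    if rec.landcover in MANAGED_LANDCOVERS:
        return "h"
    return None


def filter_sites(records: Iterable[SiteRecord]) -> FilterReport:
    """Screen records by rules a-h; multi-rule violators count once, under
    the first matching rule in a-h order."""
    counts = {r: 0 for r in "abcdefgh"}
    kept: list[SiteRecord] = []
    excluded: list[tuple[SiteRecord, str]] = []
    for rec in records:
        rule = violated_rule(rec)
        if rule is None:
            kept.append(rec)
        else:
            counts[rule] += 1
            excluded.append((rec, rule))
    return FilterReport(kept=kept, excluded_by_rule=counts, excluded=excluded)


def depth_weighted_average(
    deltas: Sequence[float], n_contents: Sequence[float]
) -> float:
    """N-content-weighted mean d15N over a site's depth layers."""
    d = np.asarray(deltas, dtype=float)
    w = np.asarray(n_contents, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one layer")
    if d.shape != w.shape:
        raise ValueError("deltas and n_contents must have equal length")
    if np.any(w < 0):
        raise ValueError("layer N contents must be >= 0")
    if w.sum() == 0:
        raise ValueError("all layer weights are zero")
    return float((d * w).sum() / w.sum())


def site_means(records: Iterable[SiteRecord]) -> pd.DataFrame:
    """Collapse multi-depth records to one d15N value per site.

    Layers are weighted by N content per unit area, approximated as
    n_conc * layer thickness; when either is missing for a layer, all
    layers of that site are weighted equally.
    """
    rows = []
    for r in records:
        thick = (
            r.depth_bottom_cm - r.depth_top_cm
            if r.depth_top_cm is not None and r.depth_bottom_cm is not None
            else None
        )
        w = (
            r.n_conc * thick
            if r.n_conc is not None and thick is not None and r.n_conc * thick > 0
            else None
        )
        rows.append((r.site_id, r.lat, r.lon, r.delta15n, w))
    df = pd.DataFrame(rows, columns=["site_id", "lat", "lon", "delta15n", "w"])
    if df.empty:
        return df.drop(columns="w")

    def _collapse(g: pd.DataFrame) -> pd.Series:
        w = g["w"].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or w.sum() == 0:
            w = np.ones(len(g))
        return pd.Series(
            {
                "lat": g["lat"].iloc[0],
                "lon": g["lon"].iloc[0],
                "delta15n": depth_weighted_average(g["delta15n"].to_numpy(), w),
            }
        )

    out = df.groupby("site_id", sort=False).apply(_collapse, include_groups=False)
    return out.reset_index()


def aggregate_to_grid(sites: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Average site-level d15N into grid-cell means.

    ``sites`` must carry one row per site (site_id, lat, lon, delta15n),
    i.e. the output of :func:`site_means`.  Returns one row per occupied
    cell: ilat, ilon, cell-center lat/lon, unweighted mean d15N, n_records.
    """
    if sites.empty:
        return pd.DataFrame(
            columns=["ilat", "ilon", "lat", "lon", "delta15n", "n_records"]
        )
    try:
        ilat, ilon = spec.cell_index(sites["lat"].to_numpy(), sites["lon"].to_numpy())
    except ValueError as e:
        bad = str(e)
        match = sites[
            (sites["lat"] < spec.lat_min) | (sites["lat"] > spec.lat_max)
            | (sites["lon"] < spec.lon_min) | (sites["lon"] > spec.lon_max)
        ]
        name = match["site_id"].iloc[0] if len(match) else "?"
        raise ValueError(f"site {name} outside grid extent ({bad})") from e
    df = sites.assign(ilat=ilat, ilon=ilon)
    out = (
        df.groupby(["ilat", "ilon"], sort=True)["delta15n"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "delta15n", "size": "n_records"})
    )
    out["lat"] = spec.lats[out["ilat"]]
    out["lon"] = spec.lons[out["ilon"]]
    return out[["ilat", "ilon", "lat", "lon", "delta15n", "n_records"]]


def records_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = [
        {
            "site_id": r.site_id,
            "lat": r.lat,
            "lon": r.lon,
            "depth_top_cm": r.depth_top_cm,
            "depth_bottom_cm": r.depth_bottom_cm,
            "delta15n_permil": r.delta15n,
            "n_conc_mg_g": r.n_conc,
            "c_conc_mg_g": r.c_conc,
            "cn_ratio": r.cn_ratio,
            "horizon": r.horizon,
            "landcover": r.landcover,
            "coastal_flag": r.coastal_flag,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _opt(v):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def frame_to_records(df: pd.DataFrame) -> list[SiteRecord]:
    records = []
    for row in df.itertuples(index=False):
        coastal = _opt(getattr(row, "coastal_flag", None))
        if isinstance(coastal, str):
            coastal = coastal.strip().lower() in {"true", "1", "yes"}
        records.append(
            SiteRecord(
                site_id=str(row.site_id),
                lat=float(row.lat),
                lon=float(row.lon),
                delta15n=float(row.delta15n_permil),
                depth_top_cm=_opt(row.depth_top_cm),
                depth_bottom_cm=_opt(row.depth_bottom_cm),
                n_conc=_opt(row.n_conc_mg_g),
                c_conc=_opt(row.c_conc_mg_g),
                cn_ratio=_opt(row.cn_ratio),
                horizon=_opt(row.horizon),
                landcover=_opt(row.landcover),
                coastal_flag=coastal if coastal is None else bool(coastal),
            )
        )
    return records


def read_sites_csv(path) -> list[SiteRecord]:
    return frame_to_records(pd.read_csv(path))


def write_sites_csv(records: Iterable[SiteRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
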