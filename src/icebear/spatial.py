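"""Post-decoding spatial analysis: 50-km rasterization, bear-day
rarefaction, the relative-dominance statistic, subset maps and
utilization-distribution isopleths.

Decoded steps are binned onto a regular 50-km grid anchored at the data
bounding box's lower-left corner and rarefied to "bear days" (one record per
unique cell, bear, date and state). The dominant state of a cell is the one
with the highest within-cell proportion *relative to its proportion across
all cells*, so locally over-represented rare states are visible; cells with
few bear days are masked or flagged low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely import box
from shapely.ops import unary_union

from .hmm import N_STATES, STATES

CELL_KM = 50.0
MIN_BEAR_DAYS = 7
HATCH_BELOW = 21


@dataclass(frozen=True)
class SquareGrid:
    """Regular square analysis grid anchored at (x0, y0), cells in km."""

    x0: float
    y0: float
    cell_km: float = CELL_KM

    def cell_of(self, x_km, y_km):
        ix = np.floor((np.asarray(x_km) - self.x0) / self.cell_km).astype(int)
        iy = np.floor((np.asarray(y_km) - self.y0) / self.cell_km).astype(int)
        return ix, iy


def make_grid(decoded: pd.DataFrame, cell_km=CELL_KM) -> SquareGrid:
    """Grid anchored at the lower-left corner of the data bounding box."""
    return SquareGrid(float(decoded["x_km"].min()),
                      float(decoded["y_km"].min()), cell_km)


def rarefy_bear_days(decoded: pd.DataFrame, grid: SquareGrid) -> pd.DataFrame:
    """Rarefy decoded steps to unique (cell, bear, date, state) records.

    ``decoded`` needs columns animal_id, timestamp, x_km, y_km, state.
    Idempotent: rarefying the result again changes nothing.
    """
    ix, iy = grid.cell_of(decoded["x_km"], decoded["y_km"])
    rec = pd.DataFrame({
        "ix": ix, "iy": iy,
        "animal_id": decoded["animal_id"].to_numpy(),
        "date": pd.DatetimeIndex(decoded["timestamp"]).normalize(),
        "state": np.asarray(decoded["state"], dtype=int),
    })
    extra = [c for c in ("age", "year", "month") if c in decoded.columns]
    for c in extra:
        rec[c] = decoded[c].to_numpy()
    rec["year"] = pd.DatetimeIndex(decoded["timestamp"]).year
    rec["month"] = pd.DatetimeIndex(decoded["timestamp"]).month
    return rec.drop_duplicates(
        subset=["ix", "iy", "animal_id", "date", "state"]
    ).reset_index(drop=True)


@dataclass
class StateRaster:
    """Per-cell bear-day counts by state on the analysis grid."""

    counts: pd.DataFrame  # index (ix, iy), one column per state index
    grid: SquareGrid | None = None

    @classmethod
    def from_records(cls, records: pd.DataFrame, grid: SquareGrid = None,
                     n_states=N_STATES):
        tab = records.groupby(["ix", "iy", "state"]).size().unstack(
            "state", fill_value=0)
        for s in range(n_states):
            if s not in tab.columns:
                tab[s] = 0
        tab = tab[sorted(tab.columns)]
        return cls(tab.astype(int), grid)

    @property
    def cell_totals(self):
        return self.counts.sum(axis=1)

    @property
    def state_totals(self):
        return self.counts.sum(axis=0)

    @property
    def total(self):
        return int(self.counts.to_numpy().sum())


def dominant_state(raster: StateRaster, min_days=MIN_BEAR_DAYS,
                   hatch_below=HATCH_BELOW) -> pd.DataFrame:
    """Per-cell dominant state by relative proportion.

    For each cell i the winner maximizes (N_i^S / N_i) / (N^S / N); states
    absent from the whole dataset get ratio 0, and ties go to the smaller
    state index. Cells with fewer than ``min_days`` bear days are masked
    (``plotted=False``); cells below ``hatch_below`` are flagged
    ``low_confidence``.
    """
    C = raster.counts.to_numpy(dtype=float)
    Ni = C.sum(axis=1)
    NS = C.sum(axis=0)
    N = C.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(NS[None, :] > 0,
                         (C / Ni[:, None]) / (NS[None, :] / N), 0.0)
    winner = np.argmax(ratio, axis=1)  # ties -> smaller state index
    out = raster.counts.reset_index()[["ix", "iy"]].copy()
    out["n_days"] = Ni.astype(int)
    out["dominant_state"] = winner
    out["state_name"] = [STATES[s] for s in winner]
    out["plotted"] = Ni >= min_days
    out["low_confidence"] = (Ni < hatch_below) & (Ni >= min_days)
    return out


def classify_ice_years(annual_means: Mapping[int, float]) -> dict:
    """Label each year low/high relative to the across-year mean
    concentration; exact-mean years are labelled high (>= convention)."""
    if len(annual_means) < 2:
        raise ValueError("need at least 2 years to classify")
    m = float(np.mean(list(annual_means.values())))
    return {y: ("high" if v >= m else "low")
            for y, v in annual_means.items()}


def subset_maps(records: pd.DataFrame, scheme: str, *,
                ice_year_labels: Mapping[int, str] = None,
                ages: Mapping[str, float] = None,
                min_days=MIN_BEAR_DAYS, hatch_below=HATCH_BELOW) -> dict:
    """Dominant-state maps recomputed within data subsets.

    ``scheme``: ``"season"`` (early winter Jan-Mar vs late winter Apr-Jun),
    ``"ice_year"`` (years labelled low vs high via ``ice_year_labels``), or
    ``"age"`` (youngest half vs oldest half of the bears by ``ages``). The
    relative-proportion statistic is recomputed with subset totals.
    """
    if scheme == "season":
        groups = {"early": records[records["month"].between(1, 3)],
                  "late": records[records["month"].between(4, 6)]}
    elif scheme == "ice_year":
        if ice_year_labels is None:
            raise ValueError("ice_year scheme requires ice_year_labels")
        lab = records["year"].map(ice_year_labels)
        groups = {"low_ice": records[lab == "low"],
                  "high_ice": records[lab == "high"]}
    elif scheme == "age":
        if ages is None:
            raise ValueError("age scheme requires an animal->age mapping")
        order = sorted(ages, key=lambda a: (ages[a], str(a)))
        younger = set(order[:len(order) // 2])
        sel = records["animal_id"].isin(younger)
        groups = {"younger": records[sel], "older": records[~sel]}
    else:
        raise ValueError(f"unknown subset scheme {scheme!r}")
    out = {}
    for label, sub in groups.items():
        if len(sub) == 0:
            out[label] = None  # empty subset flagged
            continue
        raster = StateRaster.from_records(sub)
        out[label] = dominant_state(raster, min_days, hatch_below)
    return out


def thin_daily(decoded: pd.DataFrame) -> pd.DataFrame:
    """One position per animal and date (the first fix), to reduce the
    autocorrelation carried into the kernel density estimate."""
    d = decoded.copy()
    d["_date"] = pd.DatetimeIndex(d["timestamp"]).normalize()
    out = d.sort_values("timestamp").groupby(
        ["animal_id", "_date"], as_index=False).first()
    return out.drop(columns="_date")


def save_ud_geojson(ud, path, properties=None):
    """Write a utilization-distribution isopleth polygon as GeoJSON."""
    import json

    from shapely import to_geojson

    feature = {"type": "Feature",
               "geometry": json.loads(to_geojson(ud.polygon)),
               "properties": {"level": ud.level,
                              "area_km2": ud.area_km2,
                              **(properties or {})}}
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


class UDResult(NamedTuple):
    area_km2: float
    level: float
    threshold: float
    polygon: object  # shapely (Multi)Polygon


def utilization_distribution(points, level=0.80, grid_n=200,
                             bandwidth=None) -> UDResult:
    """Kernel utilization distribution and its smallest-area isopleth.

    A bivariate Gaussian KDE (Scott plug-in bandwidth by default) is
    evaluated on a regular grid; the isopleth is the highest-density region
    containing ``level`` of the estimated distribution. Returns its area
    (km^2) and the region as a union of grid-cell boxes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 30:
        raise ValueError("need at least 30 points for a stable KDE")
    if np.linalg.matrix_rank(np.cov(pts.T)) < 2:
        raise ValueError("degenerate (collinear/duplicate) point set")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    sd = np.sqrt(np.diag(np.cov(pts.T)))
    pad = 4.0 * float(np.max(sd)) * kde.factor + 0.05 * float(np.max(sd))
    xg = np.linspace(pts[:, 0].min() - pad, pts[:, 0].max() + pad, grid_n)
    yg = np.linspace(pts[:, 1].min() - pad, pts[:, 1].max() + pad, grid_n)
    XX, YY = np.meshgrid(xg, yg)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    cell = (xg[1] - xg[0]) * (yg[1] - yg[0])
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    total = cum[-1]
    idx = int(np.searchsorted(cum, level * total))
    idx = min(idx, len(flat) - 1)
    threshold = flat[idx]
    mask = dens >= threshold
    area = float(mask.sum()) * cell
    iy, ix = np.nonzero(mask)
    dx = xg[1] - xg[0]
    dy = yg[1] - yg[0]
    boxes = box(xg[ix] - dx / 2, yg[iy] - dy / 2,
                xg[ix] + dx / 2, yg[iy] + dy / 2)
    polygon = unary_union(boxes)
    return UDResult(area, level, float(threshold), polygon)
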