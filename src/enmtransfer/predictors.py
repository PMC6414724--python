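"""Derivation of the three environmental predictor families.

* 19 bioclimatic variables (BIO1-BIO19) from monthly maximum/minimum
  temperature and precipitation, following the standard definitions used by
  the bioclim tool family: quarters are running 3-month windows with
  December-January wraparound; dispersion statistics are sample (n-1) SDs;
  BIO15 is the precipitation coefficient of variation
  100 * SD(monthly prec) / (1 + BIO12/12), whose +1 shields arid cells from
  division by zero.
* Ecosystem functional attributes (EFAs) from a 23-composite vegetation-index
  year: annual mean (productivity), seasonal SD (seasonality) and the 1-based
  composite index of the annual maximum (phenology; earliest composite wins
  ties).
* Fractional land cover by exact block aggregation of the categorical fine
  grid: per-class cell counting, never interpolation, so class mass is
  conserved to the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import ConfigurationError, GeometryError, RasterGrid
from .world import LANDCOVER_CLASSES

BIOCLIM_NAMES = tuple(f"bio{i:02d}" for i in range(1, 20))


class ArityError(ValueError):
    """A layer list has the wrong number of elements (months/composites)."""


@dataclass
class BioclimSet:
    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if tuple(self.layers.keys()) != BIOCLIM_NAMES:
            raise ArityError("a BioclimSet must hold exactly bio01..bio19 in order")

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class EFASet:
    efa_mean: RasterGrid
    efa_sd: RasterGrid
    efa_peak: RasterGrid

    def as_dict(self) -> dict[str, RasterGrid]:
        return {"efa_mean": self.efa_mean, "efa_sd": self.efa_sd, "efa_peak": self.efa_peak}

    def __len__(self) -> int:
        return 3


@dataclass
class FractionalCover:
    frac_scrubland: RasterGrid
    frac_forest: RasterGrid
    frac_cropland: RasterGrid

    def as_dict(self) -> dict[str, RasterGrid]:
        return {
            "frac_scrubland": self.frac_scrubland,
            "frac_forest": self.frac_forest,
            "frac_cropland": self.frac_cropland,
        }


def _stack_months(layers: list[RasterGrid], what: str) -> np.ndarray:
    if len(layers) != 12:
        raise ArityError(f"{what} requires exactly 12 monthly layers, got {len(layers)}")
    ref = layers[0]
    for g in layers[1:]:
        if not g.same_geometry(ref):
            raise GeometryError(f"{what} layers are not co-registered")
    return np.stack([g.values.astype(float) for g in layers])


def _quarter_sums(arr: np.ndarray) -> np.ndarray:
    """Sums over the 12 running 3-month windows (wraparound), axis 0."""
    ext = np.concatenate([arr, arr[:2]], axis=0)
    return np.stack([ext[m : m + 3].sum(axis=0) for m in range(12)])


def compute_bioclim(
    monthly_tmax: list[RasterGrid],
    monthly_tmin: list[RasterGrid],
    monthly_prec: list[RasterGrid],
) -> BioclimSet:
    """All 19 bioclimatic variables from co-registered monthly layers.

    Quarter-based variables (BIO8-BIO11, BIO16-BIO19) pick their window by
    argmax/argmin over the 12 wraparound quarters, earliest starting month on
    ties — matching the convention of the standard implementations.
    """
    tmax = _stack_months(monthly_tmax, "tmax")
    tmin = _stack_months(monthly_tmin, "tmin")
    prec = _stack_months(monthly_prec, "prec")
    if not monthly_tmax[0].same_geometry(monthly_tmin[0]) or not monthly_tmax[0].same_geometry(
        monthly_prec[0]
    ):
        raise GeometryError("tmax/tmin/prec grids are not co-registered")
    if np.any(tmax < tmin):
        raise ConfigurationError("tmax < tmin at some cell/month")

    template = monthly_tmax[0]
    tavg = (tmax + tmin) / 2.0

    b: dict[str, np.ndarray] = {}
    b["bio01"] = tavg.mean(axis=0)
    b["bio02"] = (tmax - tmin).mean(axis=0)
    b["bio04"] = tavg.std(axis=0, ddof=1) * 100.0
    b["bio05"] = tmax.max(axis=0)
    b["bio06"] = tmin.min(axis=0)
    b["bio07"] = b["bio05"] - b["bio06"]
    with np.errstate(divide="ignore", invalid="ignore"):
        b["bio03"] = np.where(b["bio07"] > 0, b["bio02"] / b["bio07"] * 100.0, 0.0)

    q_t = _quarter_sums(tavg) / 3.0   # quarter mean temperature
    q_p = _quarter_sums(prec)         # quarter precipitation total
    wettest_q = q_p.argmax(axis=0)
    driest_q = q_p.argmin(axis=0)
    warmest_q = q_t.argmax(axis=0)
    coldest_q = q_t.argmin(axis=0)

    def take(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stack, idx[None], axis=0)[0]

    b["bio08"] = take(q_t, wettest_q)
    b["bio09"] = take(q_t, driest_q)
    b["bio10"] = take(q_t, warmest_q)
    b["bio11"] = take(q_t, coldest_q)
    b["bio12"] = prec.sum(axis=0)
    b["bio13"] = prec.max(axis=0)
    b["bio14"] = prec.min(axis=0)
    b["bio15"] = 100.0 * prec.std(axis=0, ddof=1) / (1.0 + b["bio12"] / 12.0)
    b["bio16"] = take(q_p, wettest_q)
    b["bio17"] = take(q_p, driest_q)
    b["bio18"] = take(q_p, warmest_q)
    b["bio19"] = take(q_p, coldest_q)

    mask = template.nodata_mask
    for g in monthly_tmax + monthly_tmin + monthly_prec:
        mask = mask | g.nodata_mask
    return BioclimSet({name: template.with_values(b[name], mask.copy()) for name in BIOCLIM_NAMES})


def compute_efas(vi_series: list[RasterGrid]) -> EFASet:
    """Annual mean, seasonal SD and 1-based peak index of a 23-composite year."""
    if len(vi_series) != 23:
        raise ArityError(f"an EFA year requires exactly 23 composites, got {len(vi_series)}")
    ref = vi_series[0]
    for g in vi_series[1:]:
        if not g.same_geometry(ref):
            raise GeometryError("vegetation-index composites are not co-registered")
    arr = np.stack([g.values.astype(float) for g in vi_series])
    mask = np.zeros(ref.values.shape, dtype=bool)
    for g in vi_series:
        mask |= g.nodata_mask
    return EFASet(
        efa_mean=ref.with_values(arr.mean(axis=0), mask.copy()),
        efa_sd=ref.with_values(arr.std(axis=0, ddof=1), mask.copy()),
        efa_peak=ref.with_values(arr.argmax(axis=0).astype(float) + 1.0, mask.copy()),
    )


def aggregate_lulc_fractions(landcover: RasterGrid, target_cell_size: float) -> FractionalCover:
    """Per-class cover fractions on a coarser grid by exact block counting.

    The target cell size must be an integer multiple of the fine cell size;
    partial edge blocks use only the fine cells they cover.  The remainder
    1 - (scrub + forest + crop) is the "other" class.
    """
    ratio = target_cell_size / landcover.cell_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise GeometryError(
            "target cell size must be an integer multiple of the fine cell size"
        )
    k = int(round(ratio))
    codes = landcover.values.astype(int)
    nr, nc = codes.shape
    out_r = int(np.ceil(nr / k))
    out_c = int(np.ceil(nc / k))
    fracs = {cls: np.zeros((out_r, out_c)) for cls in LANDCOVER_CLASSES[:3]}
    mask = np.zeros((out_r, out_c), dtype=bool)
    for i in range(out_r):
        for j in range(out_c):
            blk = codes[i * k : (i + 1) * k, j * k : (j + 1) * k]
            mblk = landcover.nodata_mask[i * k : (i + 1) * k, j * k : (j + 1) * k]
            if mblk.all():
                mask[i, j] = True
                continue
            valid = blk[~mblk]
            for ci, cls in enumerate(LANDCOVER_CLASSES[:3]):
                fracs[cls][i, j] = np.count_nonzero(valid == ci) / valid.size
    coarse = RasterGrid(
        np.zeros((out_r, out_c)), target_cell_size, landcover.origin, mask
    )
    return FractionalCover(
        frac_scrubland=coarse.with_values(fracs["scrubland"], mask.copy()),
        frac_forest=coarse.with_values(fracs["forest"], mask.copy()),
        frac_cropland=coarse.with_values(fracs["cropland"], mask.copy()),
    )
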