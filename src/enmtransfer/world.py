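"""Synthetic two-epoch landscapes, virtual species and survey sampling.

The generator emulates the study system the pipeline is designed for: a
fine-resolution mountain landscape dominated by shrubland and forest, nested
inside a much larger coarse-resolution region; between the two survey epochs
the climate shifts, abandoned cropland encroaches to scrubland (and scrubland
to forest), and fire patches knock woody cover back.  Virtual species have a
known logistic suitability over any subset of the standardized predictors,
so every downstream claim can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import child_rng
from .raster import ConfigurationError, RasterGrid

LANDCOVER_CLASSES = ("scrubland", "forest", "cropland", "other")
N_COMPOSITES = 23
ORIGINS = ("Eurosiberian", "Mediterranean")
PHENOLOGIES = ("sedentary", "migrant")
SPECIALIZATIONS = ("generalist", "specialist")
PREFERENCES = ("forest", "open")

# Per-class seasonal vegetation-index profile: (annual mean, seasonal
# amplitude, peak composite index 0-based).  Croplands green up early and
# strongly; forests are productive with a muted cycle; bare/urban "other"
# stays low year-round.
_VI_PROFILE = {
    "scrubland": (0.30, 0.10, 12),
    "forest": (0.45, 0.15, 13),
    "cropland": (0.35, 0.25, 8),
    "other": (0.12, 0.05, 12),
}

# Monthly climatology baselines (temperate NW-Iberian shape): tmax (degC),
# diurnal range (degC), precipitation (mm) with a summer drought.
_BASE_TMAX = np.array([9, 11, 14, 16, 19, 24, 27, 27, 24, 18, 13, 10], dtype=float)
_BASE_RANGE = np.array([8, 8, 9, 9, 10, 11, 12, 12, 11, 9, 8, 8], dtype=float)
_BASE_PREC = np.array([140, 120, 100, 110, 90, 50, 25, 30, 70, 130, 160, 150], dtype=float)


@dataclass
class ChangeScenario:
    """Environmental change applied between the two survey epochs."""

    tmax_delta: float = 1.0       # degC added to every monthly tmax
    tmin_delta: float = 1.0       # degC added to every monthly tmin
    prec_delta: float = -10.0     # mm added to every monthly precipitation
    encroachment_rate: float = 0.35  # fraction of cropland->scrubland and scrubland->forest
    n_fires: int = 3
    fire_patch_radius: float = 5.0   # cells

    def is_zero(self) -> bool:
        return (
            self.tmax_delta == 0
            and self.tmin_delta == 0
            and self.prec_delta == 0
            and self.encroachment_rate == 0
            and self.n_fires == 0
        )


@dataclass
class WorldConfig:
    """Landscape parameters; defaults mirror the study system's conditions."""

    fine_shape: tuple[int, int] = (80, 80)
    fine_cell_size: float = 230.0
    coarse_cell_size: float = 10_000.0
    regional_extent_factor: float = 10.0   # regional extent / local extent
    correlation_length: float = 8.0        # smoothing sigma, in fine cells
    climate_noise_amp: float = 1.2         # degC spatial anomaly SD
    prec_noise_amp: float = 0.25           # relative precipitation anomaly SD
    climate_gradient: float = 8.0          # degC tmax span across the REGIONAL extent
    prec_gradient: float = 0.8             # relative precip span across the region
    landcover_subfactor: int = 4  # land cover lives on a (fine/subfactor) grid
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "scrubland": 0.69,
            "forest": 0.21,
            "cropland": 0.07,
            "other": 0.03,
        }
    )
    vi_noise_amp: float = 0.05
    change: ChangeScenario = field(default_factory=ChangeScenario)

    def __post_init__(self) -> None:
        nr, nc = self.fine_shape
        if nr < 1 or nc < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if self.fine_cell_size <= 0 or self.coarse_cell_size <= 0:
            raise ConfigurationError("cell sizes must be positive")
        if self.landcover_subfactor < 1:
            raise ConfigurationError("landcover_subfactor must be >= 1")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-6:
            raise ConfigurationError("class proportions must sum to 1")


@dataclass
class EpochLayers:
    """All raw layers of one epoch at one resolution tier."""

    monthly_tmax: list[RasterGrid]
    monthly_tmin: list[RasterGrid]
    monthly_prec: list[RasterGrid]
    landcover: RasterGrid | None = None      # fine tier only
    vi_series: list[RasterGrid] | None = None  # fine tier only


@dataclass
class SyntheticWorld:
    config: WorldConfig
    fine: dict[str, EpochLayers]    # keyed by epoch "t0"/"t1"
    coarse: dict[str, EpochLayers]  # climate only

    @property
    def fine_template(self) -> RasterGrid:
        return self.fine["t0"].monthly_tmax[0]

    @property
    def coarse_template(self) -> RasterGrid:
        return self.coarse["t0"].monthly_tmax[0]


@dataclass
class VirtualSpecies:
    """Ground-truth species: logistic suitability over named predictors."""

    species_id: str
    coefficients: dict[str, float]
    intercept: float
    origin: str
    phenology: str
    specialization: str
    preference: str

    def traits(self) -> dict[str, str]:
        return {
            "origin": self.origin,
            "phenology": self.phenology,
            "specialization": self.specialization,
            "preference": self.preference,
        }


# ---------------------------------------------------------------------------
# landscape generation

def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _grid_fractions(grid_geom: RasterGrid, region_center, region_width) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates normalized to [-0.5, 0.5] over the regional extent."""
    xs, ys = grid_geom.cell_centers()
    gx = (xs - region_center[0]) / region_width
    gy = (ys - region_center[1]) / region_width
    return np.meshgrid(gx, gy)


def _climate_tier(template: RasterGrid, cfg: WorldConfig, region_center,
                  region_width, rng, sigma) -> EpochLayers:
    gx, gy = _grid_fractions(template, region_center, region_width)
    # one persistent spatial anomaly per variable, shared across months
    t_anom = (
        cfg.climate_noise_amp * _smooth_field(template.values.shape, sigma, rng)
        if cfg.climate_noise_amp > 0
        else np.zeros(template.values.shape)
    )
    p_anom = (
        cfg.prec_noise_amp * _smooth_field(template.values.shape, sigma, rng)
        if cfg.prec_noise_amp > 0
        else np.zeros(template.values.shape)
    )
    spatial_t = cfg.climate_gradient * (0.6 * gx - 0.4 * gy) + t_anom
    spatial_p = cfg.prec_gradient * (0.5 * gy - 0.3 * gx) + p_anom
    tmax, tmin, prec = [], [], []
    for m in range(12):
        tx = _BASE_TMAX[m] + spatial_t
        tn = tx - _BASE_RANGE[m]
        # wetter sites are disproportionately wetter in the wet season, so
        # precipitation seasonality (its CV) itself varies across space
        w_m = 1.0 + 0.6 * np.cos(2 * np.pi * m / 12.0)
        pr = np.clip(_BASE_PREC[m] * (1.0 + w_m * spatial_p), 0.0, None)
        tmax.append(template.with_values(tx))
        tmin.append(template.with_values(tn))
        prec.append(template.with_values(pr))
    return EpochLayers(tmax, tmin, prec)


def _landcover(template: RasterGrid, cfg: WorldConfig, rng, sigma) -> RasterGrid:
    """Patch-structured categorical map matching the target class proportions.

    Generated on a grid ``landcover_subfactor`` times finer than the
    modelling grid (mirroring 30 m imagery under a ~230 m analysis grid), so
    block aggregation later yields genuinely fractional covers.
    """
    sub = cfg.landcover_subfactor
    shape = (template.n_rows * sub, template.n_cols * sub)
    sub_template = RasterGrid(
        np.zeros(shape), template.cell_size / sub, template.origin
    )
    f = _smooth_field(shape, sigma * sub, rng)
    order = np.argsort(f, axis=None)
    n = f.size
    codes = np.empty(n, dtype=float)
    start = 0
    for ci, cls in enumerate(LANDCOVER_CLASSES):
        cnt = int(round(cfg.class_proportions[cls] * n))
        if ci == len(LANDCOVER_CLASSES) - 1:
            cnt = n - start
        codes[order[start : start + cnt]] = ci
        start += cnt
    return sub_template.with_values(codes.reshape(shape))


def class_fractions(landcover: RasterGrid, template: RasterGrid) -> dict[str, np.ndarray]:
    """Per-class cover fractions of the sub-resolution map on the fine grid."""
    sub = int(round(template.cell_size / landcover.cell_size))
    codes = landcover.values.astype(int)
    nr, nc = template.n_rows, template.n_cols
    blocks = codes.reshape(nr, sub, nc, sub)
    out = {}
    for ci, cls in enumerate(LANDCOVER_CLASSES):
        out[cls] = (blocks == ci).mean(axis=(1, 3))
    return out


def _vi_series(landcover: RasterGrid, template: RasterGrid, cfg: WorldConfig,
               rng, sigma) -> list[RasterGrid]:
    """Seasonal vegetation-index year: per-cell mixture of class profiles."""
    fracs = class_fractions(landcover, template)
    shape = template.values.shape
    site_anom = (
        cfg.vi_noise_amp * _smooth_field(shape, sigma, rng)
        if cfg.vi_noise_amp > 0
        else np.zeros(shape)
    )
    series = []
    for t in range(N_COMPOSITES):
        seasonal = np.zeros(shape)
        for cls in LANDCOVER_CLASSES:
            m, a, p = _VI_PROFILE[cls]
            seasonal += fracs[cls] * (m + a * np.cos(2 * np.pi * (t - p) / N_COMPOSITES))
        eps = (
            0.4 * cfg.vi_noise_amp * _smooth_field(shape, sigma, rng)
            if cfg.vi_noise_amp > 0
            else 0.0
        )
        series.append(template.with_values(np.clip(seasonal + site_anom + eps, -1.0, 1.0)))
    return series


def make_world(config: WorldConfig, seed: int) -> SyntheticWorld:
    """Generate both epochs of a synthetic world (t1 via ``config.change``)."""
    nr, nc = config.fine_shape
    fine_w = nc * config.fine_cell_size
    fine_h = nr * config.fine_cell_size
    fine_template = RasterGrid(np.zeros((nr, nc)), config.fine_cell_size, (0.0, fine_h))

    region_w = config.regional_extent_factor * max(fine_w, fine_h)
    n_coarse = max(2, int(np.ceil(region_w / config.coarse_cell_size)))
    pad_x = (n_coarse * config.coarse_cell_size - fine_w) / 2
    pad_y = (n_coarse * config.coarse_cell_size - fine_h) / 2
    coarse_template = RasterGrid(
        np.zeros((n_coarse, n_coarse)), config.coarse_cell_size, (-pad_x, fine_h + pad_y)
    )
    center = (fine_w / 2, fine_h / 2)

    sigma_fine = config.correlation_length
    # same physical correlation length on the coarse grid
    sigma_coarse = max(
        0.5, config.correlation_length * config.fine_cell_size / config.coarse_cell_size
    )

    fine_t0 = _climate_tier(
        fine_template, config, center, region_w, child_rng(seed, "climate-fine"), sigma_fine
    )
    coarse_t0 = _climate_tier(
        coarse_template, config, center, region_w, child_rng(seed, "climate-coarse"), sigma_coarse
    )
    fine_t0.landcover = _landcover(
        fine_template, config, child_rng(seed, "landcover"), sigma_fine
    )
    fine_t0.vi_series = _vi_series(
        fine_t0.landcover, fine_template, config, child_rng(seed, "vi-t0"), sigma_fine
    )

    world = SyntheticWorld(
        config=config, fine={"t0": fine_t0}, coarse={"t0": coarse_t0}
    )
    fine_t1, coarse_t1 = apply_change(world, config.change, seed)
    world.fine["t1"] = fine_t1
    world.coarse["t1"] = coarse_t1
    return world


def apply_change(world: SyntheticWorld, change: ChangeScenario, seed: int
                 ) -> tuple[EpochLayers, EpochLayers]:
    """Derive epoch-t1 layers from t0 under a change scenario.

    Climate shifts additively; a fraction ``encroachment_rate`` of cropland
    converts to scrubland and of scrubland to forest (land abandonment);
    ``n_fires`` disc patches convert forest to scrubland and scrubland to
    bare "other".  The vegetation-index year is regenerated from the t1 land
    cover.  Cells only move between the four classes; none appear or vanish.
    """
    if not 0 <= change.encroachment_rate <= 1:
        raise ConfigurationError("encroachment_rate must be in [0, 1]")
    if change.n_fires < 0:
        raise ConfigurationError("n_fires must be non-negative")
    cfg = world.config
    rng = child_rng(seed, "change")

    def shift(tier: EpochLayers) -> EpochLayers:
        tmax = [g.with_values(g.values + change.tmax_delta) for g in tier.monthly_tmax]
        tmin = [g.with_values(g.values + change.tmin_delta) for g in tier.monthly_tmin]
        prec = [
            g.with_values(np.clip(g.values + change.prec_delta, 0.0, None))
            for g in tier.monthly_prec
        ]
        return EpochLayers(tmax, tmin, prec)

    fine_t1 = shift(world.fine["t0"])
    coarse_t1 = shift(world.coarse["t0"])

    lc = world.fine["t0"].landcover.values.astype(int).copy()
    idx = {cls: i for i, cls in enumerate(LANDCOVER_CLASSES)}
    # encroachment acts on the t0 state, both transitions simultaneously
    if change.encroachment_rate > 0:
        for src, dst in (("cropland", "scrubland"), ("scrubland", "forest")):
            cells = np.flatnonzero(world.fine["t0"].landcover.values.astype(int) == idx[src])
            k = int(round(change.encroachment_rate * cells.size))
            if k > 0:
                chosen = rng.choice(cells, size=k, replace=False)
                lc.flat[chosen] = idx[dst]
    # fires: disc patches centred on burnable (forest/scrubland) cells
    nr, nc = lc.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    for _ in range(int(change.n_fires)):
        burnable = np.flatnonzero((lc == idx["forest"]) | (lc == idx["scrubland"]))
        if burnable.size == 0:
            break
        c = rng.choice(burnable)
        cr, ccol = divmod(int(c), nc)
        disc = (rr - cr) ** 2 + (cc - ccol) ** 2 <= change.fire_patch_radius**2
        pre = lc.copy()  # both transitions act on the pre-fire state
        lc[disc & (pre == idx["forest"])] = idx["scrubland"]
        lc[disc & (pre == idx["scrubland"])] = idx["other"]

    t0 = world.fine["t0"]
    if change.is_zero():
        fine_t1.landcover = t0.landcover.copy()
        fine_t1.vi_series = [g.copy() for g in t0.vi_series]
    else:
        fine_t1.landcover = t0.landcover.with_values(lc.astype(float))
        fine_t1.vi_series = _vi_series(
            fine_t1.landcover,
            world.fine["t0"].monthly_tmax[0],
            cfg,
            child_rng(seed, "vi-t1"),
            cfg.correlation_length,
        )
    return fine_t1, coarse_t1


# ---------------------------------------------------------------------------
# virtual species

_FAMILY_PREDICTORS = {
    "CLI": ("bio05", "bio12", "bio15"),
    "LULC": ("frac_forest", "frac_scrubland", "frac_cropland"),
    "EFA": ("efa_mean", "efa_sd", "efa_peak"),
}


def _balanced_traits(i: int) -> dict[str, str]:
    """Row i of a marginally balanced binary design (parity column 4th)."""
    b0, b1, b2 = (i >> 0) & 1, (i >> 1) & 1, (i >> 2) & 1
    b3 = b0 ^ b1 ^ b2
    return {
        "origin": ORIGINS[b0],
        "phenology": PHENOLOGIES[b1],
        "specialization": SPECIALIZATIONS[b2],
        "preference": PREFERENCES[b3],
    }


def make_virtual_species(
    n_species: int,
    trait_design: str = "balanced",
    beta_ranges: tuple[float, float] = (0.25, 0.75),
    seed: int = 0,
    families: tuple[str, ...] = ("CLI", "LULC", "EFA"),
    intercept_range: tuple[float, float] = (-1.0, 0.3),
) -> list[VirtualSpecies]:
    """Draw virtual species with trait-consistent suitability coefficients.

    Coefficients apply to *standardized* predictors.  Trait links: forest
    preference forces a positive forest-fraction weight (open preference a
    negative one); specialists get 1.5x steeper responses (narrower niches);
    migrants load positively on vegetation seasonality; Mediterranean species
    positively on summer maximum temperature.
    """
    if n_species < 1:
        raise ConfigurationError("n_species must be >= 1")
    if not beta_ranges or beta_ranges[0] > beta_ranges[1] or beta_ranges[0] < 0:
        raise ConfigurationError("beta_ranges must be a (lo, hi) magnitude pair")
    if trait_design not in ("balanced",):
        raise ConfigurationError(f"unknown trait design {trait_design!r}")
    for fam in families:
        if fam not in _FAMILY_PREDICTORS:
            raise ConfigurationError(f"unknown driver family {fam!r}")

    rng = child_rng(seed, "species")
    lo, hi = beta_ranges
    out = []
    for i in range(n_species):
        traits = _balanced_traits(i)
        beta: dict[str, float] = {}
        for fam in families:
            for name in _FAMILY_PREDICTORS[fam]:
                mag = rng.uniform(lo, hi)
                sign = rng.choice([-1.0, 1.0])
                beta[name] = sign * mag
        if "LULC" in families:
            mag = abs(beta["frac_forest"])
            beta["frac_forest"] = mag if traits["preference"] == "forest" else -mag
        if "EFA" in families and traits["phenology"] == "migrant":
            beta["efa_sd"] = abs(beta["efa_sd"])
        if "CLI" in families and traits["origin"] == "Mediterranean":
            beta["bio05"] = abs(beta["bio05"])
        if traits["specialization"] == "specialist":
            beta = {k: 1.5 * v for k, v in beta.items()}
        out.append(
            VirtualSpecies(
                species_id=f"VS{i + 1:02d}",
                coefficients=beta,
                intercept=float(rng.uniform(*intercept_range)),
                **traits,
            )
        )
    return out


def true_suitability(species: VirtualSpecies, predictor_stack: dict[str, RasterGrid]) -> RasterGrid:
    """Logistic ground-truth suitability over a standardized predictor stack."""
    first = next(iter(predictor_stack.values()))
    eta = np.full(first.values.shape, species.intercept, dtype=float)
    mask = np.zeros(first.values.shape, dtype=bool)
    for name, b in species.coefficients.items():
        if name not in predictor_stack:
            raise KeyError(f"predictor {name!r} missing from the stack")
        layer = predictor_stack[name]
        eta = eta + b * layer.values
        mask |= layer.nodata_mask
    suit = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    suit = np.where(mask, 0.0, suit)
    return first.with_values(suit, mask)


# ---------------------------------------------------------------------------
# surveys

PROTOCOLS = ("calibration", "internal_tt", "external_tt")
OCC_COLUMNS = ("species_id", "x", "y", "detected", "epoch", "protocol")


class SamplingError(ValueError):
    pass


@dataclass
class SurveyDesign:
    """The three point-count campaigns of the study design."""

    n_calibration: int = 344
    n_internal: int = 204
    n_external: int = 384
    internal_subset: str = "random"  # how the revisited subset is chosen

    def __post_init__(self) -> None:
        if self.n_internal > self.n_calibration:
            raise ConfigurationError("n_internal cannot exceed n_calibration")
        if self.internal_subset not in ("random", "first"):
            raise ConfigurationError("internal_subset must be 'random' or 'first'")


def sample_survey_locations(template: RasterGrid, design: SurveyDesign, seed: int
                            ) -> dict[str, np.ndarray]:
    """Draw survey point locations (cell centers) shared by all species.

    Calibration points are uniform without replacement over unmasked cells;
    the internal-TT revisit reuses a subset of them; external-TT points are
    fresh cells disjoint from the calibration set.
    """
    rng = child_rng(seed, "survey-locations")
    free = np.flatnonzero(~template.nodata_mask.ravel())
    if design.n_calibration + design.n_external > free.size:
        raise SamplingError("survey design exceeds the number of available cells")
    chosen = rng.choice(free, size=design.n_calibration + design.n_external, replace=False)
    cal = chosen[: design.n_calibration]
    ext = chosen[design.n_calibration :]
    if design.internal_subset == "random":
        internal = rng.choice(cal, size=design.n_internal, replace=False)
    else:
        internal = cal[: design.n_internal]
    xs, ys = template.cell_centers()

    def coords(flat_idx):
        r, c = np.divmod(flat_idx, template.n_cols)
        return np.column_stack([xs[c], ys[r]])

    return {"calibration": coords(cal), "internal_tt": coords(internal),
            "external_tt": coords(ext)}


def sample_detections(
    locations: dict[str, np.ndarray],
    suit_t0: RasterGrid,
    suit_t1: RasterGrid,
    species_id: str,
    seed: int,
) -> pd.DataFrame:
    """Bernoulli presence/absence draws from the true suitability surfaces.

    Detection equals occurrence (no imperfect-detection layer): calibration
    points are drawn from the t0 truth, both transferability campaigns from
    the t1 truth.
    """
    rng = child_rng(seed, "detections", species_id)
    frames = []
    for protocol, pts in locations.items():
        suit = suit_t0 if protocol == "calibration" else suit_t1
        p = suit.sample(pts[:, 0], pts[:, 1])
        det = (rng.random(len(pts)) < p).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "species_id": species_id,
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "detected": det,
                    "epoch": "t0" if protocol == "calibration" else "t1",
                    "protocol": protocol,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def sample_surveys(
    suit_t0: RasterGrid,
    suit_t1: RasterGrid,
    design: SurveyDesign,
    seed: int,
    species_id: str = "VS01",
) -> pd.DataFrame:
    """Locations plus detections for a single species (convenience wrapper)."""
    locations = sample_survey_locations(suit_t0, design, seed)
    return sample_detections(locations, suit_t0, suit_t1, species_id, seed)


def validate_occurrences(occ: pd.DataFrame) -> None:
    """Assert the survey-geometry invariants on an occurrence table."""
    missing = set(OCC_COLUMNS) - set(occ.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns {sorted(missing)}")
    bad = set(occ["protocol"].unique()) - set(PROTOCOLS)
    if bad:
        raise ValueError(f"unknown protocols {sorted(bad)}")
    for sid, grp in occ.groupby("species_id"):
        cal = set(map(tuple, grp.loc[grp.protocol == "calibration", ["x", "y"]].to_numpy()))
        internal = set(map(tuple, grp.loc[grp.protocol == "internal_tt", ["x", "y"]].to_numpy()))
        ext = set(map(tuple, grp.loc[grp.protocol == "external_tt", ["x", "y"]].to_numpy()))
        if not internal <= cal:
            raise ValueError(f"{sid}: internal-TT locations are not a subset of calibration")
        if ext & cal:
            raise ValueError(f"{sid}: external-TT locations overlap calibration")


def prevalence_filter(occ: pd.DataFrame, min_presences: int = 15) -> list[str]:
    """Species retained for modelling: calibration presences strictly > threshold."""
    cal = occ[occ["protocol"] == "calibration"]
    counts = cal.groupby("species_id")["detected"].sum()
    return sorted(counts[counts > min_presences].index.tolist())
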