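"""End-to-end experiment orchestration, configuration and file formats.

The full in-silico experiment: simulate a two-epoch world and virtual
species -> derive the three predictor families at both scales -> fit the
7 predictor sets x 2 integration approaches per species -> evaluate under
the three regimes -> niche-overlap matrices -> multimodel inference and
trait contrasts.  Every stage is deterministic given the master seed, and
every output table carries the configuration hash so tables from different
runs cannot be mixed downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import child_rng
from . import __version__
from .ensemble import (
    APPROACHES,
    EnsembleENMResults,
    EnsembleENM,
    ModelSpec,
    PREDICTOR_SETS,
    build_combined,
    fit_regional_climate,
    project_direct,
)
from .evaluation import (
    EvalRecord,
    InputError,
    evaluate_scores,
    evaluate_transfer,
    max_tss_threshold,
    records_to_frame,
    schoener_d,
)
from .predictors import aggregate_lulc_fractions, compute_bioclim, compute_efas
from .raster import RasterGrid, standardize_stack
from .world import (
    ChangeScenario,
    SurveyDesign,
    SyntheticWorld,
    VirtualSpecies,
    WorldConfig,
    make_virtual_species,
    make_world,
    prevalence_filter,
    sample_detections,
    sample_survey_locations,
    true_suitability,
    validate_occurrences,
)
from .inference import InferenceTable, dredge_all_subsets, trait_contrast_table

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ("origin", "phenology", "specialization", "preference")
FAMILY_MEMBERS = {
    "CLI": ("bio05", "bio12", "bio15"),
    "LULC": ("frac_scrubland", "frac_forest", "frac_cropland"),
    "EFA": ("efa_mean", "efa_sd", "efa_peak"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ConfigHashMismatch(ValueError):
    """Tables from different runs were mixed."""


# ---------------------------------------------------------------------------
# configuration

@dataclass
class ExperimentConfig:
    """Everything a full run needs; defaults mirror the study design."""

    world: WorldConfig = field(default_factory=WorldConfig)
    survey: SurveyDesign = field(default_factory=SurveyDesign)
    model: ModelSpec = field(default_factory=ModelSpec)
    n_species: int = 8
    trait_design: str = "balanced"
    beta_ranges: tuple[float, float] = (0.25, 0.75)
    families: tuple[str, ...] = ("CLI", "LULC", "EFA")
    min_presences: int = 15
    auc_cut: float = 0.7
    threshold_rule: str = "max_tss"  # or "fixed" (0.5)
    traits_for_inference: tuple[str, ...] = TRAIT_COLUMNS

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        world = dict(d.pop("world", {}))
        change = ChangeScenario(**world.pop("change", {}))
        fine_shape = world.pop("fine_shape", (80, 80))
        wc = WorldConfig(fine_shape=tuple(fine_shape), change=change, **world)
        survey = SurveyDesign(**d.pop("survey", {}))
        model_d = dict(d.pop("model", {}))
        if "algorithms" in model_d:
            model_d["algorithms"] = tuple(model_d["algorithms"])
        model = ModelSpec(**model_d)
        for key in ("beta_ranges", "families", "traits_for_inference"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(world=wc, survey=survey, model=model, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def reduced_config(**overrides) -> ExperimentConfig:
    """A desk-scale configuration that completes in minutes on one CPU.

    Grid and replicate counts are scaled down; the survey design, filters and
    thresholds keep the study constants.
    """
    cfg = ExperimentConfig(
        world=WorldConfig(fine_shape=(60, 60)),
        model=ModelSpec(n_replicates=10),
        n_species=8,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# predictor derivation

@dataclass
class PredictorSuite:
    """Raw and standardized predictor stacks for both scales and epochs.

    Fine stacks hold the nine local predictors; coarse stacks the three
    regional climate predictors.  Epoch t1 is standardized with the t0
    statistics (never recomputed), so projections stay on the calibration
    scale.
    """

    fine_raw: dict[str, dict[str, RasterGrid]]
    fine_std: dict[str, dict[str, RasterGrid]]
    fine_stats: dict[str, tuple[float, float]]
    coarse_raw: dict[str, dict[str, RasterGrid]]
    coarse_std: dict[str, dict[str, RasterGrid]]
    coarse_stats: dict[str, tuple[float, float]]

    def fine_family(self, family: str, epoch: str) -> dict[str, RasterGrid]:
        return {n: self.fine_std[epoch][n] for n in FAMILY_MEMBERS[family]}


def derive_predictors(world: SyntheticWorld) -> PredictorSuite:
    """Bioclim + EFA + fractional-cover layers for both epochs and scales."""
    fine_raw: dict[str, dict[str, RasterGrid]] = {}
    coarse_raw: dict[str, dict[str, RasterGrid]] = {}
    for epoch in ("t0", "t1"):
        tier = world.fine[epoch]
        bio = compute_bioclim(tier.monthly_tmax, tier.monthly_tmin, tier.monthly_prec)
        efa = compute_efas(tier.vi_series)
        frac = aggregate_lulc_fractions(tier.landcover, world.config.fine_cell_size)
        layers = {name: bio[name] for name in FAMILY_MEMBERS["CLI"]}
        layers.update(frac.as_dict())
        layers.update(efa.as_dict())
        fine_raw[epoch] = layers
        ctier = world.coarse[epoch]
        cbio = compute_bioclim(ctier.monthly_tmax, ctier.monthly_tmin, ctier.monthly_prec)
        coarse_raw[epoch] = {name: cbio[name] for name in FAMILY_MEMBERS["CLI"]}

    fine_std_t0, fine_stats = standardize_stack(fine_raw["t0"])
    fine_std_t1, _ = standardize_stack(fine_raw["t1"], reference_stats=fine_stats)
    coarse_std_t0, coarse_stats = standardize_stack(coarse_raw["t0"])
    coarse_std_t1, _ = standardize_stack(coarse_raw["t1"], reference_stats=coarse_stats)
    return PredictorSuite(
        fine_raw=fine_raw,
        fine_std={"t0": fine_std_t0, "t1": fine_std_t1},
        fine_stats=fine_stats,
        coarse_raw=coarse_raw,
        coarse_std={"t0": coarse_std_t0, "t1": coarse_std_t1},
        coarse_stats=coarse_stats,
    )


def regional_truth(species: VirtualSpecies, coarse_std: dict[str, RasterGrid]) -> RasterGrid:
    """Climate-marginal ground truth at the regional scale.

    Only the climate coefficients act regionally (land cover and vegetation
    dynamics are local drivers), so the regional niche is the species'
    climate envelope.
    """
    clim = {k: v for k, v in species.coefficients.items() if k in coarse_std}
    sub = dataclasses.replace(species, coefficients=clim)
    return true_suitability(sub, coarse_std)


def regional_occurrences(
    species: VirtualSpecies, coarse_std: dict[str, RasterGrid], seed: int
) -> pd.DataFrame:
    """Atlas-style regional data: one Bernoulli draw per coarse cell at t0."""
    truth = regional_truth(species, coarse_std)
    template = next(iter(coarse_std.values()))
    xs, ys = template.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    ok = ~truth.nodata_mask
    p = truth.values[ok]
    rng = child_rng(seed, "regional", species.species_id)
    det = (rng.random(p.size) < p).astype(int)
    return pd.DataFrame(
        {
            "species_id": species.species_id,
            "x": xx[ok],
            "y": yy[ok],
            "detected": det,
            "epoch": "t0",
            "protocol": "calibration",
        }
    )


# ---------------------------------------------------------------------------
# per-species fitting and evaluation

@dataclass
class SpeciesModels:
    """Every fitted object and suitability surface for one species."""

    species: VirtualSpecies
    ensembles: dict[tuple[str, str], EnsembleENMResults]  # (predictor_set, approach)
    maps: dict[tuple[str, str, str], RasterGrid]          # (predictor_set, approach, epoch)
    thresholds: dict[tuple[str, str], float]
    regional: EnsembleENMResults | None = None


def _combined_names(pset: str) -> list[str]:
    return pset.split("+")


def fit_species(
    species: VirtualSpecies,
    occ: pd.DataFrame,
    suite: PredictorSuite,
    spec: ModelSpec,
    seed: int,
    threshold_rule: str = "max_tss",
    predictor_sets: tuple[str, ...] = PREDICTOR_SETS,
    approaches: tuple[str, ...] = APPROACHES,
) -> SpeciesModels:
    """Fit the requested predictor sets/approaches for one species."""
    sid = species.species_id
    cal = occ[(occ.species_id == sid) & (occ.protocol == "calibration")]

    def stage_seed(*keys) -> int:
        return int(child_rng(seed, "fit", sid, *keys).integers(2**31))

    ensembles: dict[tuple[str, str], EnsembleENMResults] = {}
    maps: dict[tuple[str, str, str], RasterGrid] = {}
    needed_fams = sorted(
        {f for pset in predictor_sets for f in _combined_names(pset)},
        key=("CLI", "LULC", "EFA").index,
    )
    need_regional = "hierarchical" in approaches and "CLI" in needed_fams

    # individual local ensembles (approach-invariant for LULC/EFA)
    for fam in needed_fams:
        if fam == "CLI" and "non_hierarchical" not in approaches:
            continue
        res = EnsembleENM(cal, suite.fine_family(fam, "t0"), spec).fit(stage_seed(fam))
        for epoch in ("t0", "t1"):
            m = res.predict_map(suite.fine_family(fam, epoch))
            for app in approaches:
                if fam == "CLI" and app == "hierarchical":
                    continue
                maps[(fam, app, epoch)] = m
        for app in approaches:
            if fam == "CLI" and app == "hierarchical":
                continue
            ensembles[(fam, app)] = res

    # regional climate model, direct-downscaled (hierarchical climate input)
    if need_regional:
        regional_occ = regional_occurrences(species, suite.coarse_std["t0"], seed)
        regional = fit_regional_climate(
            regional_occ, suite.coarse_std["t0"], spec, stage_seed("regional")
        )
        for epoch in ("t0", "t1"):
            fine_clim = {
                n: suite.fine_raw[epoch][n] for n in FAMILY_MEMBERS["CLI"]
            }
            fine_clim_std, _ = standardize_stack(
                fine_clim, reference_stats=suite.coarse_stats
            )
            maps[("CLI", "hierarchical", epoch)] = project_direct(regional, fine_clim_std)
        ensembles[("CLI", "hierarchical")] = regional
    else:
        regional = None

    # combined models: suitability surfaces of the components as predictors
    for pset in predictor_sets:
        if "+" not in pset:
            continue
        for app in approaches:
            stack_t0 = {f: maps[(f, app, "t0")] for f in _combined_names(pset)}
            res = build_combined(stack_t0, cal, spec, stage_seed(pset, app))
            ensembles[(pset, app)] = res
            for epoch in ("t0", "t1"):
                stack = {f: maps[(f, app, epoch)] for f in _combined_names(pset)}
                maps[(pset, app, epoch)] = res.predict_map(stack)

    # calibration-epoch binarization thresholds, frozen for transferability;
    # each model's threshold comes from its own calibration data, so the
    # regional (hierarchical climate) model thresholds on the regional
    # dataset — which is what lets its broad-envelope projections keep high
    # sensitivity at the local scale
    thresholds: dict[tuple[str, str], float] = {}
    xs, ys = cal["x"].to_numpy(), cal["y"].to_numpy()
    yobs = cal["detected"].to_numpy()
    for (pset, app) in ensembles:
        if threshold_rule == "fixed":
            thresholds[(pset, app)] = 0.5
        elif pset == "CLI" and app == "hierarchical":
            reg_map = regional.predict_map(suite.coarse_std["t0"])
            scores = reg_map.sample(
                regional_occ["x"].to_numpy(), regional_occ["y"].to_numpy()
            )
            thresholds[(pset, app)] = max_tss_threshold(
                scores, regional_occ["detected"].to_numpy()
            )
        else:
            scores = maps[(pset, app, "t0")].sample(xs, ys)
            thresholds[(pset, app)] = max_tss_threshold(scores, yobs)

    return SpeciesModels(
        species=species, ensembles=ensembles, maps=maps, thresholds=thresholds,
        regional=regional,
    )


def evaluate_species(models: SpeciesModels, occ: pd.DataFrame) -> list[EvalRecord]:
    """The three evaluation regimes for every (predictor_set, approach) cell."""
    sid = models.species.species_id
    cal = occ[(occ.species_id == sid) & (occ.protocol == "calibration")]
    xs, ys = cal["x"].to_numpy(), cal["y"].to_numpy()
    yobs = cal["detected"].to_numpy()
    records: list[EvalRecord] = []
    for (pset, app), res in models.ensembles.items():
        thr = models.thresholds[(pset, app)]
        scores_cal = models.maps[(pset, app, "t0")].sample(xs, ys)
        rec = evaluate_scores(
            scores_cal, yobs, sid, pset, app, "crossvalidation", threshold=thr
        )
        # headline crossvalidation AUC is the split-sample member evaluation
        rec.extras["calibration_auc"] = rec.auc
        rec.auc = res.split_sample_auc
        records.append(rec)
        for eval_type in ("internal_tt", "external_tt"):
            try:
                records.append(
                    evaluate_transfer(
                        models.maps[(pset, app, "t1")], occ, eval_type, sid, pset, app, thr
                    )
                )
            except InputError:
                # a campaign where the species was everywhere (or nowhere)
                # leaves the discrimination metrics undefined
                records.append(
                    EvalRecord(
                        species_id=sid, predictor_set=pset, approach=app,
                        eval_type=eval_type, auc=np.nan, sensitivity=np.nan,
                        tss=np.nan, kappa=np.nan, threshold=thr,
                        extras={"degenerate_campaign": True},
                    )
                )
    return records


# ---------------------------------------------------------------------------
# overlap and inference

def overlap_matrices(
    all_models: dict[str, SpeciesModels], approach: str = "non_hierarchical"
) -> dict[str, pd.DataFrame]:
    """Mean-across-species Schoener's D between predictor sets, per epoch."""
    out = {}
    for epoch in ("t0", "t1"):
        mat = pd.DataFrame(
            np.nan, index=list(PREDICTOR_SETS), columns=list(PREDICTOR_SETS)
        )
        for i, pa in enumerate(PREDICTOR_SETS):
            for pb in PREDICTOR_SETS[i:]:
                vals = [
                    schoener_d(m.maps[(pa, approach, epoch)], m.maps[(pb, approach, epoch)])
                    for m in all_models.values()
                ]
                mat.loc[pa, pb] = mat.loc[pb, pa] = float(np.mean(vals))
        out[epoch] = mat
    return out


def run_inference(
    records: pd.DataFrame, traits: tuple[str, ...] = TRAIT_COLUMNS
) -> tuple[dict[tuple[str, str], InferenceTable], pd.DataFrame]:
    """All-subsets GLM inference per evaluation type and trait, plus contrasts."""
    tables: dict[tuple[str, str], InferenceTable] = {}
    contrasts = []
    records = records.dropna(subset=["auc"])
    for trait in traits:
        for eval_type, sub in records.groupby("eval_type"):
            design = pd.DataFrame(
                {
                    "PRED": sub["predictor_set"].to_numpy(),
                    "APP": sub["approach"].to_numpy(),
                    "TRAIT": sub[trait].to_numpy(),
                }
            )
            tables[(eval_type, trait)] = dredge_all_subsets(sub["auc"].to_numpy(), design)
        ct = trait_contrast_table(records, trait)
        if not ct.empty:
            contrasts.append(ct)
    contrast_df = pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()
    return tables, contrast_df


# ---------------------------------------------------------------------------
# the full experiment

@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    world: SyntheticWorld
    suite: PredictorSuite
    species: list[VirtualSpecies]
    retained: list[str]
    occurrences: pd.DataFrame
    models: dict[str, SpeciesModels]
    records: pd.DataFrame
    overlap: dict[tuple[str, str], pd.DataFrame]  # (approach, epoch) -> matrix
    inference: dict[tuple[str, str], InferenceTable]
    contrasts: pd.DataFrame
    manifest: dict


def run_experiment(
    config: ExperimentConfig, seed: int, outdir: str | Path | None = None
) -> ExperimentResult:
    """Execute the whole pipeline; optionally persist all tables to ``outdir``."""
    t_start = time.time()
    cfg_hash = config.config_hash()
    manifest: dict = {
        "config_hash": cfg_hash,
        "seed": int(seed),
        "version": __version__,
        "warnings": [],
        "complete": False,
    }
    stage = "simulate"
    try:
        world = make_world(config.world, seed)
        species = make_virtual_species(
            config.n_species,
            config.trait_design,
            config.beta_ranges,
            seed,
            families=config.families,
        )
        stage = "derive"
        suite = derive_predictors(world)
        template = world.fine_template

        stage = "survey"
        locations = sample_survey_locations(template, config.survey, seed)
        truths = {}
        occ_frames = []
        for sp in species:
            s0 = true_suitability(sp, suite.fine_std["t0"])
            s1 = true_suitability(sp, suite.fine_std["t1"])
            truths[sp.species_id] = (s0, s1)
            occ_frames.append(
                sample_detections(locations, s0, s1, sp.species_id, seed)
            )
        occ = pd.concat(occ_frames, ignore_index=True)
        validate_occurrences(occ)
        retained = prevalence_filter(occ, config.min_presences)
        dropped = sorted(set(s.species_id for s in species) - set(retained))
        if dropped:
            manifest["warnings"].append(
                {"stage": "survey", "event": "prevalence_filter", "species": dropped}
            )

        stage = "fit"
        models: dict[str, SpeciesModels] = {}
        by_id = {s.species_id: s for s in species}
        for sid in retained:
            logger.info("fitting %s", sid)
            models[sid] = fit_species(
                by_id[sid], occ, suite, config.model, seed, config.threshold_rule
            )
            for (pset, app), res in models[sid].ensembles.items():
                if res.fallback:
                    manifest["warnings"].append(
                        {"stage": "fit", "event": "ensemble_fallback",
                         "species": sid, "predictor_set": pset, "approach": app}
                    )
                if res.fold_skips:
                    manifest["warnings"].append(
                        {"stage": "fit", "event": "fold_skips", "species": sid,
                         "predictor_set": pset, "approach": app,
                         "count": len(res.fold_skips)}
                    )

        stage = "evaluate"
        records_list: list[EvalRecord] = []
        for sid in retained:
            records_list.extend(evaluate_species(models[sid], occ))
        records = records_to_frame(records_list)
        trait_map = pd.DataFrame(
            [{"species_id": s.species_id, **s.traits()} for s in species]
        )
        records = records.merge(trait_map, on="species_id", how="left")
        records["config_hash"] = cfg_hash
        records["seed"] = int(seed)

        stage = "overlap"
        overlap: dict[tuple[str, str], pd.DataFrame] = {}
        for app in APPROACHES:
            for epoch, mat in overlap_matrices(models, app).items():
                overlap[(app, epoch)] = mat

        stage = "infer"
        inference, contrasts = run_inference(records, config.traits_for_inference)
        if not contrasts.empty:
            contrasts["config_hash"] = cfg_hash

        manifest["complete"] = True
    except Exception as exc:  # noqa: BLE001 - stage-named abort per contract
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        manifest["wall_time_s"] = round(time.time() - t_start, 2)

    result = ExperimentResult(
        config=config, seed=seed, world=world, suite=suite, species=species,
        retained=retained, occurrences=occ, models=models, records=records,
        overlap=overlap, inference=inference, contrasts=contrasts,
        manifest=manifest,
    )
    if outdir is not None:
        write_result(result, outdir)
    return result


# ---------------------------------------------------------------------------
# file formats

def write_occurrences(path: str | Path, occ: pd.DataFrame) -> None:
    validate_occurrences(occ)
    occ.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    occ = pd.read_csv(path)
    required = ["species_id", "x", "y", "detected", "epoch", "protocol"]
    missing = [c for c in required if c not in occ.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns {missing}")
    bad_protocol = ~occ["protocol"].isin(["calibration", "internal_tt", "external_tt"])
    if bad_protocol.any():
        row = int(occ.index[bad_protocol][0])
        raise ValueError(
            f"invalid value in column 'protocol' at row {row}: {occ.loc[row, 'protocol']!r}"
        )
    bad_det = ~occ["detected"].isin([0, 1])
    if bad_det.any():
        row = int(occ.index[bad_det][0])
        raise ValueError(f"invalid value in column 'detected' at row {row}")
    return occ


def load_trait_table() -> pd.DataFrame:
    """The packaged 27-species trait table (acronym + four binary traits)."""
    from importlib.resources import files

    path = files("enmtransfer").joinpath("data/trait_table.csv")
    df = pd.read_csv(str(path))
    vocab = {
        "origin": {"Eurosiberian", "Mediterranean"},
        "specialization": {"generalist", "specialist"},
        "preference": {"forest", "open"},
        "phenology": {"sedentary", "migrant"},
    }
    for col, allowed in vocab.items():
        bad = ~df[col].isin(list(allowed))
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(f"invalid value in column {col!r} at row {row}")
    return df


def write_result(result: ExperimentResult, outdir: str | Path) -> None:
    """Persist all result tables, the config and the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(outdir / "eval_records.csv", index=False)
    member_frames = []
    for sid, sm in result.models.items():
        for (pset, app), res in sm.ensembles.items():
            df = res.members_frame()
            df.insert(0, "species_id", sid)
            df.insert(1, "predictor_set", pset)
            df.insert(2, "approach", app)
            member_frames.append(df)
    if member_frames:
        members = pd.concat(member_frames, ignore_index=True)
        members["config_hash"] = result.manifest["config_hash"]
        members.to_csv(outdir / "member_aucs.csv", index=False)
    for (app, epoch), mat in result.overlap.items():
        mat.to_csv(outdir / f"overlap_{app}_{epoch}.csv")
    for (eval_type, trait), table in result.inference.items():
        df = table.table.copy()
        df["config_hash"] = result.manifest["config_hash"]
        df.to_csv(outdir / f"inference_{eval_type}_{trait}.csv", index=False)
    if not result.contrasts.empty:
        result.contrasts.to_csv(outdir / "trait_contrasts.csv", index=False)
    result.config.to_yaml(outdir / "config.yaml")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def check_config_hash(df: pd.DataFrame, config: ExperimentConfig) -> None:
    """Reject tables produced under a different configuration."""
    if "config_hash" not in df.columns:
        raise ConfigHashMismatch("table carries no config_hash column")
    hashes = set(df["config_hash"].unique())
    expected = {config.config_hash()}
    if hashes != expected:
        raise ConfigHashMismatch(
            f"table config hash {sorted(hashes)} does not match current config "
            f"{sorted(expected)}"
        )


# ---------------------------------------------------------------------------
# report

def make_report(result: ExperimentResult, outdir: str | Path) -> list[Path]:
    """Box-plot panels and overlap heatmaps summarizing a run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    rec = result.records
    fig, axes = plt.subplots(1, 3, figsize=(15, 4), sharey=True)
    for ax, eval_type in zip(axes, ("crossvalidation", "internal_tt", "external_tt")):
        sub = rec[rec.eval_type == eval_type]
        data = [sub[sub.predictor_set == p]["auc"].to_numpy() for p in PREDICTOR_SETS]
        ax.boxplot(data, tick_labels=list(PREDICTOR_SETS))
        ax.set_title(eval_type)
        ax.tick_params(axis="x", rotation=60)
        ax.set_ylabel("AUC")
    fig.tight_layout()
    p = outdir / "auc_by_predictor_set.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, len(TRAIT_COLUMNS), figsize=(14, 4), sharey=True)
    for ax, trait in zip(np.atleast_1d(axes), TRAIT_COLUMNS):
        levels = sorted(rec[trait].dropna().unique())
        data = [rec[rec[trait] == lv]["auc"].to_numpy() for lv in levels]
        ax.boxplot(data, tick_labels=levels)
        ax.set_title(trait)
    fig.tight_layout()
    p = outdir / "auc_by_trait.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    for (app, epoch), mat in result.overlap.items():
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=60)
        ax.set_yticks(range(len(mat)), mat.index)
        fig.colorbar(im, ax=ax, label="Schoener's D")
        ax.set_title(f"Niche overlap ({app}, {epoch})")
        fig.tight_layout()
        p = outdir / f"overlap_{app}_{epoch}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
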