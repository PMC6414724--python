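"""Reduced-scale in-silico hypothesis experiments.

These are the study's four hypothesis checks run against synthetic ground
truth, at problem sizes a single CPU handles in minutes:

* H1 (transferability): with real environmental change between epochs, the
  split-sample crossvalidation AUC overstates transferability — it exceeds
  the internal-TT AUC; with a frozen environment the two are exchangeable.
* H2 (predictor integration): for species whose true niche uses climate,
  land cover and vegetation functioning together, the three-way combined
  ensemble matches or beats every individual ensemble.
* H4/inference recovery: the multimodel-inference machinery finds a planted
  predictor-set effect (high sum of Akaike weights) while ignoring an absent
  approach effect, and flags a planted trait effect at p < 0.001.

The survey design, prevalence filter and consensus thresholds stay at the
study constants; only grid size, species count and replicate count are
scaled down (see the methods note).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import child_rng
from .ensemble import ModelSpec, PREDICTOR_SETS
from .inference import dredge_all_subsets, trait_contrast_table
from .pipeline import (
    ExperimentConfig,
    derive_predictors,
    evaluate_species,
    fit_species,
    run_inference,
)
from .world import (
    ChangeScenario,
    SurveyDesign,
    WorldConfig,
    make_virtual_species,
    make_world,
    prevalence_filter,
    sample_detections,
    sample_survey_locations,
    true_suitability,
    validate_occurrences,
)

H1_H2_SETS = ("CLI", "LULC", "EFA", "CLI+LULC+EFA")


def small_config(zero_change: bool = False, n_species: int = 4) -> ExperimentConfig:
    """The reduced study conditions used by the hypothesis experiments."""
    change = ChangeScenario() if not zero_change else ChangeScenario(
        tmax_delta=0.0, tmin_delta=0.0, prec_delta=0.0,
        encroachment_rate=0.0, n_fires=0,
    )
    return ExperimentConfig(
        world=WorldConfig(fine_shape=(40, 40), change=change),
        survey=SurveyDesign(),
        model=ModelSpec(algorithms=("glm", "gbm"), n_replicates=8),
        n_species=n_species,
    )


def transfer_run(seed: int, zero_change: bool = False, n_species: int = 4
                 ) -> pd.DataFrame:
    """One seed of the H1/H2 experiment: individual + three-way combined
    ensembles, non-hierarchical, all three evaluation regimes."""
    cfg = small_config(zero_change=zero_change, n_species=n_species)
    world = make_world(cfg.world, seed)
    suite = derive_predictors(world)
    species = make_virtual_species(
        cfg.n_species, cfg.trait_design, cfg.beta_ranges, seed, families=cfg.families
    )
    locations = sample_survey_locations(world.fine_template, cfg.survey, seed)
    occ_frames = []
    for sp in species:
        s0 = true_suitability(sp, suite.fine_std["t0"])
        s1 = true_suitability(sp, suite.fine_std["t1"])
        occ_frames.append(sample_detections(locations, s0, s1, sp.species_id, seed))
    occ = pd.concat(occ_frames, ignore_index=True)
    validate_occurrences(occ)
    retained = prevalence_filter(occ, cfg.min_presences)
    by_id = {s.species_id: s for s in species}
    records = []
    for sid in retained:
        models = fit_species(
            by_id[sid], occ, suite, cfg.model, seed,
            predictor_sets=H1_H2_SETS, approaches=("non_hierarchical",),
        )
        for rec in evaluate_species(models, occ):
            d = rec.as_dict()
            d["seed"] = seed
            records.append(d)
    return pd.DataFrame(records)


def h1_gap(records: pd.DataFrame) -> tuple[float, float]:
    """(mean crossvalidation AUC, mean internal-TT AUC) over species and sets."""
    cv = records.loc[records.eval_type == "crossvalidation", "auc"].mean()
    itt = records.loc[records.eval_type == "internal_tt", "auc"].mean()
    return float(cv), float(itt)


def h2_combined_wins(records: pd.DataFrame) -> bool:
    """Does the three-way combined crossvalidation AUC (mean over species)
    reach or exceed every individual family's?"""
    cv = records[records.eval_type == "crossvalidation"]
    means = cv.groupby("predictor_set")["auc"].mean()
    combined = means["CLI+LULC+EFA"]
    return bool(all(combined >= means[f] - 1e-12 for f in ("CLI", "LULC", "EFA")))


# ---------------------------------------------------------------------------
# planted-effect inference recovery (no ENM fitting needed)

def synthetic_auc_records(
    seed: int,
    pred_effect: float = 0.08,
    app_effect: float = 0.0,
    trait_effect: float = 0.0,
    n_species: int = 12,
    noise_sd: float = 0.03,
    species_base_sd: float = 0.02,
) -> pd.DataFrame:
    """AUC tables with known factor effects, for inference-recovery checks.

    Combined predictor sets gain ``pred_effect`` (three-way the most), the
    hierarchical approach gains ``app_effect``, and Mediterranean-labelled
    species gain ``trait_effect`` — plus Gaussian noise.
    """
    rng = child_rng(seed, "planted-auc")
    pred_gain = {p: pred_effect * (p.count("+") / 2.0) for p in PREDICTOR_SETS}
    rows = []
    for i in range(n_species):
        origin = "Mediterranean" if i % 2 else "Eurosiberian"
        base = 0.75 + rng.normal(0, species_base_sd) if species_base_sd > 0 else 0.75
        for pset in PREDICTOR_SETS:
            for app in ("non_hierarchical", "hierarchical"):
                auc_val = (
                    base
                    + pred_gain[pset]
                    + (app_effect if app == "hierarchical" else 0.0)
                    + (trait_effect if origin == "Mediterranean" else 0.0)
                    + rng.normal(0, noise_sd)
                )
                rows.append(
                    {
                        "species_id": f"SP{i:02d}",
                        "predictor_set": pset,
                        "approach": app,
                        "eval_type": "crossvalidation",
                        "auc": float(np.clip(auc_val, 0.0, 1.0)),
                        "origin": origin,
                    }
                )
    return pd.DataFrame(rows)


def inference_recovery(seed: int) -> dict[str, float]:
    """Importances from a planted PRED-effect / no APP-effect AUC table."""
    records = synthetic_auc_records(seed, pred_effect=0.08, app_effect=0.0)
    design = pd.DataFrame(
        {
            "PRED": records["predictor_set"],
            "APP": records["approach"],
            "TRAIT": records["origin"],
        }
    )
    table = dredge_all_subsets(records["auc"].to_numpy(), design)
    return {"sum_w_pred": table.importance["PRED"], "sum_w_app": table.importance["APP"]}


def trait_recovery(seed: int, trait_effect: float = 0.2) -> float:
    """p-value of the origin contrast with a planted trait effect."""
    records = synthetic_auc_records(seed, trait_effect=trait_effect)
    table = trait_contrast_table(records, "origin")
    overall = table[(table.predictor_set == "all")]
    return float(overall["p"].iloc[0])
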