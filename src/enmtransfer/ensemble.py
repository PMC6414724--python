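"""AUC-weighted ensemble niche models.

The modelling core is exposed statsmodels-style: :class:`EnsembleENM` is the
model (occurrence data + a predictor stack of at most three layers + a
fitting specification), its :meth:`~EnsembleENM.fit` returns an
:class:`EnsembleENMResults` carrying the single-model members, their holdout
AUCs, the consensus weights and prediction methods.

The consensus rule: every (algorithm x split-sample replicate) member with
holdout AUC above the inclusion threshold enters a weighted average, with its
raw AUC as weight.  When no member clears the bar, the single best member is
kept so that an ensemble exists for every species (logged as a fallback).

"Combined" models re-run the same machinery with the suitability surfaces of
individual ensembles as predictors; "hierarchical" integration replaces the
local climate ensemble by the direct downscaling of a coarse-resolution
regional climate model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .evaluation import auc_from_labels
from .raster import ConfigurationError, RasterGrid

logger = logging.getLogger(__name__)

PREDICTOR_SETS = ("CLI", "LULC", "EFA", "CLI+LULC", "CLI+EFA", "LULC+EFA", "CLI+LULC+EFA")
APPROACHES = ("non_hierarchical", "hierarchical")

MAX_PREDICTORS = 3


class RegistryError(KeyError):
    pass


class StratificationError(ValueError):
    pass


class FoldSkip(Exception):
    """A replicate's training fold contains a single class; replicate dropped."""


# ---------------------------------------------------------------------------
# learner registry

def _make_glm(seed: int):
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(C=1.0, max_iter=2000)


def _make_rf(seed: int):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=60, min_samples_leaf=10, random_state=seed, n_jobs=1
    )


def _make_gbm(seed: int):
    from sklearn.ensemble import GradientBoostingClassifier

    return GradientBoostingClassifier(
        n_estimators=100, max_depth=2, learning_rate=0.1, min_samples_leaf=10,
        random_state=seed,
    )


def _make_gam(seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import SplineTransformer

    return make_pipeline(
        SplineTransformer(n_knots=5, degree=3), LogisticRegression(C=1.0, max_iter=2000)
    )


def _make_fda(seed: int):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    return LinearDiscriminantAnalysis()


def _make_ann(seed: int):
    from sklearn.neural_network import MLPClassifier

    return MLPClassifier(hidden_layer_sizes=(8,), max_iter=1000, random_state=seed)


LEARNER_REGISTRY = {
    "glm": _make_glm,
    "rf": _make_rf,
    "gbm": _make_gbm,
    "gam": _make_gam,
    "fda": _make_fda,
    "ann": _make_ann,
}

DEFAULT_ALGORITHMS = ("glm", "rf", "gbm")


def register_learner(name: str, factory) -> None:
    """Add a learner factory (``factory(seed) -> fitted-API estimator``)."""
    LEARNER_REGISTRY[name] = factory


@dataclass
class ModelSpec:
    """Fitting specification shared across species and predictor sets."""

    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    n_replicates: int = 30
    train_fraction: float = 0.7
    ensemble_auc_threshold: float = 0.65
    rescale_weights: bool = False  # optionally weight by (AUC - 0.5) instead of raw AUC

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        for a in self.algorithms:
            if a not in LEARNER_REGISTRY:
                raise RegistryError(f"unregistered algorithm {a!r}")


@dataclass
class SingleModelFit:
    algorithm: str
    replicate: int
    estimator: object
    holdout_auc: float
    train_idx: np.ndarray
    test_idx: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = getattr(self.estimator, "predict_proba", None)
        if proba is not None:
            return proba(X)[:, 1]
        raw = self.estimator.decision_function(X)
        return 1.0 / (1.0 + np.exp(-raw))


def split_sample(
    observed, n_replicates: int, train_fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test partitions of the record indices.

    Each replicate draws ``round(train_fraction * n)`` records per
    presence/absence class for training, the rest for evaluation, so class
    prevalence is preserved; replicates are independent and deterministic
    for a fixed seed.
    """
    y = np.asarray(observed).astype(int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 < 2 or n0 < 2:
        raise StratificationError(
            "stratified splitting needs at least 2 presences and 2 absences"
        )
    rng = child_rng(seed, "split-sample")
    pres = np.flatnonzero(y == 1)
    abs_ = np.flatnonzero(y == 0)
    k1 = min(max(int(round(train_fraction * n1)), 1), n1 - 1)
    k0 = min(max(int(round(train_fraction * n0)), 1), n0 - 1)
    parts = []
    for _ in range(n_replicates):
        p = rng.permutation(pres)
        a = rng.permutation(abs_)
        train = np.sort(np.concatenate([p[:k1], a[:k0]]))
        test = np.sort(np.concatenate([p[k1:], a[k0:]]))
        parts.append((train, test))
    return parts


def fit_single(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    algorithm: str,
    replicate: int,
    seed: int,
) -> SingleModelFit:
    """Fit one learner on a training fold and score it on the paired holdout."""
    if algorithm not in LEARNER_REGISTRY:
        raise RegistryError(f"unregistered algorithm {algorithm!r}")
    ytr = y[train_idx]
    if ytr.min() == ytr.max():
        raise FoldSkip(f"{algorithm} replicate {replicate}: single-class training fold")
    est_seed = int(child_rng(seed, "learner", algorithm, replicate).integers(2**31))
    est = LEARNER_REGISTRY[algorithm](est_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X[train_idx], ytr)
    fit = SingleModelFit(algorithm, replicate, est, np.nan, train_idx, test_idx)
    fit.holdout_auc = float(auc_from_labels(fit.predict(X[test_idx]), y[test_idx]))
    return fit


class EnsembleENM:
    """Ensemble niche model for one species on a <= 3-layer predictor stack.

    Parameters
    ----------
    occ : DataFrame
        Occurrence records with x, y, detected columns (a single species and
        protocol — normally the calibration campaign).
    stack : dict[str, RasterGrid]
        Standardized predictor layers, at most three, co-registered with the
        occurrence coordinates.
    spec : ModelSpec
    """

    def __init__(self, occ: pd.DataFrame, stack: dict[str, RasterGrid],
                 spec: ModelSpec | None = None):
        if not 1 <= len(stack) <= MAX_PREDICTORS:
            raise ConfigurationError(
                f"models are restricted to 1..{MAX_PREDICTORS} predictors, got {len(stack)}"
            )
        self.spec = spec or ModelSpec()
        self.predictor_names = tuple(stack.keys())
        self.stack = stack
        self.occ = occ.reset_index(drop=True)
        self.y = self.occ["detected"].to_numpy().astype(int)
        self.X = extract_points(stack, self.occ["x"].to_numpy(), self.occ["y"].to_numpy())

    def fit(self, seed: int = 0) -> "EnsembleENMResults":
        parts = split_sample(
            self.y, self.spec.n_replicates, self.spec.train_fraction, seed
        )
        members: list[SingleModelFit] = []
        skips: list[str] = []
        for rep, (train, test) in enumerate(parts):
            for alg in self.spec.algorithms:
                try:
                    members.append(fit_single(self.X, self.y, train, test, alg, rep, seed))
                except FoldSkip as exc:
                    skips.append(str(exc))
                    logger.warning("fold skipped: %s", exc)
        if not members:
            raise StratificationError("every replicate was skipped; cannot fit")
        return build_ensemble(
            members,
            threshold=self.spec.ensemble_auc_threshold,
            model=self,
            skips=skips,
        )


@dataclass
class EnsembleENMResults:
    """Fitted consensus: members, inclusion, weights, prediction."""

    model: EnsembleENM | None
    members: list[SingleModelFit]
    included: list[SingleModelFit]
    weights: np.ndarray
    threshold: float
    fallback: bool = False
    fold_skips: list[str] = field(default_factory=list)
    predictor_names: tuple[str, ...] = ()

    @property
    def mean_holdout_auc(self) -> float:
        """Mean holdout AUC of the included (consensus) members."""
        return float(np.mean([m.holdout_auc for m in self.included]))

    @property
    def split_sample_auc(self) -> float:
        """Split-sample evaluation of the whole model set: mean holdout AUC
        over all fitted members.  This is the crossvalidation accuracy the
        evaluation stage reports; averaging only the included members would
        condition on the same noisy AUC used for inclusion and bias the
        estimate upward."""
        return float(np.mean([m.holdout_auc for m in self.members]))

    def members_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "algorithm": [m.algorithm for m in self.members],
                "replicate": [m.replicate for m in self.members],
                "holdout_auc": [m.holdout_auc for m in self.members],
                "included": [m in self.included for m in self.members],
            }
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """AUC-weighted convex combination of member predictions."""
        preds = np.stack([m.predict(X) for m in self.included])
        w = self.weights / self.weights.sum()
        return w @ preds

    def predict_map(self, stack: dict[str, RasterGrid]) -> RasterGrid:
        """Suitability surface on a co-registered (standardized) stack."""
        for name in self.predictor_names:
            if name not in stack:
                raise KeyError(f"stack is missing predictor {name!r}")
        sub = {name: stack[name] for name in self.predictor_names}
        first = next(iter(sub.values()))
        mask = np.zeros(first.values.shape, dtype=bool)
        for g in sub.values():
            mask |= g.nodata_mask
        X = np.column_stack([g.values.ravel() for g in sub.values()])
        vals = np.zeros(X.shape[0])
        ok = ~mask.ravel()
        vals[ok] = self.predict(X[ok])
        return first.with_values(vals.reshape(first.values.shape), mask)

    def summary(self) -> str:
        lines = [
            "Ensemble niche model results",
            "=" * 34,
            f"Predictors:        {', '.join(self.predictor_names)}",
            f"Members fitted:    {len(self.members)}",
            f"Members included:  {len(self.included)} (AUC > {self.threshold})"
            + ("  [fallback: best member]" if self.fallback else ""),
            f"Fold skips:        {len(self.fold_skips)}",
            f"Mean holdout AUC:  {self.mean_holdout_auc:.3f}",
            "",
            "Per-algorithm holdout AUC (mean over replicates):",
        ]
        df = self.members_frame()
        for alg, grp in df.groupby("algorithm"):
            lines.append(
                f"  {alg:<6} {grp['holdout_auc'].mean():.3f} "
                f"(included {int(grp['included'].sum())}/{len(grp)})"
            )
        return "\n".join(lines)


def build_ensemble(
    members: list[SingleModelFit],
    threshold: float = 0.65,
    model: EnsembleENM | None = None,
    skips: list[str] | None = None,
) -> EnsembleENMResults:
    """Consensus over single models: include AUC > threshold, weight by AUC.

    If no member clears the threshold the single best member is used alone,
    with a logged warning — an ensemble must exist for every species so that
    downstream hypothesis tests see a complete design.
    """
    if not members:
        raise ConfigurationError("cannot build an ensemble from zero members")
    included = [m for m in members if m.holdout_auc > threshold]
    fallback = False
    if not included:
        best = max(members, key=lambda m: m.holdout_auc)
        included = [best]
        fallback = True
        logger.warning(
            "no member exceeded AUC %.2f; falling back to best member %s/%d (AUC %.3f)",
            threshold, best.algorithm, best.replicate, best.holdout_auc,
        )
    rescale = model.spec.rescale_weights if model is not None else False
    raw = np.array([m.holdout_auc for m in included], dtype=float)
    weights = np.clip(raw - 0.5, 1e-9, None) if rescale else raw
    names = model.predictor_names if model is not None else ()
    return EnsembleENMResults(
        model=model,
        members=members,
        included=included,
        weights=weights,
        threshold=threshold,
        fallback=fallback,
        fold_skips=list(skips or []),
        predictor_names=names,
    )


def extract_points(stack: dict[str, RasterGrid], x, y) -> np.ndarray:
    """Predictor matrix (n_points, n_layers) sampled at point coordinates."""
    return np.column_stack([g.sample(x, y) for g in stack.values()])


def build_combined(
    suitability_maps: dict[str, RasterGrid],
    occ: pd.DataFrame,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> EnsembleENMResults:
    """Combined model: refit the ensemble machinery on 2-3 suitability maps.

    The individual ensembles' predicted surfaces become the predictor stack,
    which integrates the driver families while keeping every component model
    within the three-variable complexity cap by construction.
    """
    if not 2 <= len(suitability_maps) <= MAX_PREDICTORS:
        raise ConfigurationError("combined models take 2 or 3 suitability maps")
    return EnsembleENM(occ, suitability_maps, spec).fit(seed)


def fit_regional_climate(
    coarse_occ: pd.DataFrame,
    coarse_bioclim: dict[str, RasterGrid],
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> EnsembleENMResults:
    """Standard ensemble fitted at the coarse regional resolution."""
    return EnsembleENM(coarse_occ, coarse_bioclim, spec).fit(seed)


def project_direct(
    regional_results: EnsembleENMResults, fine_stack: dict[str, RasterGrid]
) -> RasterGrid:
    """Direct downscaling: evaluate the regional response surface cell-wise
    on fine-resolution climate standardized with the regional training stats."""
    return regional_results.predict_map(fine_stack)
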