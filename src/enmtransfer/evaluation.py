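"""Discrimination metrics, evaluation regimes and niche overlap.

Models are scored within the calibration epoch (split-sample
"crossvalidation"), against a revisit of the calibration locations at the
later epoch ("internal TT": temporally but not spatially independent) and
against a spatially distinct later-epoch campaign ("external TT": temporally
and spatially independent).  AUC is the headline threshold-independent
metric; sensitivity, TSS and kappa are computed at the max-TSS threshold
frozen on calibration data, so transferability scores never re-tune the
binarization on evaluation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

EVAL_TYPES = ("crossvalidation", "internal_tt", "external_tt")


class InputError(ValueError):
    pass


class ContractError(ValueError):
    """eval_type and occurrence protocol do not match."""


@dataclass
class EvalRecord:
    """One accuracy measurement for a species x predictor set x approach cell."""

    species_id: str
    predictor_set: str
    approach: str
    eval_type: str
    auc: float
    sensitivity: float
    tss: float
    kappa: float
    threshold: float
    n_points: int = 0
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "species_id": self.species_id,
            "predictor_set": self.predictor_set,
            "approach": self.approach,
            "eval_type": self.eval_type,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "tss": self.tss,
            "kappa": self.kappa,
            "threshold": self.threshold,
            "n_points": self.n_points,
        }
        d.update(self.extras)
        return d


def auc(presence_scores, absence_scores) -> float:
    """Mann-Whitney AUC: P(presence score > absence score), ties count 1/2.

    Computed through midranks, which is exactly the pairwise fraction
    sum_{i,j}[s_i > s_j] + 0.5 [s_i == s_j] / (n1 n0).
    """
    pres = np.asarray(presence_scores, dtype=float)
    abs_ = np.asarray(absence_scores, dtype=float)
    if pres.size == 0 or abs_.size == 0:
        raise InputError("both score classes must be non-empty")
    ranks = rankdata(np.concatenate([pres, abs_]))
    r1 = ranks[: pres.size].sum()
    u = r1 - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * abs_.size))


def auc_from_labels(scores, observed) -> float:
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed).astype(int)
    return auc(scores[observed == 1], scores[observed == 0])


def confusion_metrics(scores, observed, threshold: float) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, TSS, kappa) at ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed).astype(int)
    if not 0 <= threshold <= 1:
        raise InputError("threshold must lie in [0, 1]")
    if observed.min() == observed.max():
        raise InputError("confusion metrics need both presences and absences")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (observed == 1)))
    fn = int(np.sum((pred == 0) & (observed == 1)))
    tn = int(np.sum((pred == 0) & (observed == 0)))
    fp = int(np.sum((pred == 1) & (observed == 0)))
    n = tp + fn + tn + fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    tss = sens + spec - 1.0
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return sens, spec, tss, kappa


def max_tss_threshold(scores, observed) -> float:
    """Smallest observed score maximizing TSS (candidate set = unique scores)."""
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed).astype(int)
    if observed.min() == observed.max():
        raise InputError("max-TSS threshold needs both classes")
    best_t, best_tss = None, -np.inf
    for t in np.unique(scores):
        tss = confusion_metrics(scores, observed, float(np.clip(t, 0, 1)))[2]
        if tss > best_tss + 1e-12:
            best_tss, best_t = tss, float(np.clip(t, 0, 1))
    return best_t


_PROTOCOL_FOR_EVAL = {"internal_tt": "internal_tt", "external_tt": "external_tt"}


def evaluate_scores(
    scores,
    observed,
    species_id: str,
    predictor_set: str,
    approach: str,
    eval_type: str,
    threshold: float | None = None,
) -> EvalRecord:
    """Build one EvalRecord from paired scores and observations.

    ``threshold`` is the frozen calibration-epoch max-TSS threshold for the
    transferability regimes; when None (crossvalidation) it is derived from
    the supplied data itself.
    """
    if eval_type not in EVAL_TYPES:
        raise ContractError(f"unknown eval_type {eval_type!r}")
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed).astype(int)
    if threshold is None:
        threshold = max_tss_threshold(scores, observed)
    sens, _, tss, kappa = confusion_metrics(scores, observed, threshold)
    return EvalRecord(
        species_id=species_id,
        predictor_set=predictor_set,
        approach=approach,
        eval_type=eval_type,
        auc=auc_from_labels(scores, observed),
        sensitivity=sens,
        tss=tss,
        kappa=kappa,
        threshold=threshold,
        n_points=int(observed.size),
    )


def evaluate_transfer(
    suitability_map,
    occ: pd.DataFrame,
    eval_type: str,
    species_id: str,
    predictor_set: str,
    approach: str,
    threshold: float,
) -> EvalRecord:
    """Score a t1 suitability map against a transferability campaign.

    The occurrence subset must carry the protocol matching ``eval_type`` and
    epoch t1; the binarization threshold is the calibration-epoch one.
    """
    if eval_type not in _PROTOCOL_FOR_EVAL:
        raise ContractError("evaluate_transfer handles internal_tt/external_tt only")
    sub = occ[(occ["species_id"] == species_id) & (occ["protocol"] == _PROTOCOL_FOR_EVAL[eval_type])]
    if len(sub) == 0 or (sub["epoch"] != "t1").any():
        raise ContractError(
            f"eval_type {eval_type!r} requires t1 occurrences of protocol "
            f"{_PROTOCOL_FOR_EVAL[eval_type]!r}"
        )
    scores = suitability_map.sample(sub["x"].to_numpy(), sub["y"].to_numpy())
    return evaluate_scores(
        scores, sub["detected"].to_numpy(), species_id, predictor_set, approach,
        eval_type, threshold=threshold,
    )


def schoener_d(map_a, map_b) -> float:
    """Schoener's D niche overlap between two suitability surfaces.

    Each map is normalized to sum 1 over the shared unmasked cells;
    D = 1 - 0.5 * sum |p_a - p_b|, so 1 means identical occupancy patterns
    and 0 disjoint ones.  Scale-invariant by construction.
    """
    shared = ~(map_a.nodata_mask | map_b.nodata_mask)
    a = map_a.values[shared].astype(float)
    b = map_b.values[shared].astype(float)
    if np.any(a < 0) or np.any(b < 0):
        raise InputError("Schoener's D requires non-negative suitabilities")
    if a.sum() <= 0 or b.sum() <= 0:
        raise InputError("cannot normalize an all-zero suitability map")
    pa = a / a.sum()
    pb = b / b.sum()
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def count_transferable(records: list[EvalRecord] | pd.DataFrame, auc_cut: float = 0.7) -> int:
    """Number of species with AUC strictly above the cut (one record each)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.as_dict() for r in records])
    if len(df) == 0:
        return 0
    if df["eval_type"].nunique() > 1:
        raise InputError("records must share a single eval_type")
    return int((df["auc"] > auc_cut).sum())


def records_to_frame(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])
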