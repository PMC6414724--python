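"""Multimodel inference on AUC variation and trait contrasts.

AUC values from the evaluation stage are explained with Gaussian-identity
GLMs over the categorical factors PRED (predictor set), APP (modelling
approach) and TRAIT (one species trait per run).  All main-effects subsets
(no interactions) are fitted; models are ranked by AIC, candidate support is
delta-AIC < 7, factor importance is the summed Akaike weight of the models
containing the factor (consequential when > 0.5).  Trait groups are compared
with a paired Wilcoxon signed-rank test at the conservative p < 0.001 rule.

The Gaussian likelihood uses the ML variance (RSS/n) so AIC is comparable
across fixed-effect structures, and k counts the residual-variance parameter.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu, norm

logger = logging.getLogger(__name__)

SUPPORT_DELTA = 7.0
IMPORTANCE_CUT = 0.5
SIGNIFICANCE_P = 0.001
_SIGMA2_FLOOR = 1e-12


class AliasingError(ValueError):
    """The design matrix is rank-deficient (collinear factor columns)."""


class DegenerateTestError(ValueError):
    pass


@dataclass
class GaussianGLMFit:
    factors: tuple[str, ...]
    coefficients: pd.Series
    loglik: float
    aic: float
    k: int
    n: int
    sigma2: float
    degenerate: bool = False

    @property
    def label(self) -> str:
        return " + ".join(self.factors) if self.factors else "(intercept)"


def _design_matrix(design: pd.DataFrame, factors: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(design))}, index=design.index)
    for f in factors:
        col = design[f]
        if col.dtype.kind in "ifu" and col.nunique() > 8:
            X[f] = col.astype(float)  # numeric covariate passthrough
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=f, drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def gaussian_glm(response, design: pd.DataFrame, factors: tuple[str, ...] | None = None
                 ) -> GaussianGLMFit:
    """OLS fit of AUC on treatment-coded factors, with the ML Gaussian loglik.

    loglik = -(n/2) (ln(2 pi sigma2) + 1), sigma2 = RSS/n;
    AIC = -2 loglik + 2 k with k = #coefficients + 1 (variance parameter).
    A perfect fit is floored at sigma2 = 1e-12 and flagged degenerate.
    """
    y = np.asarray(response, dtype=float)
    if factors is None:
        factors = tuple(design.columns)
    X = _design_matrix(design, tuple(factors))
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise AliasingError(
            f"rank-deficient design for factors {factors}: columns {list(X.columns)}"
        )
    res = sm.OLS(y, X).fit()
    n = len(y)
    sigma2 = float(res.ssr / n)
    degenerate = sigma2 < _SIGMA2_FLOOR
    if degenerate:
        sigma2 = _SIGMA2_FLOOR
        logger.warning("perfect fit for %s: variance floored", factors)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = X.shape[1] + 1
    return GaussianGLMFit(
        factors=tuple(factors),
        coefficients=res.params,
        loglik=float(loglik),
        aic=float(-2.0 * loglik + 2.0 * k),
        k=k,
        n=n,
        sigma2=sigma2,
        degenerate=degenerate,
    )


def akaike_weights(aics) -> tuple[np.ndarray, np.ndarray]:
    """(delta, weight) from a vector of AICs: delta_i = AIC_i - AIC_min,
    W_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


@dataclass
class InferenceTable:
    """Ranked all-subsets model set with Akaike weights and importances."""

    table: pd.DataFrame            # model, k, loglik, AIC, delta, weight
    importance: dict[str, float]   # factor -> sum of weights of models containing it
    factors: tuple[str, ...]
    fits: list[GaussianGLMFit] = field(default_factory=list)

    @property
    def support_set(self) -> pd.DataFrame:
        return self.table[self.table["delta"] < SUPPORT_DELTA]

    def consequential_factors(self) -> list[str]:
        return [f for f, w in self.importance.items() if w > IMPORTANCE_CUT]


def dredge_all_subsets(response, design: pd.DataFrame,
                       candidate_factors: tuple[str, ...] | None = None) -> InferenceTable:
    """Fit all 2^m main-effects models (including intercept-only) and rank them."""
    if candidate_factors is None:
        candidate_factors = tuple(design.columns)
    if len(candidate_factors) > 10:
        raise ValueError("all-subsets enumeration is capped at 10 factors")
    fits = []
    for r in range(len(candidate_factors) + 1):
        for comb in itertools.combinations(candidate_factors, r):
            fits.append(gaussian_glm(response, design, comb))
    aics = np.array([f.aic for f in fits])
    delta, w = akaike_weights(aics)
    order = np.argsort(aics, kind="stable")
    table = pd.DataFrame(
        {
            "model": [fits[i].label for i in order],
            "k": [fits[i].k for i in order],
            "loglik": [fits[i].loglik for i in order],
            "AIC": aics[order],
            "delta": delta[order],
            "weight": w[order],
        }
    )
    importance = {
        f: float(sum(w[i] for i, fit in enumerate(fits) if f in fit.factors))
        for f in candidate_factors
    }
    return InferenceTable(table=table, importance=importance,
                          factors=tuple(candidate_factors), fits=fits)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

def _exact_wplus_pvalue(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p over the 2^n equiprobable sign assignments.

    Midranks may be half-integers; doubling gives an integer convolution.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences are midranked.
    The p-value is exact (full sign-assignment distribution) for n <= 25 and
    a tie-corrected normal approximation with continuity correction above.
    Returns (W, p) with W = min(W+, W-).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    if d.size < 5:
        raise DegenerateTestError(
            f"only {d.size} nonzero differences; need at least 5"
        )
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    n = d.size
    if n <= 25:
        p = _exact_wplus_pvalue(w_plus, ranks)
    else:
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(np.sum(ranks**2) / 4.0)
        cc = 0.5 if w_plus != mean else 0.0
        z = (w_plus - mean - np.sign(w_plus - mean) * cc) / sd
        p = float(min(1.0, 2.0 * (1.0 - norm.cdf(abs(z)))))
    return min(w_plus, w_minus), p


def trait_contrast_table(
    eval_records: pd.DataFrame,
    trait_column: str,
    method: str = "paired",
) -> pd.DataFrame:
    """Compare AUC between the two levels of one species trait.

    For each evaluation type, species-level AUCs are averaged per trait group
    within every configuration (predictor_set x approach); the paired test
    treats configurations as the pairing unit.  Per (eval_type,
    predictor_set) group means are also reported.  ``method='unpaired'``
    switches to a Mann-Whitney rank-sum over species-level values.
    """
    levels = sorted(eval_records[trait_column].dropna().unique())
    if len(levels) < 2:
        warnings.warn(f"trait column {trait_column!r} has fewer than two levels; "
                      "empty contrast table", stacklevel=2)
        return pd.DataFrame(
            columns=["eval_type", "predictor_set", "trait", "level_a", "level_b",
                     "mean_a", "mean_b", "W", "p", "significant"]
        )
    la, lb = levels[:2]
    rows = []
    for eval_type, sub in eval_records.groupby("eval_type"):
        # overall contrast: configuration-level paired group means
        cfg = (
            sub.groupby(["predictor_set", "approach", trait_column])["auc"]
            .mean()
            .unstack(trait_column)
            .dropna()
        )
        try:
            if method == "paired":
                stat, p = wilcoxon_signed_rank(cfg[la].to_numpy(), cfg[lb].to_numpy())
            else:
                stat, p = mannwhitneyu(
                    sub.loc[sub[trait_column] == la, "auc"],
                    sub.loc[sub[trait_column] == lb, "auc"],
                )
                stat, p = float(stat), float(p)
        except DegenerateTestError:
            stat, p = np.nan, 1.0
        rows.append(
            {
                "eval_type": eval_type,
                "predictor_set": "all",
                "trait": trait_column,
                "level_a": la,
                "level_b": lb,
                "mean_a": sub.loc[sub[trait_column] == la, "auc"].mean(),
                "mean_b": sub.loc[sub[trait_column] == lb, "auc"].mean(),
                "W": stat,
                "p": p,
                "significant": bool(p < SIGNIFICANCE_P),
            }
        )
        for pred_set, psub in sub.groupby("predictor_set"):
            rows.append(
                {
                    "eval_type": eval_type,
                    "predictor_set": pred_set,
                    "trait": trait_column,
                    "level_a": la,
                    "level_b": lb,
                    "mean_a": psub.loc[psub[trait_column] == la, "auc"].mean(),
                    "mean_b": psub.loc[psub[trait_column] == lb, "auc"].mean(),
                    "W": np.nan,
                    "p": np.nan,
                    "significant": False,
                }
            )
    return pd.DataFrame(rows)
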