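"""Screening accuracy of relative-weight indices for excess body fat.

Excess fat is defined by sex-specific body-fat-percentage thresholds
(strictly above 35% for females, 25% for males).  Discrimination is measured
by the rank-based AUC (the probability a random high-fat subject's index
exceeds a random low-fat subject's, ties counted one half — identical to the
ROC area of a single-predictor logistic model, because the fitted
probability is monotone in the score).  Operating cutoffs maximize the
Youden index (sensitivity + specificity) with the classification rule
"index >= cutoff -> predicted high".  Accuracy is additionally reported
within relative-sitting-height (RSH) thirds cut at the 2.5% and 97.5%
per-sex quantiles, and old-vs-new formulas are compared by ordinal category
reclassification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

from .anthropometry import (CategoryScheme, classify, compute_index,
                            derive_measures, map_category_thresholds)

__all__ = [
    "BF_THRESHOLDS",
    "ScreeningResult",
    "ReclassificationResult",
    "label_excess_fat",
    "auc",
    "youden_optimal_cutoff",
    "stratify_rsh",
    "reclassification",
    "build_screening_table",
    "YoudenCutoffScreen",
]

#: Sex-specific body-fat-percentage rule for the "high fat" label (strict >).
BF_THRESHOLDS = {"F": 35.0, "M": 25.0}

RSH_STRATA = ("all", "rsh_lower", "rsh_middle", "rsh_upper")


@dataclass
class ScreeningResult:
    formula: str
    stratum: str
    n: int
    auc: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent


@dataclass
class ReclassificationResult:
    pct_changed: float
    pct_up: float
    pct_down: float
    n: int


def label_excess_fat(cohort: pd.DataFrame,
                     thresholds: dict[str, float] | None = None) -> np.ndarray:
    """Boolean high-fat labels from bf_pct with the sex-specific strict rule."""
    thresholds = thresholds or BF_THRESHOLDS
    bf = cohort["bf_pct"].to_numpy(dtype=float)
    if np.isnan(bf).any():
        n_missing = int(np.isnan(bf).sum())
        raise ValueError(f"{n_missing} records missing bf_pct; exclude them first")
    cut = cohort["sex"].map(thresholds).to_numpy(dtype=float)
    return bf > cut


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be present")


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score_high > score_low) with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    ranks = rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_optimal_cutoff(scores, labels) -> tuple[float, float, float]:
    """Cutoff maximizing sensitivity + specificity; rule: score >= cutoff -> high.

    Candidates are midpoints between consecutive distinct sorted scores plus
    -inf and +inf; ties in the Youden index break toward the smallest cutoff.
    Returns ``(cutoff, sensitivity_pct, specificity_pct)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    uniq = np.unique(s)
    mid = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], mid, [np.inf]))
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    n1, n0 = pos_sorted.size, neg_sorted.size
    # sens(c) = #(pos >= c)/n1 ; spec(c) = #(neg < c)/n0
    sens = (n1 - np.searchsorted(pos_sorted, candidates, side="left")) / n1
    spec = np.searchsorted(neg_sorted, candidates, side="left") / n0
    j = sens + spec
    # ties (including fp-jittered exact ties) break toward the smallest
    # cutoff; genuine Youden differences are multiples of 1/(n1*n0) >> 1e-12
    i = int(np.nonzero(j >= j.max() - 1e-12)[0][0])
    return float(candidates[i]), float(100 * sens[i]), float(100 * spec[i])


def sens_spec_at_cutoff(scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity (percent) under score >= cutoff -> high."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    pred = s >= cutoff
    sens = 100.0 * np.mean(pred[y])
    spec = 100.0 * np.mean(~pred[~y])
    return float(sens), float(spec)


def stratify_rsh(cohort: pd.DataFrame, q_lo: float = 0.025, q_hi: float = 0.975,
                 ) -> pd.Series:
    """Assign RSH thirds cut at the per-sex empirical quantiles.

    lower: rsh < q(q_lo); middle: q(q_lo) <= rsh < q(q_hi); upper:
    rsh >= q(q_hi).  Quantiles use linear interpolation on the evaluation
    cohort itself.
    """
    if "rsh" not in cohort.columns:
        cohort = derive_measures(cohort)
    import warnings
    if len(cohort) < 40:
        warnings.warn("fewer than 40 subjects: RSH strata are unreliable")
    out = pd.Series(index=cohort.index, dtype=object)
    for sex, sub in cohort.groupby("sex"):
        r = sub["rsh"].to_numpy(dtype=float)
        lo, hi = np.quantile(r, [q_lo, q_hi])
        if lo == hi:  # degenerate distribution: no usable extreme strata
            warnings.warn("RSH quantiles coincide; assigning everyone to the "
                          "middle stratum")
            stratum = np.full(r.shape, "rsh_middle", dtype=object)
        else:
            stratum = np.where(r < lo, "rsh_lower",
                               np.where(r < hi, "rsh_middle", "rsh_upper"))
        out.loc[sub.index] = stratum
    return out


def reclassification(old_categories, new_categories) -> ReclassificationResult:
    """Percent of subjects changing ordinal category, split by direction."""
    old = pd.Categorical(old_categories, ordered=True)
    new = pd.Categorical(new_categories, categories=old.categories, ordered=True)
    if set(pd.Categorical(new_categories).categories) - set(old.categories):
        raise ValueError("category label sets do not match")
    if len(old) != len(new):
        raise ValueError("category vectors must have equal length")
    n = len(old)
    up = int(np.sum(new.codes > old.codes))
    down = int(np.sum(new.codes < old.codes))
    return ReclassificationResult(
        pct_changed=100.0 * (up + down) / n,
        pct_up=100.0 * up / n,
        pct_down=100.0 * down / n,
        n=n,
    )


class YoudenCutoffScreen(BaseEstimator, ClassifierMixin):
    """Threshold screen on a scalar score, tuned by the Youden index.

    ``fit(scores, labels)`` learns the cutoff maximizing
    sensitivity + specificity on the training sample; ``predict`` applies
    score >= cutoff.

    Attributes
    ----------
    cutoff_ : float
    sensitivity_, specificity_ : float   (percent, on the training sample)
    auc_ : float
    """

    def fit(self, X, y):
        s = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=bool)
        self.cutoff_, self.sensitivity_, self.specificity_ = \
            youden_optimal_cutoff(s, y)
        self.auc_ = auc(s, y)
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise ValueError("YoudenCutoffScreen is not fitted")
        return np.asarray(X, dtype=float).reshape(-1) >= self.cutoff_


def build_screening_table(
    train: pd.DataFrame,
    test: pd.DataFrame,
    formulas: dict[str, float],
    old_scheme: CategoryScheme | None = None,
    bf_thresholds: dict[str, float] | None = None,
) -> tuple[list[ScreeningResult], ReclassificationResult | None]:
    """Evaluate index formulas as excess-fat screens on a held-out cohort.

    Cutoffs (Youden) are learned on ``train`` and frozen; AUC, sensitivity
    and specificity are measured on ``test``, overall and within RSH thirds.
    When exactly two formulas are given, the second is also mapped onto the
    first's category scheme by training-set quantile matching and the
    test-set reclassification fractions are reported.

    ``train`` and ``test`` must be single-sex (the rules are sex-specific).
    """
    from .anthropometry import DEFAULT_SCHEME
    old_scheme = old_scheme or DEFAULT_SCHEME
    for part, name in ((train, "train"), (test, "test")):
        if part["sex"].nunique() > 1:
            raise ValueError(f"{name} cohort must be single-sex")
    train = derive_measures(train)
    test = derive_measures(test)
    y_train = label_excess_fat(train, bf_thresholds)
    y_test = label_excess_fat(test, bf_thresholds)
    strata = stratify_rsh(test)

    results: list[ScreeningResult] = []
    screens: dict[str, YoudenCutoffScreen] = {}
    for fname, power in formulas.items():
        s_train = compute_index(train["weight_kg"], train["height_m"], power)
        s_test = compute_index(test["weight_kg"], test["height_m"], power)
        screen = YoudenCutoffScreen().fit(s_train, y_train)
        screens[fname] = screen
        for stratum in RSH_STRATA:
            mask = np.ones(len(test), dtype=bool) if stratum == "all" \
                else (strata == stratum).to_numpy()
            if mask.sum() == 0 or y_test[mask].all() or not y_test[mask].any():
                results.append(ScreeningResult(fname, stratum, int(mask.sum()),
                                               np.nan, screen.cutoff_,
                                               np.nan, np.nan))
                continue
            sens, spec = sens_spec_at_cutoff(s_test[mask], y_test[mask],
                                             screen.cutoff_)
            results.append(ScreeningResult(
                formula=fname, stratum=stratum, n=int(mask.sum()),
                auc=auc(s_test[mask], y_test[mask]), cutoff=screen.cutoff_,
                sensitivity=sens, specificity=spec))

    reclass = None
    if len(formulas) == 2:
        (old_name, old_p), (new_name, new_p) = formulas.items()
        old_train = compute_index(train["weight_kg"], train["height_m"], old_p)
        new_train = compute_index(train["weight_kg"], train["height_m"], new_p)
        new_scheme = map_category_thresholds(old_train, new_train, old_scheme)
        old_cat = classify(compute_index(test["weight_kg"], test["height_m"],
                                         old_p), old_scheme)
        new_cat = classify(compute_index(test["weight_kg"], test["height_m"],
                                         new_p), new_scheme)
        reclass = reclassification(old_cat, new_cat)
    return results, reclass


def screening_table_to_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
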