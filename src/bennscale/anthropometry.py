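"""Derived anthropometric indices and categorical classification.

The central object is the relative-weight index

    index(p) = weight (kg) / height (m)^p,

with the conventional formula at p = 2.  Also computes body-fat percentage,
waist:hip ratio (WHR), waist:height ratio (WHtR) and relative sitting height
(RSH), and maps ordinal weight categories between index formulas by quantile
matching on a training sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "IndexFormula",
    "CategoryScheme",
    "OLD_BMI",
    "DEFAULT_SCHEME",
    "compute_index",
    "derive_measures",
    "classify",
    "map_category_thresholds",
    "QuantileCategoryMapper",
]


@dataclass(frozen=True)
class IndexFormula:
    """A relative-weight index weight/height^power, height in metres."""

    name: str
    power: float

    def __post_init__(self):
        if not np.isfinite(self.power):
            raise ValueError("power must be finite")


#: Conventional body mass index, weight/height^2.
OLD_BMI = IndexFormula("BMI_old", 2.0)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered weight categories defined by ascending index thresholds.

    ``labels`` has one more entry than ``thresholds``; binning is half-open
    and left-closed: category k covers thresholds[k-1] <= x < thresholds[k],
    with the lowest bin unbounded below and the highest unbounded above.
    """

    labels: tuple[str, ...] = ("underweight", "normal", "overweight", "obese")
    thresholds: tuple[float, ...] = (18.5, 25.0, 30.0)

    def __post_init__(self):
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need exactly one more label than threshold")
        t = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")


DEFAULT_SCHEME = CategoryScheme()


def compute_index(weight, height, formula: IndexFormula | float, ids=None) -> np.ndarray:
    """Evaluate weight/height^p elementwise; weight in kg, height in metres.

    Non-positive weights or heights are rejected; when ``ids`` is supplied the
    offending record ids are named in the error message.
    """
    p = formula.power if isinstance(formula, IndexFormula) else float(formula)
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    bad = ~((w > 0) & (h > 0))
    if np.any(bad):
        if ids is not None:
            names = np.asarray(ids)[np.atleast_1d(bad)][:20]
            raise ValueError(f"non-positive weight or height for ids: {list(names)}")
        raise ValueError("weight and height must be positive")
    with np.errstate(over="ignore"):
        out = w / h**p
    if not np.all(np.isfinite(out)):
        # extreme |p|: evaluate in log space
        out = np.exp(np.log(w) - p * np.log(h))
    return out


def derive_measures(cohort: pd.DataFrame) -> pd.DataFrame:
    """Augment a cohort with bf_pct, whr, whtr and rsh columns.

    bf_pct = 100*FM/weight; whr = WC/hip; whtr = WC/height (both in cm,
    i.e. WC in cm over height in cm); rsh = sitting height / standing height.
    """
    need = ["weight_kg", "fat_mass_kg", "wc_cm", "hip_cm", "height_m",
            "sitting_height_m"]
    for col in need:
        if col not in cohort.columns:
            raise ValueError(f"missing required column {col!r}")
        vals = cohort[col].to_numpy(dtype=float)
        if np.any(~(vals > 0)) and col != "fat_mass_kg":
            bad = cohort.loc[~(cohort[col] > 0), "id"].head(20).tolist()
            raise ValueError(f"non-positive {col} for ids: {bad}")
    out = cohort.copy()
    out["bf_pct"] = 100.0 * out["fat_mass_kg"] / out["weight_kg"]
    out["whr"] = out["wc_cm"] / out["hip_cm"]
    out["whtr"] = out["wc_cm"] / (out["height_m"] * 100.0)
    out["rsh"] = out["sitting_height_m"] / out["height_m"]
    out.attrs = dict(cohort.attrs)
    return out


def classify(values, scheme: CategoryScheme = DEFAULT_SCHEME) -> pd.Categorical:
    """Bin index values into ordered categories (left-closed bins).

    A value exactly equal to a threshold goes to the category above it.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("index values must be finite")
    codes = np.searchsorted(np.asarray(scheme.thresholds), x, side="right")
    return pd.Categorical.from_codes(codes, categories=list(scheme.labels),
                                     ordered=True)


def map_category_thresholds(train_old_index, train_new_index,
                            old_scheme: CategoryScheme = DEFAULT_SCHEME,
                            ) -> CategoryScheme:
    """Derive thresholds for a new index formula by quantile matching.

    Each new threshold is the empirical quantile (linear interpolation) of
    the new index at the cumulative fraction of training subjects falling
    below the corresponding old threshold, so marginal category frequencies
    on the training sample are preserved to within 1/n.
    """
    old = np.asarray(train_old_index, dtype=float)
    new = np.asarray(train_new_index, dtype=float)
    if old.shape != new.shape:
        raise ValueError("old and new index vectors must cover the same subjects")
    fracs = [np.mean(old < t) for t in old_scheme.thresholds]
    thresholds = tuple(float(np.quantile(new, f)) for f in fracs)
    if not np.all(np.diff(thresholds) > 0):
        raise ValueError("degenerate index distribution: mapped thresholds "
                         "are not strictly increasing")
    return CategoryScheme(labels=old_scheme.labels, thresholds=thresholds)


class QuantileCategoryMapper(BaseEstimator, TransformerMixin):
    """Transfer an ordinal category scheme to a new index by quantile matching.

    Parameters
    ----------
    old_scheme : CategoryScheme
        The scheme defined on the reference (old) index scale.

    Attributes
    ----------
    scheme_ : CategoryScheme
        Thresholds on the new index scale, fitted on training data.
    """

    def __init__(self, old_scheme: CategoryScheme = DEFAULT_SCHEME):
        self.old_scheme = old_scheme

    def fit(self, X, y):
        """Fit from new-index values ``X`` and old-index values ``y``."""
        self.scheme_ = map_category_thresholds(y, X, self.old_scheme)
        return self

    def transform(self, X) -> pd.Categorical:
        return classify(X, self.scheme_)
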