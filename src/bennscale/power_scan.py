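"""Exponent grid search with age-adjusted partial correlations.

For each power p on a uniform grid, the index weight/height^p is correlated
with height and with body-fatness measures after both variables are linearly
adjusted for age (partial Pearson correlation of residuals).  Two selection
criteria operate on the resulting curves:

* height independency — the power at which the correlation with height is
  zero (located as the grid point of minimum |r|, with a sign-change check);
* fatness dependency — the power maximizing the (signed) correlation with a
  body-fatness measure.

Index values are formed in log space, ``exp(log w - p log h)`` with per-power
centering, so powers up to |p| = 50 never overflow; the multiplicative
rescaling is invisible to correlations.

Confidence intervals use the Fisher z transform:
``tanh(atanh(r) +/- 1.96 / sqrt(n - g - 3))`` with g control variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .anthropometry import compute_index, derive_measures

__all__ = [
    "PowerGrid",
    "CorrelationCurve",
    "CriterionOptimum",
    "partial_corr",
    "scan_powers",
    "find_height_independent_power",
    "find_max_corr_power",
    "build_criterion_table",
    "BennExponentSelector",
    "MEASURE_COLUMNS",
    "FATNESS_MEASURES",
    "curves_to_frame",
    "criterion_table_to_frame",
    "allometric_exponent_loglog",
]

#: Measure name -> cohort column.
MEASURE_COLUMNS: dict[str, str] = {
    "height": "height_m",
    "bf_pct": "bf_pct",
    "weight": "weight_kg",
    "fat_mass": "fat_mass_kg",
    "fat_free_mass": "fat_free_mass_kg",
    "wc": "wc_cm",
    "whr": "whr",
    "whtr": "whtr",
}

FATNESS_MEASURES = ("bf_pct", "weight", "fat_mass", "fat_free_mass",
                    "wc", "whr", "whtr")

_Z95 = 1.96  # two-sided 95% normal quantile, fixed


@dataclass(frozen=True)
class PowerGrid:
    """Uniform, endpoint-inclusive grid of height exponents.

    Powers are represented as exact integer hundredths to avoid floating
    accumulation drift, so the step must be a positive multiple of 0.01.
    """

    p_min: float = -50.0
    p_max: float = 50.0
    step: float = 0.01

    def __post_init__(self):
        if not self.step > 0:
            raise ValueError("step must be > 0")
        for v in (self.p_min, self.p_max, self.step):
            if abs(round(v * 100) - v * 100) > 1e-6:
                raise ValueError("grid bounds and step must be multiples of 0.01")
        if self.p_min >= self.p_max:
            raise ValueError("p_min must be < p_max")

    @property
    def powers(self) -> np.ndarray:
        k_min = round(self.p_min * 100)
        k_max = round(self.p_max * 100)
        k_step = round(self.step * 100)
        return np.arange(k_min, k_max + 1, k_step, dtype=np.int64) / 100.0


@dataclass
class CorrelationCurve:
    """Age-adjusted partial correlation of index(p) with one measure."""

    measure: str
    powers: np.ndarray
    r: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: int


@dataclass
class CriterionOptimum:
    """One criterion row: the selected power and correlations there."""

    criterion: str
    power: float
    r_at_optimum: float
    correlations: dict[str, float] = field(default_factory=dict)
    sign_change_bracketed: bool | None = None
    warning: str | None = None


def _control_matrix(control) -> np.ndarray:
    c = np.asarray(control, dtype=float)
    return c[:, None] if c.ndim == 1 else c


def _residualizer(control):
    """Orthonormal basis Q of [1, control]; residual(x) = x - Q (Q^T x)."""
    C = _control_matrix(control)
    n = C.shape[0]
    X = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(X)
    return Q


def fisher_ci(r: np.ndarray, n: int, g: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """95% Fisher-z interval with n - g - 3 effective degrees of freedom."""
    df = n - g - 3
    if df <= 0:
        raise ValueError("need n > g + 3 for Fisher confidence intervals")
    half = _Z95 / np.sqrt(df)
    with np.errstate(divide="ignore"):  # |r| = 1 -> z = inf, tanh(inf) = 1
        z = np.arctanh(np.clip(r, -1.0, 1.0))
    return np.tanh(z - half), np.tanh(z + half)


def partial_corr(x, y, control) -> tuple[float, float, float]:
    """Partial Pearson correlation of x and y given linear control variables.

    Computed as the plain correlation of the residuals of x and y after
    least-squares regression on an intercept plus the control columns.
    Returns ``(r, ci_lo, ci_hi)`` with a 95% Fisher-z interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = _control_matrix(control)
    n = x.shape[0]
    if y.shape[0] != n or C.shape[0] != n:
        raise ValueError("x, y and control must have equal length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(C))):
        raise ValueError("inputs must be finite")
    if np.allclose(C.std(axis=0), 0.0):
        raise ValueError("control variable has zero variance")
    Q = _residualizer(C)
    rx = x - Q @ (Q.T @ x)
    ry = y - Q @ (Q.T @ y)
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    scale_x = np.linalg.norm(x - x.mean())
    scale_y = np.linalg.norm(y - y.mean())
    if sx <= 1e-10 * scale_x or sy <= 1e-10 * scale_y or sx == 0 or sy == 0:
        raise ValueError("undefined correlation: zero residual variance")
    r = float((rx @ ry) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    lo, hi = fisher_ci(np.array(r), n, g=C.shape[1])
    return r, float(lo), float(hi)


def scan_powers(cohort: pd.DataFrame, measures=None,
                grid: PowerGrid | None = None, control: str = "age",
                ) -> dict[str, CorrelationCurve]:
    """Compute age-adjusted partial-correlation curves over the power grid.

    ``cohort`` must be single-sex with derived measures present (see
    :func:`bennscale.anthropometry.derive_measures`; they are derived on the
    fly when absent).  Correlations are computed exactly at every grid point.
    """
    grid = grid or PowerGrid()
    if measures is None:
        measures = list(MEASURE_COLUMNS)
    if cohort["sex"].nunique() > 1:
        raise ValueError("scan_powers expects a single-sex cohort")
    if any(MEASURE_COLUMNS[m] not in cohort.columns for m in measures):
        cohort = derive_measures(cohort)

    n = len(cohort)
    w = cohort["weight_kg"].to_numpy(dtype=float)
    h = cohort["height_m"].to_numpy(dtype=float)
    if np.any(~(w > 0)) or np.any(~(h > 0)):
        raise ValueError("weight and height must be positive")
    log_w, log_h = np.log(w), np.log(h)
    Q = _residualizer(cohort[control].to_numpy(dtype=float))

    M = np.column_stack([cohort[MEASURE_COLUMNS[m]].to_numpy(dtype=float)
                         for m in measures])
    M = M - Q @ (Q.T @ M)
    M_norm = M / np.linalg.norm(M, axis=0)

    powers = grid.powers
    n_powers = powers.shape[0]
    R = np.empty((n_powers, len(measures)))
    block = max(1, int(20_000_000 // max(n, 1)))
    for start in range(0, n_powers, block):
        P = powers[start:start + block]
        S = log_w[:, None] - np.outer(log_h, P)
        S -= S.mean(axis=0, keepdims=True)  # rescaling; invisible to correlations
        I = np.exp(S)
        if not np.all(np.isfinite(I)):
            raise FloatingPointError(
                f"non-finite index values in power block starting at {P[0]}")
        norm_pre = np.linalg.norm(I, axis=0)
        I -= Q @ (Q.T @ I)
        norm_res = np.linalg.norm(I, axis=0)
        # a residual-constant index (exact allometry at p = p_true) has zero
        # covariance with everything: the correlation limit is 0
        degenerate = norm_res <= 1e-10 * norm_pre
        norm_res[degenerate] = 1.0
        I /= norm_res
        block_r = I.T @ M_norm
        block_r[degenerate] = 0.0
        if degenerate.any():
            warnings.warn("index has zero residual variance at power(s) "
                          f"{P[degenerate]}; correlations set to 0 there")
        R[start:start + block] = block_r
    np.clip(R, -1.0, 1.0, out=R)

    curves = {}
    for j, m in enumerate(measures):
        lo, hi = fisher_ci(R[:, j], n, g=1)
        curves[m] = CorrelationCurve(measure=m, powers=powers, r=R[:, j],
                                     ci_lo=lo, ci_hi=hi, n=n)
    return curves


def find_height_independent_power(curve: CorrelationCurve) -> CriterionOptimum:
    """Select the power where the correlation with height crosses zero.

    The optimum is the grid point minimizing |r|; ties break toward the
    smaller power.  A warning is attached when no sign change brackets the
    optimum anywhere on the grid.
    """
    if curve.measure != "height":
        raise ValueError("expected the height correlation curve")
    i = int(np.argmin(np.abs(curve.r)))
    signs = np.sign(curve.r)
    nonzero = signs[signs != 0]
    bracketed = bool(np.any(np.diff(nonzero) != 0) or np.any(signs == 0))
    warning = None if bracketed else (
        "no sign change on the grid; returning the minimum-|r| point")
    if warning:
        warnings.warn(warning)
    return CriterionOptimum(criterion="height", power=float(curve.powers[i]),
                            r_at_optimum=float(curve.r[i]),
                            sign_change_bracketed=bracketed, warning=warning)


def find_max_corr_power(curve: CorrelationCurve) -> CriterionOptimum:
    """Select the power maximizing the signed correlation with a measure.

    Ties break toward the smaller power; a plateau wider than 10 grid points
    at the maximum attaches a warning.
    """
    i = int(np.argmax(curve.r))
    plateau = int(np.sum(curve.r >= curve.r[i] - 1e-12))
    warning = None
    if plateau > 10:
        warning = f"plateau of {plateau} grid points at the maximum"
        warnings.warn(warning)
    return CriterionOptimum(criterion=curve.measure,
                            power=float(curve.powers[i]),
                            r_at_optimum=float(curve.r[i]), warning=warning)


def _correlations_at(cohort: pd.DataFrame, power: float, measures,
                     control: str = "age") -> dict[str, float]:
    idx = compute_index(cohort["weight_kg"], cohort["height_m"], power)
    ctrl = cohort[control].to_numpy(dtype=float)
    out = {}
    for m in measures:
        r, _, _ = partial_corr(idx, cohort[MEASURE_COLUMNS[m]].to_numpy(dtype=float),
                               ctrl)
        out[m] = r
    return out


def build_criterion_table(cohort: pd.DataFrame, grid: PowerGrid | None = None,
                          control: str = "age") -> list[CriterionOptimum]:
    """Build the criterion-optima report for one sex.

    Rows: the conventional formula (p = 2.00), the height-independency
    criterion, and one fatness-dependency row per measure; each row carries
    the age-adjusted correlations with all eight measures at that row's
    power.
    """
    grid = grid or PowerGrid()
    cohort = derive_measures(cohort)
    curves = scan_powers(cohort, list(MEASURE_COLUMNS), grid, control)
    rows: list[CriterionOptimum] = []
    rows.append(CriterionOptimum(criterion="old_formula", power=2.0,
                                 r_at_optimum=np.nan))
    rows.append(find_height_independent_power(curves["height"]))
    for m in FATNESS_MEASURES:
        rows.append(find_max_corr_power(curves[m]))
    for row in rows:
        row.correlations = _correlations_at(cohort, row.power,
                                            list(MEASURE_COLUMNS), control)
        if row.criterion == "old_formula":
            row.r_at_optimum = row.correlations["height"]
    return rows


def curves_to_frame(curves: dict[str, CorrelationCurve]) -> pd.DataFrame:
    """Long-format export: power, measure, r, ci_lo, ci_hi."""
    parts = []
    for m, c in curves.items():
        parts.append(pd.DataFrame({"power": c.powers, "measure": m, "r": c.r,
                                   "ci_lo": c.ci_lo, "ci_hi": c.ci_hi}))
    return pd.concat(parts, ignore_index=True)


def criterion_table_to_frame(rows: list[CriterionOptimum]) -> pd.DataFrame:
    recs = []
    for row in rows:
        rec = {"criterion": row.criterion, "power": row.power}
        rec.update({f"r_{m}": v for m, v in row.correlations.items()})
        recs.append(rec)
    return pd.DataFrame(recs)


def allometric_exponent_loglog(cohort: pd.DataFrame, control: str = "age") -> float:
    """Cross-check utility: log-log regression slope of weight on height.

    Fits log(weight) ~ 1 + log(height) + control by least squares and returns
    the height coefficient.  Not used by the selection pipeline (which is
    correlation-criterion based); provided for comparison only.
    """
    X = np.column_stack([
        np.ones(len(cohort)),
        np.log(cohort["height_m"].to_numpy(dtype=float)),
        _control_matrix(cohort[control].to_numpy(dtype=float)),
    ])
    y = np.log(cohort["weight_kg"].to_numpy(dtype=float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1])


class BennExponentSelector(BaseEstimator, TransformerMixin):
    """Select a height exponent for weight/height^p by a correlation criterion.

    Fit on a single-sex cohort table; ``transform`` then evaluates the
    selected index on any cohort.  The default criterion is height
    independency (age-adjusted partial correlation with height equal to
    zero); any fatness measure name selects the maximal-correlation
    criterion for that measure instead.

    Parameters
    ----------
    criterion : str, default "height"
        "height" or one of the fatness measures
        (bf_pct, weight, fat_mass, fat_free_mass, wc, whr, whtr).
    grid : PowerGrid, optional
        Exponent grid; defaults to -50..50 in steps of 0.01.
    control : str, default "age"
        Cohort column linearly adjusted for in the partial correlations.

    Attributes
    ----------
    power_ : float
        The selected exponent (a grid point, two decimals).
    optimum_ : CriterionOptimum
        Full selection record including the correlation at the optimum.
    curve_ : CorrelationCurve
        The criterion measure's correlation curve.
    n_ : int
        Number of training subjects.
    """

    def __init__(self, criterion: str = "height", grid: PowerGrid | None = None,
                 control: str = "age"):
        self.criterion = criterion
        self.grid = grid
        self.control = control

    def fit(self, X: pd.DataFrame, y=None):
        if self.criterion not in MEASURE_COLUMNS:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        grid = self.grid or PowerGrid()
        X = derive_measures(X)
        curves = scan_powers(X, [self.criterion], grid, self.control)
        curve = curves[self.criterion]
        if self.criterion == "height":
            self.optimum_ = find_height_independent_power(curve)
        else:
            self.optimum_ = find_max_corr_power(curve)
        self.curve_ = curve
        self.power_ = self.optimum_.power
        self.n_ = curve.n
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Evaluate the selected index weight/height^power_ on a cohort."""
        if not hasattr(self, "power_"):
            raise ValueError("BennExponentSelector is not fitted")
        return compute_index(X["weight_kg"], X["height_m"], self.power_,
                             ids=X.get("id"))

    def formula_(self, name: str | None = None):
        from .anthropometry import IndexFormula
        return IndexFormula(name or f"BMI_p{self.power_:.2f}", self.power_)
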