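"""Cox proportional-hazards comparison of relative-weight index formulas.

Index values are categorized into fifths (quintile groups, lowest fifth as
reference) and entered as indicator covariates in a Cox model adjusted for
age, deprivation score and categorical covariates.  The partial likelihood
with the Efron tie correction is maximized by Newton iteration with
step-halving; the implementation is self-contained so that analytic
score/information can be verified against finite differences and against an
independent survival fitter in tests.  Model fit is compared via the Akaike
information criterion, AIC = -2 log PL + 2k (lower is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .anthropometry import compute_index
from .cohort import CATEGORICAL_LEVELS

__all__ = [
    "SurvivalFit",
    "assign_fifths",
    "cox_loglik",
    "CoxProportionalHazards",
    "build_design",
    "fit_cox",
    "compare_formulas_survival",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "townsend", "education", "smoking", "alcohol",
                      "ethnicity")


@dataclass
class SurvivalFit:
    """Cox fit summary for one index formula."""

    formula: str
    coef: dict[str, float]
    se: dict[str, float]
    hr_by_fifth: dict[int, tuple[float, float, float]]  # fifth -> (HR, lo, hi)
    log_partial_likelihood: float
    aic: float
    n: int
    events: int
    n_iter: int = 0
    dropped_columns: list[str] = field(default_factory=list)


def assign_fifths(values) -> np.ndarray:
    """Quintile group (1-5) per value; cutpoints at the 20/40/60/80 empirical
    percentiles (linear interpolation); values equal to a cutpoint fall in
    the lower fifth."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values for fifths")
    cuts = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    fifths = np.searchsorted(cuts, x, side="left") + 1
    counts = np.bincount(fifths, minlength=6)[1:]
    if (counts == 0).any():
        empty = [i + 1 for i, c in enumerate(counts) if c == 0]
        raise ValueError(f"ties leave fifth(s) {empty} empty; "
                         "cannot form quintile groups")
    return fifths


def _efron_quantities(time, event, X, beta):
    """Log partial likelihood, score and information under Efron ties.

    Processes unique times in decreasing order, accumulating risk-set sums
    incrementally (O(n p^2) total).
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")[::-1]  # decreasing time
    t_s, e_s, X_s = time[order], event[order], X[order]
    eta = X_s @ beta
    eta -= eta.max()  # multiplicative normalization of the risk scores
    w = np.exp(eta)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        t = t_s[i]
        while j < n and t_s[j] == t:
            k = j
            S0 += w[k]
            wx = w[k] * X_s[k]
            S1 += wx
            S2 += np.outer(wx, X_s[k])
            j += 1
        deaths = np.nonzero(e_s[i:j] == 1)[0] + i
        d = deaths.size
        if d > 0:
            Xd = X_s[deaths]
            wd = w[deaths]
            sd0 = wd.sum()
            sd1 = wd @ Xd
            sd2 = (wd[:, None] * Xd).T @ Xd
            loglik += eta[deaths].sum()
            grad += Xd.sum(axis=0)
            for l in range(d):
                c = l / d
                D0 = S0 - c * sd0
                D1 = S1 - c * sd1
                D2 = S2 - c * sd2
                loglik -= np.log(D0)
                v = D1 / D0
                grad -= v
                info += D2 / D0 - np.outer(v, v)
        i = j
    return loglik, grad, info


def cox_loglik(time, event, X, beta, ties: str = "efron") -> float:
    """Efron- or Breslow-tie-corrected Cox log partial likelihood."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if ties == "efron":
        ll, _, _ = _efron_quantities(time, event, X, beta)
        return float(ll)
    if ties == "breslow":
        ll, _, _ = _breslow_quantities(time, event, X, beta)
        return float(ll)
    raise ValueError(f"unknown tie method {ties!r}")


def _breslow_quantities(time, event, X, beta):
    """Same contract as _efron_quantities with the Breslow approximation
    (full tied-death denominator for every death)."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")[::-1]
    t_s, e_s, X_s = time[order], event[order], X[order]
    eta = X_s @ beta
    eta -= eta.max()
    w = np.exp(eta)
    loglik, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        t = t_s[i]
        while j < n and t_s[j] == t:
            S0 += w[j]
            wx = w[j] * X_s[j]
            S1 += wx
            S2 += np.outer(wx, X_s[j])
            j += 1
        deaths = np.nonzero(e_s[i:j] == 1)[0] + i
        d = deaths.size
        if d > 0:
            loglik += eta[deaths].sum() - d * np.log(S0)
            v = S1 / S0
            grad += X_s[deaths].sum(axis=0) - d * v
            info += d * (S2 / S0 - np.outer(v, v))
        i = j
    return loglik, grad, info


class CoxProportionalHazards(BaseEstimator):
    """Cox proportional-hazards regression (Efron ties, Newton iteration).

    ``fit(X, y)`` takes a design matrix (DataFrame or array, no intercept)
    and ``y`` as a two-column structure ``(follow_time, event)``.  Newton
    steps with step-halving run until the sup-norm of the score drops below
    ``tol``.

    Attributes
    ----------
    coef_, se_ : ndarray
    loglik_ : float          log partial likelihood at the optimum
    aic_ : float             -2 loglik + 2 * n_params
    n_iter_ : int
    names_ : list of str     design column names
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-8,
                 max_iter: int = 50, max_abs_coef: float = 20.0):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter
        self.max_abs_coef = max_abs_coef

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.names_ = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            self.names_ = [f"x{i}" for i in range(Xv.shape[1])]
        y = np.asarray(y, dtype=float)
        time, event = y[:, 0], y[:, 1].astype(int)
        if np.any(time <= 0):
            raise ValueError("follow-up times must be positive")
        if not set(np.unique(event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        const = Xv.std(axis=0) == 0
        if const.any():
            bad = [self.names_[i] for i in np.nonzero(const)[0]]
            raise ValueError(f"constant design columns: {bad}")
        n, p = Xv.shape
        n_events = int(event.sum())
        if n_events < 10 * p:
            warnings.warn(f"only {n_events} events for {p} coefficients; "
                          "estimates may be unstable")
        quantities = _efron_quantities if self.ties == "efron" \
            else _breslow_quantities

        beta = np.zeros(p)
        ll, grad, info = quantities(time, event, Xv, beta)
        for it in range(1, self.max_iter + 1):
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
            new_beta, new = beta, None
            # accept any step that does not decrease the likelihood beyond
            # its own floating-point noise floor (relative to |ll|)
            ll_slack = 1e-10 * (abs(ll) + 1.0)
            for _ in range(30):  # step-halving
                cand = beta + step
                ll_c, g_c, i_c = quantities(time, event, Xv, cand)
                if np.isfinite(ll_c) and ll_c >= ll - ll_slack:
                    new_beta, new = cand, (ll_c, g_c, i_c)
                    break
                step = step / 2.0
            if new is None:
                raise RuntimeError("Cox fit failed: step-halving exhausted "
                                   f"at iteration {it} (loglik {ll:.6g})")
            beta = new_beta
            ll, grad, info = new
            if np.abs(beta).max() > self.max_abs_coef:
                raise RuntimeError("Cox fit failed: coefficient magnitude "
                                   "exceeds bound (possible separation)")
            if np.abs(grad).max() < self.tol:
                break
        else:
            raise RuntimeError(
                f"Cox fit did not converge in {self.max_iter} iterations "
                f"(|grad|_inf = {np.abs(grad).max():.3g})")
        self.coef_ = beta
        cov = np.linalg.inv(info)
        self.se_ = np.sqrt(np.diag(cov))
        self.loglik_ = float(ll)
        self.aic_ = -2.0 * float(ll) + 2.0 * p
        self.n_iter_ = it
        self.n_ = n
        self.events_ = n_events
        return self

    def hazard_ratios(self) -> pd.DataFrame:
        """HR = exp(coef) with Wald 95% CI exp(coef +/- 1.96 SE)."""
        hr = np.exp(self.coef_)
        lo = np.exp(self.coef_ - 1.96 * self.se_)
        hi = np.exp(self.coef_ + 1.96 * self.se_)
        return pd.DataFrame({"coef": self.coef_, "se": self.se_, "hr": hr,
                             "ci_lo": lo, "ci_hi": hi}, index=self.names_)


def build_design(cohort: pd.DataFrame, fifths: np.ndarray | None = None,
                 covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Expand covariates into a Cox design matrix.

    Numeric covariates (age, townsend) enter untransformed.  Categorical
    covariates expand into indicators against the first declared level as
    reference; "unknown" is an ordinary level.  Indicator columns for levels
    absent from the data are dropped (recorded via the returned frame's
    ``attrs['dropped']``).  ``fifths`` adds indicators for fifths 2-5
    (fifth 1 is the reference).
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            vals = cohort[cov].astype(str)
            unknown = set(vals.unique()) - set(levels)
            if unknown:
                raise ValueError(f"unexpected {cov} levels: {sorted(unknown)}")
            for level in levels[1:]:
                cols[f"{cov}[{level}]"] = (vals == level).to_numpy(dtype=float)
        else:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    if fifths is not None:
        fifths = np.asarray(fifths)
        for k in (2, 3, 4, 5):
            cols[f"fifth[{k}]"] = (fifths == k).astype(float)
    X = pd.DataFrame(cols, index=cohort.index)
    dropped = [c for c in X.columns if X[c].std() == 0 and X[c].sum() == 0]
    X = X.drop(columns=dropped)
    X.attrs["dropped"] = dropped
    return X


def _drop_separated_indicators(X: pd.DataFrame, event: np.ndarray
                               ) -> pd.DataFrame:
    """Merge zero-event (or all-event) indicator levels into the reference.

    An indicator level observed with no deaths (or only deaths) has an
    unbounded partial-likelihood coefficient; merging it into the reference
    level is the standard remedy.  Dropped columns are recorded in
    ``attrs['dropped']``.
    """
    dropped = list(X.attrs.get("dropped", []))
    keep = []
    for col in X.columns:
        v = X[col].to_numpy()
        is_indicator = np.isin(v, (0.0, 1.0)).all()
        if is_indicator and 0 < v.sum() < v.size:
            in_ev = event[v == 1]
            out_ev = event[v == 0]
            # all deaths inside or outside the level -> unbounded coefficient
            if in_ev.sum() == 0 or in_ev.sum() == in_ev.size \
                    or out_ev.sum() == 0:
                dropped.append(col)
                continue
        keep.append(col)
    # family-level separation: if the reference group of an indicator family
    # (all family columns zero) has no events, every family coefficient is
    # jointly unbounded; drop the whole family.
    families: dict[str, list[str]] = {}
    for col in keep:
        if "[" in col:
            families.setdefault(col.split("[", 1)[0], []).append(col)
    for fam, cols in families.items():
        member = X[cols].to_numpy().sum(axis=1) > 0
        if (~member).any() and event[~member].sum() == 0:
            dropped.extend(cols)
            keep = [c for c in keep if c not in cols]
    out = X[keep]
    out.attrs["dropped"] = dropped
    if len(dropped) > len(X.attrs.get("dropped", [])):
        warnings.warn(f"merged separated indicator levels into reference: "
                      f"{dropped}")
    return out


def fit_cox(cohort: pd.DataFrame, index_values, formula_name: str = "index",
            covariates=DEFAULT_COVARIATES) -> SurvivalFit:
    """Fit the adjusted Cox model with index fifths for one formula."""
    fifths = assign_fifths(index_values)
    X = build_design(cohort, fifths=fifths, covariates=covariates)
    event = cohort["event"].to_numpy(dtype=float)
    X = _drop_separated_indicators(X, event)
    y = np.column_stack([cohort["follow_time_y"].to_numpy(dtype=float),
                         event])
    model = CoxProportionalHazards().fit(X, y)
    hr = model.hazard_ratios()
    hr_by_fifth = {1: (1.0, 1.0, 1.0)}
    for k in (2, 3, 4, 5):
        name = f"fifth[{k}]"
        if name in hr.index:
            row = hr.loc[name]
            hr_by_fifth[k] = (float(row["hr"]), float(row["ci_lo"]),
                              float(row["ci_hi"]))
        else:  # merged into the reference for lack of events
            hr_by_fifth[k] = (np.nan, np.nan, np.nan)
    return SurvivalFit(
        formula=formula_name,
        coef=dict(zip(model.names_, map(float, model.coef_))),
        se=dict(zip(model.names_, map(float, model.se_))),
        hr_by_fifth=hr_by_fifth,
        log_partial_likelihood=model.loglik_,
        aic=model.aic_,
        n=model.n_,
        events=model.events_,
        n_iter=model.n_iter_,
        dropped_columns=X.attrs.get("dropped", []),
    )


def compare_formulas_survival(cohort: pd.DataFrame, formulas: dict[str, float],
                              covariates=DEFAULT_COVARIATES,
                              ) -> tuple[list[SurvivalFit], float]:
    """Fit the Cox model per formula on the same subjects; ΔAIC = last - first."""
    fits = []
    for name, power in formulas.items():
        idx = compute_index(cohort["weight_kg"], cohort["height_m"], power)
        fits.append(fit_cox(cohort, idx, formula_name=name,
                            covariates=covariates))
    delta_aic = fits[-1].aic - fits[0].aic
    return fits, delta_aic
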