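"""Cohort-level statistics for network-averaged imaging measures.

Covers the association analyses run on the imaging cohort:

* parcel-to-network aggregation (weighted means);
* linear age/sex/puberty models with AIC candidate selection,
  standardized coefficients and Wald 95% CIs (significance at the
  study's alpha = 0.005);
* model-predicted percent change of a measure across the age range;
* scan-rescan repeatability as the two-way consistency ICC(3,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "aggregate_roi",
    "CohortLinearModel",
    "CohortModelResults",
    "fit_linear_models",
    "percent_change_over_age",
    "compute_icc",
    "IccResult",
    "ALPHA",
]

#: significance threshold used throughout the cohort analyses.
ALPHA = 0.005

#: candidate mean structures, in increasing complexity. sex:pdss is the
#: puberty-by-sex interaction.
CANDIDATES = (
    ("age",),
    ("age", "sex"),
    ("age", "sex", "pdss"),
    ("age", "sex", "pdss", "sex:pdss"),
)


def aggregate_roi(parcel_values, labels, weights=None) -> pd.Series:
    """Weighted mean of parcel values within each network.

    Parameters
    ----------
    parcel_values
        Series (or dict) of a measure per parcel.
    labels
        Mapping parcel -> network label; every parcel must be labelled.
    weights
        Optional parcel sizes; unweighted mean when absent.
    """
    values = pd.Series(parcel_values, dtype=float)
    labels = pd.Series(labels)
    missing = values.index.difference(labels.index)
    if len(missing):
        raise KeyError(f"unlabelled parcels: {list(missing)[:5]}")
    w = (
        pd.Series(1.0, index=values.index)
        if weights is None
        else pd.Series(weights, dtype=float).reindex(values.index)
    )
    df = pd.DataFrame(
        {"value": values, "network": labels.reindex(values.index), "w": w}
    )
    grouped = df.groupby("network", sort=True)
    return grouped.apply(
        lambda g: np.average(g["value"], weights=g["w"]), include_groups=False
    ).rename("mean")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable cannot be standardized")
    return (x - x.mean()) / sd


def _design(df: pd.DataFrame, terms) -> np.ndarray | None:
    """Standardized design for one candidate; None if collinear.

    Continuous variables are z-scored, sex is coded +-0.5, and the
    sex-by-puberty interaction is the product of the coded columns.
    """
    cols = [np.ones(len(df))]
    built: dict[str, np.ndarray] = {}
    for term in terms:
        if term == "sex":
            sex = df["sex"]
            levels = sorted(sex.astype(str).unique())
            if len(levels) == 1:
                return None
            built[term] = np.where(sex.astype(str) == levels[0], -0.5, 0.5)
        elif term == "sex:pdss":
            built[term] = built["sex"] * built["pdss"]
        else:
            built[term] = _zscore(df[term].to_numpy(float))
        cols.append(built[term])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    return X


@dataclass
class CohortModelResults:
    """AIC-selected linear model for one outcome.

    ``params`` holds standardized coefficients with Wald 95% CIs and
    p-values; ``aic_table`` the AIC of every (estimable) candidate.
    ``raw_results`` is the same mean structure refitted on the
    unstandardized scale, used for prediction.
    """

    outcome: str
    selected_terms: tuple[str, ...]
    params: pd.DataFrame
    r2_adj: float
    aic_table: pd.Series
    raw_results: sm.regression.linear_model.RegressionResultsWrapper
    data: pd.DataFrame

    @property
    def significant(self) -> pd.Series:
        return self.params["p"] < ALPHA

    def summary(self) -> str:
        lines = [
            f"outcome: {self.outcome}",
            f"selected (lowest AIC): {' + '.join(self.selected_terms)}",
            f"adj. R^2 = {self.r2_adj:.3f}",
            "",
            "standardized coefficients (95% CI):",
            self.params.round(4).to_string(),
            "",
            "candidate AICs:",
            self.aic_table.round(2).to_string(),
        ]
        return "\n".join(lines)


class CohortLinearModel:
    """Age/sex/puberty linear modelling of one cohort measure.

    ``fit`` evaluates the candidate lattice {age; age+sex; age+sex+PDSS;
    age+sex+PDSS+sex:PDSS} by OLS on z-standardized variables (sex coded
    +-0.5), picks the lowest-AIC candidate and reports standardized
    betas with Wald 95% CIs. Collinear candidates are skipped with a
    warning.
    """

    def __init__(self, data: pd.DataFrame, outcome: str):
        required = {outcome, "age"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        data = data.dropna(subset=[c for c in (outcome, "age", "sex", "pdss") if c in data])
        if len(data) < 20:
            raise ValueError(f"need n >= 20 complete rows, got {len(data)}")
        self.data = data.reset_index(drop=True)
        self.outcome = outcome

    def fit(self) -> CohortModelResults:
        y = _zscore(self.data[self.outcome].to_numpy(float))
        aics, fits = {}, {}
        for terms in CANDIDATES:
            if any(t.split(":")[0] not in self.data.columns.union(["sex:pdss"]) and t != "sex:pdss"
                   for t in terms):
                continue
            if ("pdss" in [t for t in terms if ":" not in t] or "sex:pdss" in terms) and "pdss" not in self.data:
                continue
            if "sex" in terms and "sex" not in self.data:
                continue
            X = _design(self.data, terms)
            if X is None:
                warnings.warn(f"candidate {terms} collinear; skipped")
                continue
            res = sm.OLS(y, X).fit()
            key = " + ".join(terms)
            aics[key] = res.aic
            fits[key] = (terms, res)
        if not fits:
            raise ValueError("no estimable candidate model")
        best = min(aics, key=aics.get)
        terms, res = fits[best]
        ci = res.conf_int(alpha=0.05)
        names = ["intercept", *terms]
        params = pd.DataFrame(
            {
                "beta": res.params,
                "ci_lo": ci[:, 0],
                "ci_hi": ci[:, 1],
                "p": res.pvalues,
            },
            index=names,
        )
        raw = self._refit_raw(terms)
        return CohortModelResults(
            outcome=self.outcome,
            selected_terms=terms,
            params=params,
            r2_adj=float(res.rsquared_adj),
            aic_table=pd.Series(aics).sort_values(),
            raw_results=raw,
            data=self.data,
        )

    def _refit_raw(self, terms):
        """Same mean structure on original scales, for prediction."""
        df = self.data.copy()
        sex_levels = sorted(df["sex"].astype(str).unique()) if "sex" in df else []
        cols = {"const": np.ones(len(df))}
        for t in terms:
            if t == "sex":
                cols["sex"] = np.where(df["sex"].astype(str) == sex_levels[0], -0.5, 0.5)
            elif t == "sex:pdss":
                cols["sex:pdss"] = cols["sex"] * df["pdss"].to_numpy(float)
            else:
                cols[t] = df[t].to_numpy(float)
        X = pd.DataFrame(cols)
        return sm.OLS(df[self.outcome].to_numpy(float), X).fit()


def fit_linear_models(data: pd.DataFrame, outcome: str) -> CohortModelResults:
    """Functional wrapper over :class:`CohortLinearModel`."""
    return CohortLinearModel(data, outcome).fit()


def percent_change_over_age(
    results: CohortModelResults, age_lo: float, age_hi: float
) -> float:
    """Model-predicted percent change between two ages.

    100 * (yhat(age_hi) - yhat(age_lo)) / yhat(age_lo), with sex at the
    +-0.5 midpoint (0) and puberty at its sample mean. Undefined
    (raises) when the younger-age prediction is not positive.
    """
    if "age" not in results.selected_terms:
        raise ValueError("selected model has no age term")
    raw = results.raw_results
    cols = raw.model.exog_names
    ref = {"const": 1.0, "sex": 0.0}
    if "pdss" in cols:
        ref["pdss"] = float(results.data["pdss"].mean())
    ref["sex:pdss"] = 0.0
    rows = []
    for age in (age_lo, age_hi):
        ref["age"] = age
        rows.append([ref[c] for c in cols])
    y_lo, y_hi = raw.predict(np.asarray(rows))
    if y_lo <= 0:
        raise ValueError(f"prediction at age {age_lo} is non-positive ({y_lo:.3g})")
    return float(100.0 * (y_hi - y_lo) / y_lo)


@dataclass(frozen=True)
class IccResult:
    """Two-way consistency ICC(3,1) with its F-test and components."""

    icc: float
    p: float
    between_ms: float
    within_ms: float
    n_subjects: int
    n_sessions: int

    def __post_init__(self) -> None:
        assert -1.0 <= self.icc <= 1.0 + 1e-12


def compute_icc(
    data: pd.DataFrame,
    subject: str = "subject",
    session: str = "session",
    value: str = "value",
) -> IccResult:
    """Scan-rescan ICC(3,1): (BMS - EMS) / (BMS + (k-1) EMS).

    Two-way mixed model, consistency form, computed from the ANOVA mean
    squares of a complete subject x session table; the p-value is the F
    test of the between-subject effect (BMS/EMS). Subjects with fewer
    sessions than the mode are dropped with a warning.
    """
    counts = data.groupby(subject)[value].count()
    k = int(counts.mode().iloc[0])
    keep = counts[counts == k].index
    dropped = counts.index.difference(keep)
    if len(dropped):
        warnings.warn(f"excluding subjects with != {k} sessions: {list(dropped)}")
        data = data[data[subject].isin(keep)]
    n = data[subject].nunique()
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects with >= 2 sessions each")
    wide = data.pivot_table(index=subject, columns=session, values=value)
    x = wide.to_numpy(float)
    grand = x.mean()
    subj_means = x.mean(axis=1)
    sess_means = x.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_sess = n * np.sum((sess_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_sess
    # identical sessions leave only floating-point residue in the error SS;
    # clamp so the degenerate case yields ICC = 1 exactly
    if ss_err < 1e-10 * max(ss_tot, 1e-300):
        ss_err = 0.0
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms + (k - 1) * ems == 0:
        icc = 0.0
    else:
        icc = (bms - ems) / (bms + (k - 1) * ems)
    if ems == 0:
        p = 0.0 if bms > 0 else 1.0
    else:
        f = bms / ems
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return IccResult(float(icc), p, float(bms), float(ems), n, k)
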