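"""Non-spatial cohort statistics: contingency tests, rank tests, correlation,
binary logistic risk modelling with Nagelkerke R-squared, and the cohort
summary tables.

Dialect notes: the chi-squared statistic is the plain Pearson X^2 *without*
Yates continuity correction; Kruskal-Wallis uses the tie-corrected H; all
tests are two-sided at alpha = 0.05 unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "ContingencyTable",
    "LogisticFit",
    "HemorrhageRiskModel",
    "chi_squared",
    "kruskal_wallis",
    "pearson_r",
    "logistic_fit",
    "cohort_summary",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("contingency table is empty")


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    Returns (X^2, degrees of freedom, p). Expected counts come from the
    row/column margins; a zero margin is rejected.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = ContingencyTable(counts).counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: a row or column margin is zero")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test across >= 2 samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # all observations identical: H = 0 by convention
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs two equal-length samples of >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class LogisticFit:
    """Maximum-likelihood binary logistic regression fit."""

    coefficients: dict[str, float]
    intercept: float
    p_values: dict[str, float]
    std_errors: dict[str, float]
    log_likelihood: float
    null_log_likelihood: float
    model_chi2: float
    model_p: float
    nagelkerke_r2: float
    n: int
    converged: bool


def nagelkerke_r2(ll: float, ll0: float, n: int) -> float:
    """Rescaled Cox-Snell pseudo R^2, bounded in [0, 1]."""
    cs = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    return float(cs / denom) if denom > 0 else 0.0


def logistic_fit(outcome, predictors: dict | pd.DataFrame) -> LogisticFit:
    """Fit logit(P(outcome=1)) = b0 + sum_k beta_k x_k by maximum likelihood.

    Newton-type iteratively reweighted least squares via statsmodels; Wald
    p per coefficient; Nagelkerke R^2 from the fitted and null likelihoods.
    Complete separation is reported as a non-converged fit rather than an
    exception.
    """
    y = np.asarray(outcome, dtype=float).reshape(-1)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    Xdf = pd.DataFrame(predictors)
    if len(Xdf) != len(y):
        raise ValueError("outcome and predictors disagree in length")
    names = list(Xdf.columns)
    X = sm.add_constant(Xdf.to_numpy(dtype=float), has_constant="add")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=100, tol=1e-10)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = sm.Logit(y, X).fit(
                disp=False, method="bfgs", maxiter=200
            )
            converged = False
    if np.abs(res.params).max() > 50:
        converged = False
        warnings.warn(
            "diverging coefficients: possible complete separation", stacklevel=2
        )

    ll = float(res.llf)
    ll0 = float(res.llnull)
    chi2 = 2.0 * (ll - ll0)
    return LogisticFit(
        coefficients={k: float(v) for k, v in zip(names, res.params[1:])},
        intercept=float(res.params[0]),
        p_values={k: float(v) for k, v in zip(names, res.pvalues[1:])},
        std_errors={k: float(v) for k, v in zip(names, res.bse[1:])},
        log_likelihood=ll,
        null_log_likelihood=ll0,
        model_chi2=chi2,
        model_p=float(sps.chi2.sf(chi2, len(names))),
        nagelkerke_r2=nagelkerke_r2(ll, ll0, len(y)),
        n=len(y),
        converged=converged,
    )


class HemorrhageRiskModel(BaseEstimator):
    """Binary logistic hemorrhage-risk model as a sklearn-style classifier.

    Wraps the maximum-likelihood logistic fit used for the multivariable
    analysis of hemorrhage predictors (age, deep target location, histology),
    exposing sklearn conventions: ``fit(X, y)``, ``predict_proba``, fitted
    attributes with trailing underscores.
    """

    def __init__(self, feature_names: list[str] | None = None) -> None:
        self.feature_names = feature_names

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim == 1:
                Xv = Xv[:, None]
            names = self.feature_names or [f"x{i}" for i in range(Xv.shape[1])]
        fit = logistic_fit(y, pd.DataFrame(Xv, columns=names))
        self.fit_ = fit
        self.feature_names_ = names
        self.coef_ = np.array([fit.coefficients[k] for k in names])
        self.intercept_ = fit.intercept
        self.nagelkerke_r2_ = fit.nagelkerke_r2
        self.model_chi2_ = fit.model_chi2
        self.converged_ = fit.converged
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        return self.intercept_ + Xv @ self.coef_

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _mean_sd(x) -> str:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return "n/a"
    return f"{x.mean():.1f}±{x.std(ddof=1):.1f}" if x.size > 1 else f"{x.mean():.1f}"


def _row_chi2(flag_a: np.ndarray, flag_b: np.ndarray):
    """2x2 chi-squared of two boolean vectors; None when degenerate."""
    tab = np.array(
        [
            [int((flag_a & flag_b).sum()), int((flag_a & ~flag_b).sum())],
            [int((~flag_a & flag_b).sum()), int((~flag_a & ~flag_b).sum())],
        ]
    )
    try:
        x2, _, p = chi_squared(tab)
        return x2, p
    except ValueError:
        return None


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Patient-characteristics and hemorrhage-characteristics tables.

    Returns a dict with ``patients`` (hemorrhage vs no-hemorrhage comparison
    with per-row X^2 / Kruskal-Wallis statistics), ``hemorrhage``
    (volume/symptom/location breakdown of the bleeds), ``diagnostic_yield``
    and ``notes``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort
    bbh = df["bbh"].astype(bool).to_numpy()
    notes: list[str] = []
    both_strata = bool(bbh.any() and (~bbh).any())
    if not both_strata:
        notes.append("only one hemorrhage stratum present: comparisons skipped")

    rows = []

    def add(row_name, total, in_bbh, in_no, stat=None, kind=""):
        entry = {
            "row": row_name, "total": total, "bbh": in_bbh, "no_bbh": in_no,
            "statistic": np.nan, "p": np.nan, "test": kind,
        }
        if stat is not None:
            entry["statistic"], entry["p"] = stat
        rows.append(entry)

    n = len(df)
    n1, n0 = int(bbh.sum()), int((~bbh).sum())
    add("n", n, n1, n0)

    if "system" in df:
        robot = (df["system"] == "robot").to_numpy()
        stat = _row_chi2(robot, bbh) if both_strata else None
        add("system robot", int(robot.sum()), int(robot[bbh].sum()),
            int(robot[~bbh].sum()), stat, "chi2")
    if "age" in df:
        stat = None
        if both_strata:
            stat = kruskal_wallis([df.loc[bbh, "age"], df.loc[~bbh, "age"]])
        add("age", _mean_sd(df["age"]), _mean_sd(df.loc[bbh, "age"]),
            _mean_sd(df.loc[~bbh, "age"]), stat, "kruskal")
    if "sex" in df:
        female = (df["sex"] == "f").to_numpy()
        stat = _row_chi2(female, bbh) if both_strata else None
        add("sex f", int(female.sum()), int(female[bbh].sum()),
            int(female[~bbh].sum()), stat, "chi2")
    if "trajectory_length_mm" in df:
        stat = None
        if both_strata:
            stat = kruskal_wallis(
                [df.loc[bbh, "trajectory_length_mm"], df.loc[~bbh, "trajectory_length_mm"]]
            )
        add("trajectory length (mm)", _mean_sd(df["trajectory_length_mm"]),
            _mean_sd(df.loc[bbh, "trajectory_length_mm"]),
            _mean_sd(df.loc[~bbh, "trajectory_length_mm"]), stat, "kruskal")

    for column, prefix in (("target_region", "target"), ("histology", "histology")):
        if column not in df:
            continue
        for cat in sorted(df[column].astype(str).unique()):
            flag = (df[column].astype(str) == cat).to_numpy()
            stat = _row_chi2(flag, bbh) if both_strata else None
            add(f"{prefix} {cat}", int(flag.sum()), int(flag[bbh].sum()),
                int(flag[~bbh].sum()), stat, "chi2")

    patients = pd.DataFrame(rows)

    sub = df[bbh]
    hem_rows = []
    if n1 > 0:
        vols = sub["bbh_volume_ml"].to_numpy(dtype=float)
        hem_rows.append({"feature": "volume (ml)",
                         "value": f"{vols.mean():.1f}±{vols.std(ddof=1) if n1 > 1 else 0:.1f} "
                                  f"[{vols.min():.1f}-{vols.max():.1f}]",
                         "count": n1, "pct_of_cohort": round(100 * n1 / n, 1)})
    symptomatic = sub["symptomatic"].astype(bool).to_numpy() if n1 else np.zeros(0, bool)

    def hem_count(name, k):
        hem_rows.append({"feature": name, "value": int(k), "count": int(k),
                         "pct_of_cohort": round(100 * k / n, 1)})

    hem_count("asymptomatic hemorrhage", n1 - int(symptomatic.sum()) if n1 else 0)
    hem_count("symptomatic hemorrhage", int(symptomatic.sum()) if n1 else 0)
    for col, name in (
        ("sensorimotor_deficit", "sensorimotor deficits"),
        ("aphasia", "aphasia"),
        ("reduced_vigilance", "reduced vigilance"),
        ("revision", "revision surgery"),
        ("persistent_deficit", "persistent deficits"),
    ):
        hem_count(name, int(sub[col].astype(bool).sum()) if (n1 and col in sub) else 0)
    for loc in ("intralesional", "extralesional", "both"):
        k = int((sub["bbh_location"] == loc).sum()) if (n1 and "bbh_location" in sub) else 0
        hem_count(f"location {loc}", k)
    hemorrhage = pd.DataFrame(hem_rows)

    if "histology" in df:
        conclusive = (df["histology"].astype(str) != "inconclusive").to_numpy()
        dy = float(conclusive.mean())
    else:
        dy = float("nan")

    return {
        "patients": patients,
        "hemorrhage": hemorrhage,
        "diagnostic_yield": dy,
        "notes": notes,
    }
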