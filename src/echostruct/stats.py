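"""Statistical evaluation: group comparisons, standardized regressions,
tertile trend tests, Kruskal-Wallis, correlations and reader-reproducibility ICC.

Conventions: all p values are two-sided; the Student t-test pools variances;
the chi-square test applies no continuity correction; regression predictors
are standardized to mean 0, SD 1 (sample SD, n-1) so coefficients are per
1-SD of the predictor; no multiple-testing adjustment is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_ALPHA = 0.05


def _nearest_rank(values: np.ndarray, q: float) -> float:
    """Nearest-rank order statistic (float-valued twin of the intensity
    percentile used for the SIC)."""
    n = values.size
    # epsilon guards ceil against float error when q*n/100 is an exact integer
    rank = min(max(math.ceil(q * n / 100.0 - 1e-9), 1), n)
    return float(np.partition(values, rank - 1)[rank - 1])


@dataclass(frozen=True)
class StatTestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    df: float | None = None
    estimate: float | None = None
    se: float | None = None
    groups: tuple | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    coefficient: float  # per 1-SD of the raw predictor
    se: float
    p_value: float
    n: int
    outcome: str = ""
    predictor: str = ""
    covariates: tuple = ()
    model: str = "ols"


# ---------------------------------------------------------------------------
# elementary tests


def two_sample_t(x, y) -> StatTestResult:
    """Pooled-variance Student t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    return StatTestResult(
        test_name="two_sample_t",
        statistic=float(t),
        p_value=float(p),
        n=n1 + n2,
        df=float(df),
        estimate=float(x.mean() - y.mean()),
    )


def chi_square_test(table) -> StatTestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("contingency table must be a 2-D array of non-negative counts")
    total = table.sum()
    if total <= 0:
        raise ValueError("empty contingency table")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatTestResult(
        test_name="chi_square",
        statistic=float(stat),
        p_value=float(p),
        n=int(total),
        df=float(dof),
    )


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# regression


def standardize(x) -> np.ndarray:
    """Center and scale to unit sample SD (n-1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero predictor variance")
    return (x - x.mean()) / sd


def ols_standardized(
    outcome,
    predictor,
    covariates=None,
    logistic: bool = False,
    names: tuple = ("outcome", "predictor"),
) -> RegressionResult:
    """Regress ``outcome`` on the standardized predictor (plus covariates).

    Binary outcomes are fitted as a linear probability model by default;
    pass ``logistic=True`` for maximum-likelihood logistic regression.
    """
    y = np.asarray(outcome, dtype=float)
    z = standardize(predictor)
    cols = [np.ones_like(z), z]
    cov_names: tuple = ()
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == y.size and cov.ndim == 2:
            cov = cov.T
        for j in range(cov.shape[0]):
            cols.append(cov[j].astype(float))
        cov_names = tuple(f"cov{j}" for j in range(cov.shape[0]))
    X = np.column_stack(cols)
    if y.size <= X.shape[1] + 1:
        raise ValueError("too few observations for the design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix")
    if logistic:
        fit = sm.Logit(y, X).fit(disp=0)
        model = "logistic"
    else:
        fit = sm.OLS(y, X).fit()
        if fit.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))):
            raise ValueError("degenerate fit: residual variance is zero")
        model = "ols"
    return RegressionResult(
        coefficient=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(y.size),
        outcome=names[0],
        predictor=names[1],
        covariates=cov_names,
        model=model,
    )


# ---------------------------------------------------------------------------
# ordered-group tests


def tertile_assign(values) -> np.ndarray:
    """Ordinal tertile (1, 2, 3) per value; cuts at the nearest-rank 33.3rd
    and 66.7th percentiles with ties assigned to the lower tertile."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need n >= 3 for tertiles")
    if np.ptp(values) == 0:
        raise ValueError("degenerate tertiles: all values equal")
    c1 = _nearest_rank(values, 100.0 / 3.0)
    c2 = _nearest_rank(values, 200.0 / 3.0)
    return (1 + (values > c1).astype(int) + (values > c2).astype(int)).astype(int)


def cuzick_trend(values, groups) -> StatTestResult:
    """Rank test for trend across ordered groups (Cuzick / Stata nptrend).

    Uses midranks for ties; the z statistic is the linear rank statistic
    T = sum(score_i * rank_i) standardized by its exact permutation moments.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size or values.size < 3:
        raise ValueError("need matched values and groups, n >= 3")
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least 2 ordered groups")
    # group scores 1, 2, ... in sorted level order
    score_of = {lev: i + 1 for i, lev in enumerate(levels)}
    scores = np.array([score_of[g] for g in groups], dtype=float)
    ranks = sps.rankdata(values)  # midranks
    n = values.size
    if np.ptp(ranks) == 0:
        raise ValueError("all values tied")
    T = float(np.sum(scores * ranks))
    e_t = n * scores.mean() * ranks.mean()
    var_t = np.sum((scores - scores.mean()) ** 2) * np.sum((ranks - ranks.mean()) ** 2) / (n - 1)
    if var_t <= 0:
        raise ValueError("degenerate trend statistic")
    z = (T - e_t) / math.sqrt(var_t)
    p = 2 * sps.norm.sf(abs(z))
    return StatTestResult(
        test_name="cuzick_trend",
        statistic=float(z),
        p_value=float(p),
        n=int(n),
        groups=tuple(int(levels[i]) if np.issubdtype(levels.dtype, np.integer) else levels[i] for i in range(levels.size)),
    )


def kruskal_wallis(*group_samples) -> StatTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k-1)."""
    if len(group_samples) == 1:
        group_samples = tuple(group_samples[0])
    samples = [np.asarray(g, dtype=float) for g in group_samples]
    if len(samples) < 2 or any(s.size < 1 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    n_total = sum(s.size for s in samples)
    if n_total < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        # no information: identical distributions by construction
        return StatTestResult(
            test_name="kruskal_wallis", statistic=0.0, p_value=1.0, n=n_total,
            df=float(len(samples) - 1),
        )
    h, p = sps.kruskal(*samples)
    return StatTestResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n=n_total,
        df=float(len(samples) - 1),
    )


# ---------------------------------------------------------------------------
# reader reproducibility


def icc_reproducibility(ratings) -> StatTestResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    ``ratings`` is an (n subjects) x (k readers) array with no missing cells.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be subjects x readers")
    n, k = ratings.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 readings each")
    if np.isnan(ratings).any():
        raise ValueError("missing cells are not allowed")
    grand = ratings.mean()
    subj_means = ratings.mean(axis=1)
    reader_means = ratings.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_reader = n * np.sum((reader_means - grand) ** 2)
    ss_total = np.sum((ratings - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_reader
    msr = ss_subj / (n - 1)
    msc = ss_reader / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= 0:
        raise ValueError("zero between-subject variance")
    icc = (msr - mse) / denom
    return StatTestResult(
        test_name="icc_2_1",
        statistic=float(icc),
        p_value=1.0 if msr <= mse else float(sps.f.sf(msr / mse, n - 1, (n - 1) * (k - 1))),
        n=n,
        df=float(n - 1),
        estimate=float(icc),
    )


# ---------------------------------------------------------------------------
# analysis grid

DEFAULT_ECHO_VARS = ("lvwt", "lvdd", "lv_mass", "rwt", "e_prime", "sic", "msi")
DEFAULT_BP_VARS = ("sbp", "dbp", "map")


def _sex_indicator(col: pd.Series) -> np.ndarray:
    return (col.astype(str).str.upper().isin(["F", "FEMALE", "1"])).to_numpy(dtype=float)


def run_clinical_analysis(
    table: pd.DataFrame,
    echo_vars=DEFAULT_ECHO_VARS,
    bp_vars=DEFAULT_BP_VARS,
    covariates=("age", "sex"),
    logistic: bool = False,
) -> dict:
    """The full two-group analysis grid on a cohort table.

    Returns a dict of tidy DataFrames: ``group_comparison`` (per-variable
    t-tests plus chi-square for sex), ``status_regression`` (group status vs
    each standardized echo variable, unadjusted and covariate-adjusted),
    ``bp_regression`` (each BP measure vs each standardized echo variable),
    and ``tertile_trend`` (trend of each echo variable across BP tertiles).
    """
    if "group" not in table.columns:
        raise KeyError("missing required columns: group")
    levels = list(pd.unique(table["group"]))
    if len(levels) != 2:
        raise ValueError(f"clinical analysis expects exactly 2 groups, got {levels}")
    g0 = table[table["group"] == levels[0]]
    g1 = table[table["group"] == levels[1]]
    echo_vars = [v for v in echo_vars if v in table.columns]
    bp_vars = [v for v in bp_vars if v in table.columns]
    missing = [v for v in (echo_vars or ["sic"]) if v not in table.columns]
    if missing:
        raise KeyError(f"missing required columns: {', '.join(missing)}")

    comp_rows = []
    for var in list(bp_vars) + echo_vars + [c for c in ("age",) if c in table.columns]:
        res = two_sample_t(g0[var], g1[var])
        comp_rows.append(
            {
                "variable": var,
                "test": res.test_name,
                f"mean_{levels[0]}": float(g0[var].mean()),
                f"mean_{levels[1]}": float(g1[var].mean()),
                "statistic": res.statistic,
                "p": res.p_value,
                "n": res.n,
            }
        )
    if "sex" in table.columns:
        counts = pd.crosstab(table["group"], table["sex"]).to_numpy()
        res = chi_square_test(counts)
        comp_rows.append(
            {"variable": "sex", "test": res.test_name, "statistic": res.statistic,
             "p": res.p_value, "n": res.n}
        )
    group_comparison = pd.DataFrame(comp_rows)

    status = (table["group"] == levels[1]).to_numpy(dtype=float)
    cov_arrays = []
    cov_names = []
    for c in covariates:
        if c not in table.columns:
            continue
        if c == "sex":
            cov_arrays.append(_sex_indicator(table[c]))
        else:
            cov_arrays.append(table[c].to_numpy(dtype=float))
        cov_names.append(c)

    def regress(outcome, outcome_name, adjusted):
        rows = []
        cov = np.column_stack(cov_arrays) if (adjusted and cov_arrays) else None
        for var in echo_vars:
            rr = ols_standardized(
                outcome,
                table[var].to_numpy(dtype=float),
                covariates=cov,
                logistic=logistic and outcome_name == "status",
                names=(outcome_name, var),
            )
            rows.append(
                {
                    "outcome": outcome_name,
                    "predictor": var,
                    "model": "adjusted" if adjusted else "unadjusted",
                    "coefficient": rr.coefficient,
                    "se": rr.se,
                    "p": rr.p_value,
                    "n": rr.n,
                }
            )
        return rows

    status_rows = regress(status, "status", adjusted=False) + regress(status, "status", adjusted=True)
    status_regression = pd.DataFrame(status_rows)

    bp_rows = []
    for bp in bp_vars:
        y = table[bp].to_numpy(dtype=float)
        bp_rows += regress(y, bp, adjusted=False)
        bp_rows += regress(y, bp, adjusted=True)
    bp_regression = pd.DataFrame(bp_rows)

    trend_rows = []
    for bp in bp_vars:
        tert = tertile_assign(table[bp].to_numpy(dtype=float))
        for var in echo_vars:
            res = cuzick_trend(table[var].to_numpy(dtype=float), tert)
            trend_rows.append(
                {"bp_measure": bp, "variable": var, "z": res.statistic, "p": res.p_value,
                 "n": res.n}
            )
    tertile_trend = pd.DataFrame(trend_rows)

    return {
        "group_comparison": group_comparison,
        "status_regression": status_regression,
        "bp_regression": bp_regression,
        "tertile_trend": tertile_trend,
    }


def write_analysis_bundle(results: dict, csv_path=None, json_path=None) -> None:
    """Persist the analysis grid as one tidy CSV and/or a JSON bundle."""
    frames = []
    for name, df in results.items():
        tagged = df.copy()
        tagged.insert(0, "panel", name)
        frames.append(tagged)
    tidy = pd.concat(frames, ignore_index=True)
    if csv_path is not None:
        tidy.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {name: df.to_dict(orient="records") for name, df in results.items()}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
            fh.write("\n")
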