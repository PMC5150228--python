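"""Age-trend regression and population statistics for user-level features.

The central object is :class:`AgeTrendModel`: a weighted least-squares
regression of per-(age, sex) cell means on centered age, its square, sex
(male = 0, female = 1) and the sex-by-age interactions, with weights
equal to the number of users in each cell. Because every predictor is a
function of (age, sex) alone, the cell-level weighted fit has exactly
the same coefficients as an ordinary least-squares fit to the
un-aggregated user-level rows; only R² differs (the averaging removes
within-age variance, so the cell-level R² is higher). Age is centered
at 42 years so the intercept is the predicted value for a 42-year-old
male.

When either sex-by-age interaction is significant, separate per-sex
models in age and age² are fitted (:meth:`AgeTrendResults.sex_refits`).

Also here: the pooled two-sample sex t-test, the within-/between-age
variance decomposition (ages 78+ pooled into one bin), cross-feature
Pearson correlation, and Tukey five-number summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

CENTER_AGE = 42.0
POOL_AGE = 78  # ages >= POOL_AGE form a single bin in the variance decomposition
TERM_NAMES = ("intercept", "age", "age2", "sex", "age_sex", "age2_sex")

#: significance thresholds and their table markers, most stringent first
STAR_LEVELS = ((1e-4, "†"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars_for_p(p: float) -> str:
    """Significance marker for a p-value (†, ***, **, *, or empty)."""
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return ""


def _design(age: np.ndarray, sex: np.ndarray, center_age: float) -> pd.DataFrame:
    a = np.asarray(age, dtype=float) - center_age
    s = np.asarray(sex, dtype=float)
    return pd.DataFrame(
        {
            "intercept": np.ones_like(a),
            "age": a,
            "age2": a * a,
            "sex": s,
            "age_sex": a * s,
            "age2_sex": a * a * s,
        }
    )


def aggregate_cells(
    users: pd.DataFrame, response: str, by_sex: bool = True
) -> pd.DataFrame:
    """Per-(age, sex) cell means and counts for one response.

    Users with a missing response (e.g. no detectable alpha peak) are
    excluded from that response's cells, so the cell weights are adjusted
    per feature.
    """
    if users.empty:
        raise ValueError("empty cohort: no users to aggregate")
    cols = ["age", "sex"] if by_sex else ["age"]
    df = users.loc[users[response].notna(), cols + [response]]
    if df.empty:
        raise ValueError(f"no users with a value for {response!r}")
    cells = (
        df.groupby(cols)[response]
        .agg(mean="mean", n="count")
        .reset_index()
        .rename(columns={"mean": response})
    )
    return cells


class AgeTrendModel:
    """WLS age-trend model on (age, sex) cell means.

    Parameters
    ----------
    cells : DataFrame with columns ``age``, ``sex``, the response, and
        ``n`` (cell count, used as the WLS weight).
    response : name of the response column.
    center_age : centering constant for age, default 42 years.
    users : optional user-level frame the cells were aggregated from;
        kept so results can report user counts and verify the WLS/OLS
        coefficient identity.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        response: str,
        center_age: float = CENTER_AGE,
        users: pd.DataFrame | None = None,
    ):
        required = {"age", "sex", "n", response}
        missing = required - set(cells.columns)
        if missing:
            raise ValueError(f"cells missing columns: {sorted(missing)}")
        if (cells["n"] <= 0).any():
            raise ValueError("cell weights must be positive")
        self.cells = cells.reset_index(drop=True)
        self.response = response
        self.center_age = center_age
        self.users = users
        self.exog = _design(self.cells["age"], self.cells["sex"], center_age)
        self.endog = self.cells[response].to_numpy(dtype=float)
        self.weights = self.cells["n"].to_numpy(dtype=float)

    @classmethod
    def from_users(
        cls, users: pd.DataFrame, response: str, center_age: float = CENTER_AGE
    ) -> "AgeTrendModel":
        """Build the cell-level model from user-level rows."""
        cells = aggregate_cells(users, response)
        kept = users.loc[users[response].notna()]
        return cls(cells, response, center_age=center_age, users=kept)

    def _check_rank(self, X: pd.DataFrame) -> None:
        if len(X) <= X.shape[1]:
            raise ValueError(
                f"{len(X)} cells cannot identify {X.shape[1]} terms: need more cells"
            )
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # name the offending terms by finding a maximal independent prefix
            bad = []
            cols: list[str] = []
            for c in X.columns:
                trial = X[cols + [c]].to_numpy()
                if np.linalg.matrix_rank(trial) < len(cols) + 1:
                    bad.append(c)
                else:
                    cols.append(c)
            raise ValueError(f"design matrix rank deficient; collinear terms: {bad}")

    def fit(self) -> "AgeTrendResults":
        self._check_rank(self.exog)
        res = sm.WLS(self.endog, self.exog, weights=self.weights).fit()
        return AgeTrendResults(model=self, _sm=res)

    def fit_user_level(self):
        """OLS on the un-aggregated user rows (coefficient cross-check)."""
        if self.users is None:
            raise ValueError("no user-level data attached to this model")
        X = _design(self.users["age"], self.users["sex"], self.center_age)
        y = self.users[self.response].to_numpy(dtype=float)
        return sm.OLS(y, X).fit()


@dataclass
class SexRefit:
    """Per-sex model in age and age², triggered by a significant interaction."""

    sex: int
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    n_cells: int


@dataclass
class AgeTrendResults:
    """Estimates, uncertainties and diagnostics for one age-trend fit."""

    model: AgeTrendModel
    _sm: object  # statsmodels RegressionResults
    refit_alpha: float = 0.05
    _refits: dict[int, SexRefit] | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._sm.params), index=TERM_NAMES)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.asarray(self._sm.bse), index=TERM_NAMES)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(np.asarray(self._sm.pvalues), index=TERM_NAMES)

    @property
    def rsquared(self) -> float:
        return float(self._sm.rsquared)

    @property
    def df_resid(self) -> float:
        return float(self._sm.df_resid)

    @property
    def n_cells(self) -> int:
        return len(self.model.cells)

    @property
    def n_users(self) -> int:
        return int(self.model.weights.sum())

    @property
    def stars(self) -> pd.Series:
        return self.pvalues.map(stars_for_p)

    def predict(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        X = _design(np.asarray(age), np.asarray(sex), self.model.center_age)
        return X.to_numpy() @ np.asarray(self._sm.params)

    @property
    def interaction_significant(self) -> bool:
        """True when either sex-by-age interaction is significant."""
        p = self.pvalues
        return bool(p["age_sex"] < self.refit_alpha or p["age2_sex"] < self.refit_alpha)

    def sex_refits(self, min_cells: int = 4) -> dict[int, SexRefit]:
        """Per-sex age/age² fits, emitted only when an interaction is significant.

        Returns an empty mapping when neither interaction reaches the
        trigger level. A sex with fewer than ``min_cells`` cells is
        skipped with a warning.
        """
        if not self.interaction_significant:
            return {}
        if self._refits is not None:
            return self._refits
        out: dict[int, SexRefit] = {}
        for sex in (0, 1):
            sub = self.model.cells[self.model.cells["sex"] == sex]
            if len(sub) < min_cells:
                warnings.warn(
                    f"sex={sex}: only {len(sub)} cells, per-sex refit skipped",
                    stacklevel=2,
                )
                continue
            a = sub["age"].to_numpy(dtype=float) - self.model.center_age
            X = pd.DataFrame({"intercept": np.ones_like(a), "age": a, "age2": a * a})
            res = sm.WLS(
                sub[self.model.response].to_numpy(dtype=float),
                X,
                weights=sub["n"].to_numpy(dtype=float),
            ).fit()
            idx = ["intercept", "age", "age2"]
            out[sex] = SexRefit(
                sex=sex,
                params=pd.Series(np.asarray(res.params), index=idx),
                bse=pd.Series(np.asarray(res.bse), index=idx),
                pvalues=pd.Series(np.asarray(res.pvalues), index=idx),
                rsquared=float(res.rsquared),
                n_cells=len(sub),
            )
        self._refits = out
        return out

    def summary(self) -> str:
        lines = [
            f"Age-trend WLS: {self.model.response}",
            f"cells: {self.n_cells}   users: {self.n_users}   "
            f"R2: {self.rsquared:.3f}   df_resid: {self.df_resid:.0f}",
            f"{'term':<10}{'coef':>12}{'se':>12}{'p':>12}  sig",
        ]
        for t in TERM_NAMES:
            lines.append(
                f"{t:<10}{self.params[t]:>12.5f}{self.bse[t]:>12.5f}"
                f"{self.pvalues[t]:>12.3g}  {self.stars[t]}"
            )
        refits = self.sex_refits()
        for sex, r in refits.items():
            label = "male" if sex == 0 else "female"
            lines.append(
                f"  by-sex ({label}): age {r.params['age']:.5f}"
                f"{stars_for_p(r.pvalues['age'])}, age2 {r.params['age2']:.5f}"
                f"{stars_for_p(r.pvalues['age2'])}, R2 {r.rsquared:.3f}"
            )
        return "\n".join(lines)


def fit_wls(
    cells: pd.DataFrame, response: str, center_age: float = CENTER_AGE
) -> AgeTrendResults:
    """Fit the age-trend WLS model to an (age, sex) cell table."""
    return AgeTrendModel(cells, response, center_age=center_age).fit()


def fit_age_trend(
    users: pd.DataFrame, response: str, center_age: float = CENTER_AGE
) -> AgeTrendResults:
    """Aggregate user rows into cells and fit the age-trend model."""
    return AgeTrendModel.from_users(users, response, center_age=center_age).fit()


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def sex_ttest(users: pd.DataFrame, response: str) -> TTestResult:
    """Pooled-variance two-sample t-test of female vs male means.

    Positive t means the female mean is higher. df = n_total - 2.
    """
    df = users.loc[users[response].notna()]
    male = df.loc[df["sex"] == 0, response].to_numpy(dtype=float)
    female = df.loc[df["sex"] == 1, response].to_numpy(dtype=float)
    if len(male) < 2 or len(female) < 2:
        raise ValueError("need at least two users of each sex")
    t, p = stats.ttest_ind(female, male, equal_var=True)
    return TTestResult(t=float(t), df=len(male) + len(female) - 2, p=float(p))


@dataclass
class VarianceDecomposition:
    between_age_sd: float
    mean_within_age_sd: float
    n_bins: int
    pool_age: int = POOL_AGE


def variance_decomposition(
    users: pd.DataFrame, response: str, pool_age: int = POOL_AGE
) -> VarianceDecomposition:
    """Within- vs between-age variability of one feature.

    Within-age SD: SD across users at each age, averaged over ages (ages
    with a single user contribute nothing). Between-age SD: SD across the
    per-age means. Ages >= ``pool_age`` are grouped into one bin because
    they are sparsely populated.
    """
    df = users.loc[users[response].notna(), ["age", response]].copy()
    if df.empty:
        raise ValueError(f"no users with a value for {response!r}")
    df["age_bin"] = df["age"].clip(upper=pool_age)
    grouped = df.groupby("age_bin")[response]
    means = grouped.mean()
    sds = grouped.std(ddof=1).dropna()
    return VarianceDecomposition(
        between_age_sd=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        mean_within_age_sd=float(sds.mean()) if len(sds) else 0.0,
        n_bins=len(means),
        pool_age=pool_age,
    )


@dataclass
class CorrelationResult:
    r: float
    slope: float
    p: float
    n: int


def feature_correlation(users: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Pearson correlation and simple-regression slope of y on x."""
    df = users.loc[users[x].notna() & users[y].notna(), [x, y]]
    if len(df) < 3:
        raise ValueError(f"need >= 3 paired observations, have {len(df)}")
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValueError("correlation undefined: a feature has zero variance")
    res = stats.linregress(xv, yv)
    return CorrelationResult(
        r=float(res.rvalue), slope=float(res.slope), p=float(res.pvalue), n=len(df)
    )


@dataclass
class DistributionSummary:
    median: float
    q1: float
    q3: float
    lower_adjacent: float
    upper_adjacent: float


def summarize_distribution(values) -> DistributionSummary:
    """Tukey five-number summary with adjacent values.

    Quartiles are medians of the lower/upper halves excluding the overall
    median when n is odd; adjacent values are the most extreme data
    points within 1.5 IQR of the quartiles.
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("need at least one value")
    n = x.size
    med = float(np.median(x))
    half = n // 2
    if n == 1:
        q1 = q3 = med
    else:
        q1 = float(np.median(x[:half]))
        q3 = float(np.median(x[n - half :]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return DistributionSummary(
        median=med,
        q1=q1,
        q3=q3,
        lower_adjacent=float(inside.min()),
        upper_adjacent=float(inside.max()),
    )


def long_format(features: pd.DataFrame, band: str = "total") -> pd.DataFrame:
    """User x task x channel long table of one band's log power."""
    from .session_io import CHANNELS

    frames = []
    for ch in CHANNELS:
        col = f"log_{band}_{ch}"
        sub = features[["user_id", "task", "age", "sex", col]].rename(
            columns={col: "value"}
        )
        sub["channel"] = ch
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out["age_c"] = out["age"] - CENTER_AGE
    return out.dropna(subset=["value"])


def fit_omnibus(long_df: pd.DataFrame):
    """Gating model with age, age², sex, task and channel plus all
    interactions up to four-way, on the user x task x channel long table.

    Used only to justify per-channel/per-task analyses: a significant
    task or channel interaction means the factors cannot be collapsed.
    """
    formula = "value ~ (age_c + I(age_c**2) + sex + C(task) + C(channel)) ** 4"
    return smf.ols(formula, data=long_df).fit()
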