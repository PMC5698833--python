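"""Cohort statistics: correlations, age-group ANOVA, IOP regression.

The statistical surface mirrors how a tonometry cohort is usually analysed:
pairwise Pearson correlations with two-tailed significance (reported raw,
no multiplicity correction), one-way ANOVA across the paediatric / adult /
elderly age groups, and an ordinary-least-squares regression of measured
IOP on age, CCT and the estimated Young's modulus, summarised by the
pseudo-R^2 = 1 - RSS/TSS (the explained proportion of IOP variation).  The
fitted linear predictor

    IOP [mmHg] = -8.106 + 0.034 age [y] + 0.036 CCT [um] + 8.922 E [MPa]

is exposed as a closed-form prediction model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CollinearityError",
    "DegenerateDesignError",
    "RegressionResult",
    "predict_iop",
    "pseudo_r2",
    "pearson_matrix",
    "fit_iop_regression",
    "anova_age_groups",
    "IOP_COEFFICIENTS",
]

#: Published-style IOP prediction coefficients (mmHg units).
IOP_COEFFICIENTS = {
    "intercept": -8.106,
    "age": 0.034,
    "cct_um": 0.036,
    "E_mpa": 8.922,
}


class CollinearityError(ValueError):
    """Rank-deficient regression design."""


class DegenerateDesignError(ValueError):
    """Fewer than two nonempty groups."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary for the IOP model.

    ``params``/``se``/``pvalues`` are keyed by covariate (plus
    ``intercept``); ``pseudo_r2`` is 1 - RSS/TSS of the full model;
    ``marginal_r2`` is the explained proportion when each covariate enters
    alone, ``sequential_r2`` the increment when it enters after those listed
    before it (both per-covariate conventions are computed and labelled
    because cohort reports rarely say which they use).
    """

    params: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    pseudo_r2: float
    marginal_r2: dict[str, float]
    sequential_r2: dict[str, float]
    nobs: int

    def __post_init__(self) -> None:
        if self.pseudo_r2 > 1.0 + 1e-12:
            raise ValueError("pseudo_r2 cannot exceed 1")


def predict_iop(age: float, cct_um: float, E_mpa: float) -> float:
    """Closed-form IOP prediction (mmHg) from age, CCT and modulus."""
    c = IOP_COEFFICIENTS
    return (
        c["intercept"] + c["age"] * age + c["cct_um"] * cct_um + c["E_mpa"] * E_mpa
    )


def pseudo_r2(y_obs: np.ndarray, y_fit: np.ndarray) -> float:
    """Explained proportion ``1 - RSS / TSS`` with TSS about the mean of
    the observations.  Equals the classical R^2 when ``y_fit`` is a
    least-squares fit."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y_obs.shape != y_fit.shape or y_obs.ndim != 1:
        raise ValueError("y_obs and y_fit must be 1-D arrays of equal length")
    if y_obs.size < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant observations: total variation undefined")
    rss = float(np.sum((y_obs - y_fit) ** 2))
    return 1.0 - rss / tss


def pearson_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations and two-tailed p-values.

    Returns ``(r, p)`` dataframes; the correlation matrix is symmetric with
    unit diagonal.  Constant columns yield NaN entries (flagged undefined)
    rather than an exception.  Significance is conventionally read at the
    raw 0.05 and 0.01 two-tailed levels.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlation p-values")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        xa = table[a].to_numpy(dtype=float)
        if np.std(xa) == 0:
            r.loc[a, a] = np.nan
        for b in cols[i + 1 :]:
            xb = table[b].to_numpy(dtype=float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(xa, xb)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


def fit_iop_regression(
    table: pd.DataFrame,
    response: str = "iop_mmhg",
    covariates: tuple[str, ...] = ("age", "cct_um", "E_mpa"),
) -> RegressionResult:
    """OLS of measured IOP on the fixed covariate set.

    The three published covariates (age, CCT, modulus) are fitted jointly;
    per-covariate explained proportions are reported in both the marginal
    (covariate alone) and sequential (in listed order) conventions.
    """
    missing = [c for c in (response, *covariates) if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks columns {missing}")
    if len(table) <= len(covariates) + 1:
        raise ValueError("need more rows than covariates plus intercept")
    y = table[response].to_numpy(dtype=float)
    X = table[list(covariates)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    names = ["intercept", *covariates]
    params = dict(zip(names, map(float, fit.params)))
    se = dict(zip(names, map(float, fit.bse)))
    pvalues = dict(zip(names, map(float, fit.pvalues)))

    def r2_of(subset: list[str]) -> float:
        Xs = sm.add_constant(
            table[subset].to_numpy(dtype=float), has_constant="add"
        )
        return pseudo_r2(y, sm.OLS(y, Xs).fit().fittedvalues)

    marginal = {c: r2_of([c]) for c in covariates}
    sequential: dict[str, float] = {}
    prev = 0.0
    for k, c in enumerate(covariates):
        cur = r2_of(list(covariates[: k + 1]))
        sequential[c] = cur - prev
        prev = cur
    return RegressionResult(
        params=params,
        se=se,
        pvalues=pvalues,
        pseudo_r2=pseudo_r2(y, np.asarray(fit.fittedvalues)),
        marginal_r2=marginal,
        sequential_r2=sequential,
        nobs=int(fit.nobs),
    )


def anova_age_groups(
    table: pd.DataFrame,
    value_columns: list[str] | None = None,
    age_column: str = "age",
    bins: tuple[float, float] = (14.0, 64.0),
) -> pd.DataFrame:
    """One-way ANOVA of each parameter across the standard age groups.

    Groups are ``age <= bins[0]`` (paediatric), ``bins[0] < age <= bins[1]``
    (adult) and ``age > bins[1]`` (elderly).  Returns a dataframe with the
    F statistic and p-value per parameter plus the group sizes.
    """
    if age_column not in table.columns:
        raise KeyError(f"table lacks column {age_column!r}")
    age = table[age_column].to_numpy(dtype=float)
    masks = [
        age <= bins[0],
        (age > bins[0]) & (age <= bins[1]),
        age > bins[1],
    ]
    nonempty = [m for m in masks if m.sum() > 0]
    if len(nonempty) < 2:
        raise DegenerateDesignError("need at least two nonempty age groups")
    cols = value_columns if value_columns is not None else [
        c
        for c in table.columns
        if pd.api.types.is_numeric_dtype(table[c]) and c != age_column
    ]
    rows = []
    for c in cols:
        groups = [table.loc[m, c].to_numpy(dtype=float) for m in nonempty]
        if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
            f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = sps.f_oneway(*groups)
        rows.append(
            {
                "parameter": c,
                "F": float(f_stat),
                "p": float(p_val),
                **{f"n_group{k}": int(m.sum()) for k, m in enumerate(masks)},
            }
        )
    return pd.DataFrame(rows)
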