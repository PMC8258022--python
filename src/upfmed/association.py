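"""Descriptive and regression analyses of the analysis table.

One row per participant: exposure (NOVA 4 % of energy), mediator (DASH
score), outcome (CMR score, modelled as continuous), and covariates.
Provides the Pearson correlation matrix, two-group t tests, chi-square
independence tests, the one-way ANOVA of exposure across misreporting
categories, and OLS fits for the fixed covariate sets of the diet-quality
(mediator) and CMR (outcome) models.

Dummy coding uses fixed reference categories: female, non-smoker, lowest
income and education bands, low physical activity, acceptable
misreporting. These are recorded on every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

__all__ = [
    "CATEGORY_LEVELS",
    "FitResult",
    "prepare_categories",
    "pearson_matrix",
    "fit_ols",
    "mediator_model",
    "outcome_model",
    "ttest_by",
    "chi2_independence",
    "anova_by",
    "reporting_category_anova",
    "plot_correlation_matrix",
]

#: Category orderings; the first level of each is the dummy-coding reference.
CATEGORY_LEVELS = {
    "sex": ["female", "male"],
    "smoking": ["non_smoker", "current_smoker"],
    "education": ["below_gcse", "gcse", "a_level", "higher"],
    "income": ["lt26k", "26_38k", "38_58k", "58_78k", "gt80k"],
    "pal": ["low", "medium", "high"],
    "misreporting": ["acceptable", "under", "over"],
}

#: Covariates of the adjusted diet-quality model as listed in the text.
MEDIATOR_COVARIATES_TEXT = ("age", "sex", "smoking", "education", "income", "misreporting")
#: Covariates of the adjusted diet-quality model as listed in the table footnote.
MEDIATOR_COVARIATES_FOOTNOTE = ("age", "education", "income", "misreporting")
#: Covariates of the CMR model (without the mediator).
OUTCOME_COVARIATES = ("age", "sex", "bmi", "smoking", "education", "income", "pal", "misreporting")


def prepare_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Cast known categorical columns to ordered Categoricals (reference first)."""
    out = table.copy()
    for col, levels in CATEGORY_LEVELS.items():
        if col in out.columns:
            out[col] = pd.Categorical(out[col], categories=levels)
            if out[col].isna().any():
                raise ValueError(f"column {col!r} contains values outside {levels}")
    return out


@dataclass
class FitResult:
    """Coefficients, standard errors and p-values of one fitted model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    model_label: str
    formula: str
    reference_levels: dict = field(default_factory=dict)
    _sm: object = field(default=None, repr=False, compare=False)

    def __getitem__(self, term: str) -> float:
        return float(self.params[term])

    def term(self, name: str) -> str:
        """Design-matrix name of the single term containing ``name``."""
        hits = [t for t in self.params.index if t == name]
        if not hits:
            raise KeyError(f"term {name!r} not in model {self.model_label!r}")
        return hits[0]

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return np.asarray(self._sm.predict(data))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )


def fit_ols(formula: str, data: pd.DataFrame, label: str = "ols") -> FitResult:
    """Ordinary least squares via the formula interface.

    Raises on a rank-deficient design, listing the collinear columns,
    rather than silently pseudo-inverting.
    """
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        bad = [model.exog_names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {exog.shape[1]} columns; "
            f"collinear terms: {bad or model.exog_names}"
        )
    res = model.fit()
    if int(res.nobs) <= exog.shape[1]:
        raise ValueError("need more observations than design columns")
    refs = {c: CATEGORY_LEVELS[c][0] for c in CATEGORY_LEVELS if c in data.columns}
    return FitResult(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        nobs=int(res.nobs),
        model_label=label,
        formula=formula,
        reference_levels=refs,
        _sm=res,
    )


def _formula(outcome: str, terms) -> str:
    return f"{outcome} ~ " + " + ".join(terms)


def mediator_model(
    table: pd.DataFrame,
    exposure: str = "nova4_pct",
    mediator: str = "dash",
    variant: str = "text",
) -> FitResult:
    """Adjusted diet-quality model (DASH on NOVA 4 share + covariates).

    ``variant='text'`` adjusts for age, sex, smoking, education, income
    and misreporting; ``variant='footnote'`` drops sex and smoking.
    """
    covs = {"text": MEDIATOR_COVARIATES_TEXT, "footnote": MEDIATOR_COVARIATES_FOOTNOTE}[variant]
    data = prepare_categories(table)
    return fit_ols(_formula(mediator, (exposure, *covs)), data, label=f"mediator_{variant}")


def outcome_model(
    table: pd.DataFrame,
    exposure: str = "nova4_pct",
    mediator: str = "dash",
    outcome: str = "cmr",
    adjust_for_diet_quality: bool = False,
) -> FitResult:
    """CMR model; with ``adjust_for_diet_quality`` the mediator enters too."""
    terms = (exposure, *OUTCOME_COVARIATES) + ((mediator,) if adjust_for_diet_quality else ())
    data = prepare_categories(table)
    label = "outcome_adjusted" if adjust_for_diet_quality else "outcome_total"
    return fit_ols(_formula(outcome, terms), data, label=label)


# --------------------------------------------------------------------------
# Descriptive tests
# --------------------------------------------------------------------------

def pearson_matrix(columns: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix and two-sided p-values (t with n-2 df)."""
    x = columns.to_numpy(float)
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 rows")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = columns.columns[sd == 0].tolist()
        raise ValueError(f"constant columns have undefined correlation: {bad}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, 1e-300))
    p = 2.0 * st.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    cols = columns.columns
    return (pd.DataFrame(r, index=cols, columns=cols), pd.DataFrame(p, index=cols, columns=cols))


@dataclass(frozen=True)
class GroupTest:
    test: str
    statistic: float
    df: float
    pvalue: float
    groups: tuple


def ttest_by(table: pd.DataFrame, value: str, group: str) -> GroupTest:
    """Student's t (pooled variance) for a two-level grouping."""
    levels = [g for g, _ in table.groupby(group, observed=True)]
    if len(levels) != 2:
        raise ValueError(f"{group!r} must have exactly 2 levels, found {levels}")
    a, b = (table.loc[table[group] == g, value].to_numpy(float) for g in levels)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs n >= 2")
    res = st.ttest_ind(a, b, equal_var=True)
    return GroupTest("t", float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue), tuple(levels))


def chi2_independence(table: pd.DataFrame, a: str, b: str) -> GroupTest:
    ct = pd.crosstab(table[a], table[b])
    if (ct.sum(axis=1) == 0).any() or (ct.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an empty margin")
    res = st.chi2_contingency(ct.to_numpy(), correction=False)
    return GroupTest("chi2", float(res.statistic), float(res.dof), float(res.pvalue),
                     (tuple(ct.index), tuple(ct.columns)))


def anova_by(table: pd.DataFrame, value: str, group: str) -> GroupTest:
    """One-way ANOVA of a continuous variable across >= 2 groups."""
    samples = [g[value].to_numpy(float) for _, g in table.groupby(group, observed=True)]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    res = st.f_oneway(*samples)
    k, n = len(samples), sum(len(s) for s in samples)
    return GroupTest("anova_F", float(res.statistic), float(k - 1), float(res.pvalue),
                     tuple(sorted(table[group].unique().tolist(), key=str)))


def reporting_category_anova(table: pd.DataFrame, exposure: str = "nova4_pct") -> GroupTest:
    """Difference in NOVA 4 energy share across misreporting categories."""
    return anova_by(table, exposure, "misreporting")


def plot_correlation_matrix(corr: pd.DataFrame, path=None):
    """Annotated heatmap of a correlation matrix; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * len(corr), 1.0 + 0.7 * len(corr)))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr)), corr.index)
    for i in range(len(corr)):
        for j in range(len(corr)):
            ax.text(j, i, f"{corr.iat[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
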