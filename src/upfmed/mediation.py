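"""Model-based causal mediation for linear mediator and outcome models.

The estimand decomposes the effect of the exposure (NOVA 4 % of energy)
on the outcome (CMR score) into the average causal mediation effect
through diet quality and the average direct effect:

* mediator model:  M = a*X + covariates + error
* outcome model:   Y = c'*X + b*M + covariates + error
* ACME = a*b, ADE = c', total effect = a*b + c'.

Point estimates come from the product of coefficients; an independent
counterfactual-prediction route (simulate M under X and X+1, push both
through the outcome model, average the difference) is provided and must
agree with the product to numerical precision for linear models.
Uncertainty comes from a nonparametric pairs bootstrap: participants are
resampled with replacement, both models refitted per replicate, and
percentile confidence intervals and continuity-corrected bootstrap
p-values reported.

Typical use::

    model = MediationModel(table, exposure="nova4_pct", mediator="dash",
                           outcome="cmr")
    res = model.fit(sims=1000, seed=7)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

from ._rng import substream
from .association import FitResult, fit_ols, prepare_categories
from .errors import UpfmedError

__all__ = [
    "MEDIATION_COVARIATES",
    "MediationModel",
    "MediationResults",
    "acme_product",
    "acme_counterfactual",
    "UnsupportedModelError",
]

#: Covariates used in both mediation models: age, sex, BMI, smoking,
#: misreporting, education, physical activity and income band.
MEDIATION_COVARIATES = (
    "age", "sex", "bmi", "smoking", "misreporting", "education", "pal", "income",
)


class UnsupportedModelError(UpfmedError):
    """The counterfactual route requires linear (OLS) mediator/outcome fits."""


def _coef(fit: FitResult, name: str) -> float:
    if name not in fit.params.index:
        raise KeyError(
            f"model {fit.model_label!r} has no term {name!r}; terms: {list(fit.params.index)}"
        )
    return float(fit.params[name])


def acme_product(
    mediator_fit: FitResult,
    outcome_fit: FitResult,
    exposure: str = "nova4_pct",
    mediator: str = "dash",
) -> tuple[float, float, float]:
    """(ACME, ADE, total) by the product of coefficients.

    ACME = a*b with a the exposure coefficient of the mediator model and
    b the mediator coefficient of the outcome model; ADE is the exposure
    coefficient of the outcome model; total = ACME + ADE.
    """
    a = _coef(mediator_fit, exposure)
    b = _coef(outcome_fit, mediator)
    c_direct = _coef(outcome_fit, exposure)
    acme = a * b
    return acme, c_direct, acme + c_direct


def acme_counterfactual(
    mediator_fit: FitResult,
    outcome_fit: FitResult,
    table: pd.DataFrame,
    exposure: str = "nova4_pct",
    mediator: str = "dash",
) -> float:
    """ACME by counterfactual prediction (independent of the product formula).

    For every participant, predict the mediator at the observed exposure
    and at exposure + 1; push both predictions through the outcome model
    holding exposure at its observed value; average the outcome
    difference. Equals the product of coefficients exactly for linear
    models.
    """
    from statsmodels.regression.linear_model import OLS

    for f in (mediator_fit, outcome_fit):
        if f._sm is None or not isinstance(f._sm.model, OLS):
            raise UnsupportedModelError(
                f"counterfactual ACME needs linear OLS fits; {f.model_label!r} is not"
            )
    data = table.copy()
    m_at_x = mediator_fit.predict(data)
    shifted = data.copy()
    shifted[exposure] = shifted[exposure] + 1.0
    m_at_x1 = mediator_fit.predict(shifted)

    lo = data.copy()
    lo[mediator] = m_at_x
    hi = data.copy()
    hi[mediator] = m_at_x1
    return float(np.mean(outcome_fit.predict(hi) - outcome_fit.predict(lo)))


@dataclass
class MediationResults:
    """Estimates, bootstrap uncertainty and diagnostics of a mediation fit."""

    acme: float
    ade: float
    total_effect: float
    proportion_mediated: float
    conf_ints: pd.DataFrame          # rows acme/ade/total, cols lower/upper
    pvalues: dict
    sims: int
    seed: int | None
    ci_level: float
    ci_method: str
    n_failed_replicates: int
    nobs: int
    mediator_fit: FitResult = field(repr=False)
    outcome_fit: FitResult = field(repr=False)
    boot_draws: pd.DataFrame = field(default=None, repr=False)

    @property
    def p_floor(self) -> float:
        """Smallest attainable two-sided bootstrap p at this replicate count."""
        return 2.0 / (self.sims + 1)

    def conf_int(self) -> pd.DataFrame:
        return self.conf_ints

    def summary(self) -> str:
        rows = []
        for name, val in (("ACME", self.acme), ("ADE", self.ade), ("Total effect", self.total_effect)):
            key = {"ACME": "acme", "ADE": "ade", "Total effect": "total"}[name]
            lo, hi = self.conf_ints.loc[key]
            p = self.pvalues[key]
            pstr = f"{p:.4f}" + (" (floor)" if p <= self.p_floor + 1e-15 else "")
            rows.append(f"{name:<22}{val:>12.5f}  [{lo:.5f}, {hi:.5f}]  p={pstr}")
        pm = ("undefined" if np.isnan(self.proportion_mediated)
              else f"{self.proportion_mediated:.3f}")
        lines = [
            "Causal mediation (linear models, nonparametric pairs bootstrap)",
            "=" * 70,
            f"{'':<22}{'Estimate':>12}  {int(self.ci_level)}% CI ({self.ci_method})",
            *rows,
            f"{'Proportion mediated':<22}{pm:>12}",
            "-" * 70,
            f"n = {self.nobs}, sims = {self.sims}, seed = {self.seed}, "
            f"failed replicates = {self.n_failed_replicates}",
            f"Bootstrap p-values are floored at 2/(sims+1) = {self.p_floor:.4g}.",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "acme": self.acme,
            "ade": self.ade,
            "total_effect": self.total_effect,
            "proportion_mediated": None if np.isnan(self.proportion_mediated) else self.proportion_mediated,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "conf_int": {k: list(map(float, v)) for k, v in self.conf_ints.iterrows()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "sims": self.sims,
            "seed": self.seed,
            "n_failed_replicates": self.n_failed_replicates,
            "nobs": self.nobs,
        }

    def plot(self, path=None):
        """Histogram of the bootstrap ACME draws with the CI marked."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(self.boot_draws["acme"], bins=40, color="steelblue", alpha=0.8)
        lo, hi = self.conf_ints.loc["acme"]
        for x, c in ((self.acme, "black"), (lo, "firebrick"), (hi, "firebrick")):
            ax.axvline(x, color=c, lw=1.2)
        ax.set_xlabel("bootstrap ACME")
        ax.set_ylabel("replicates")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class MediationModel:
    """Linear mediation model for a participant-level analysis table.

    Parameters
    ----------
    data : DataFrame with exposure, mediator, outcome and covariates.
    exposure, mediator, outcome : column names.
    covariates : terms entering both models (default the standard set).
    ci_level : confidence level in percent.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str = "nova4_pct",
        mediator: str = "dash",
        outcome: str = "cmr",
        covariates: tuple[str, ...] | None = None,
        ci_level: float = 95.0,
    ):
        if not 0 < ci_level < 100:
            raise ValueError("ci_level must be in (0, 100)")
        self.exposure, self.mediator, self.outcome = exposure, mediator, outcome
        self.covariates = tuple(
            covariates if covariates is not None
            else (c for c in MEDIATION_COVARIATES if c in data.columns)
        )
        self.ci_level = float(ci_level)
        self.data = prepare_categories(data).reset_index(drop=True)
        if self.data.isna().any().any():
            raise ValueError("analysis table must be complete-case (no missing values)")
        covs = " + ".join(self.covariates)
        tail = f" + {covs}" if covs else ""
        self.mediator_formula = f"{mediator} ~ {exposure}{tail}"
        self.outcome_formula = f"{outcome} ~ {exposure} + {mediator}{tail}"
        # design matrices built once; the bootstrap resamples their rows
        med = smf.ols(self.mediator_formula, data=self.data)
        out = smf.ols(self.outcome_formula, data=self.data)
        self._Xm, self._ym = med.exog, med.endog
        self._Xy, self._yy = out.exog, out.endog
        self._im = med.exog_names.index(exposure)
        self._iy_x = out.exog_names.index(exposure)
        self._iy_m = out.exog_names.index(mediator)
        self.nobs = self._Xm.shape[0]
        if self.nobs <= max(self._Xm.shape[1], self._Xy.shape[1]):
            raise ValueError("need more rows than design columns")

    @classmethod
    def from_formula(
        cls, mediator_formula: str, outcome_formula: str, data: pd.DataFrame, **kw
    ) -> "MediationModel":
        """Construct from explicit ``mediator ~ exposure + ...`` formulas.

        The exposure is the first right-hand term of the mediator
        formula; covariates are the shared remaining terms.
        """
        lhs_m, rhs_m = (s.strip() for s in mediator_formula.split("~"))
        lhs_y, rhs_y = (s.strip() for s in outcome_formula.split("~"))
        terms_m = [t.strip() for t in rhs_m.split("+")]
        exposure = terms_m[0]
        covs = tuple(t for t in terms_m[1:])
        return cls(data, exposure=exposure, mediator=lhs_m, outcome=lhs_y,
                   covariates=covs, **kw)

    def _replicate(self, idx: np.ndarray) -> tuple[float, float] | None:
        """(a, (b, c')) slopes for one resample, or None if rank-deficient."""
        bm, _, rank_m, _ = np.linalg.lstsq(self._Xm[idx], self._ym[idx], rcond=None)
        if rank_m < self._Xm.shape[1]:
            return None
        by, _, rank_y, _ = np.linalg.lstsq(self._Xy[idx], self._yy[idx], rcond=None)
        if rank_y < self._Xy.shape[1]:
            return None
        return bm[self._im], (by[self._iy_m], by[self._iy_x])

    def fit(
        self,
        sims: int = 1000,
        seed: int | None = None,
        ci_method: str = "percentile",
        keep_draws: bool = True,
    ) -> MediationResults:
        """Point estimates plus ``sims`` bootstrap replicates.

        A replicate whose resample yields a rank-deficient design is
        redrawn (and counted); more than 5% such failures aborts.
        ``ci_method`` is ``'percentile'`` (default) or ``'bca'``.
        """
        if sims < 1:
            raise ValueError("sims must be >= 1")
        if ci_method not in ("percentile", "bca"):
            raise ValueError("ci_method must be 'percentile' or 'bca'")
        med_fit = fit_ols(self.mediator_formula, self.data, label="mediation_mediator")
        out_fit = fit_ols(self.outcome_formula, self.data, label="mediation_outcome")
        acme, ade, total = acme_product(med_fit, out_fit, self.exposure, self.mediator)

        rng = substream(seed if seed is not None else 0, "mediation-bootstrap")
        n = self.nobs
        draws = np.empty((sims, 3))
        failed = 0
        max_failed = max(1, int(np.ceil(0.05 * sims)))
        s = 0
        while s < sims:
            idx = rng.integers(0, n, size=n)
            rep = self._replicate(idx)
            if rep is None:
                failed += 1
                if failed > max_failed:
                    raise RuntimeError(
                        f"{failed} rank-deficient bootstrap replicates (> 5% of sims={sims})"
                    )
                continue
            a, (b, c_direct) = rep
            draws[s] = (a * b, c_direct, a * b + c_direct)
            s += 1

        alpha = 1.0 - self.ci_level / 100.0
        ci = {}
        for j, key in enumerate(("acme", "ade", "total")):
            col = draws[:, j]
            point = (acme, ade, total)[j]
            if ci_method == "percentile" or sims < 3:
                lo, hi = np.percentile(col, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            else:
                lo, hi = self._bca_interval(col, point, key, alpha)
            ci[key] = (float(lo), float(hi))
        pvals = {
            key: float(min(1.0, 2.0 * min(
                (np.sum(draws[:, j] <= 0) + 1) / (sims + 1),
                (np.sum(draws[:, j] >= 0) + 1) / (sims + 1),
            )))
            for j, key in enumerate(("acme", "ade", "total"))
        }
        if total != 0 and np.sign(acme) == np.sign(total):
            prop = acme / total
        else:
            warnings.warn("ACME and total effect differ in sign; proportion mediated undefined")
            prop = float("nan")
        return MediationResults(
            acme=acme,
            ade=ade,
            total_effect=total,
            proportion_mediated=prop,
            conf_ints=pd.DataFrame(ci, index=["lower", "upper"]).T,
            pvalues=pvals,
            sims=sims,
            seed=seed,
            ci_level=self.ci_level,
            ci_method=ci_method,
            n_failed_replicates=failed,
            nobs=n,
            mediator_fit=med_fit,
            outcome_fit=out_fit,
            boot_draws=pd.DataFrame(draws, columns=["acme", "ade", "total"]) if keep_draws else None,
        )

    def _bca_interval(self, col: np.ndarray, point: float, key: str, alpha: float):
        """Bias-corrected and accelerated interval (jackknife acceleration)."""
        sims = len(col)
        z0 = st.norm.ppf((np.sum(col < point) + 0.5) / (sims + 1))
        jack = np.empty(self.nobs)
        all_idx = np.arange(self.nobs)
        for i in range(self.nobs):
            idx = np.delete(all_idx, i)
            rep = self._replicate(idx)
            if rep is None:
                jack[i] = point
                continue
            a, (b, c_direct) = rep
            jack[i] = {"acme": a * b, "ade": c_direct, "total": a * b + c_direct}[key]
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * (np.sum((jm - jack) ** 2) ** 1.5)
        acc = num / den if den > 0 else 0.0
        out = []
        for q in (alpha / 2, 1 - alpha / 2):
            z = st.norm.ppf(q)
            adj = st.norm.cdf(z0 + (z0 + z) / (1 - acc * (z0 + z)))
            out.append(np.percentile(col, 100 * np.clip(adj, 0.0, 1.0)))
        return out[0], out[1]
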