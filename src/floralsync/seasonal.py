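"""Seasonal trend and siring-success models.

Three model classes in the statsmodels idiom (construct from a DataFrame,
``.fit()`` returns a Results object with a ``summary()`` table):

``SexRatioTrendModel``
    Binomial (logit) trend of the inflorescence sex ratio on first
    flowering day: penalized-spline smooth with an MLL random intercept,
    plus the linear-logit mixed counterpart for the AIC comparison.  The
    nested inflorescence-within-MLL grouping is dropped automatically (and
    flagged) when it is unidentifiable, i.e. when inflorescences are
    observed once each.

``PTOTrendModel``
    Gaussian trend of daily genet-level pollen-transfer opportunity on day,
    MLL random intercept, with the linear mixed counterpart.

``SiringSuccessModel``
    Linear mixed model of log10 daily siring success on siring date and
    PTO (stepwise: each alone and together, compared by AIC), MLL random
    intercept, via statsmodels MixedLM.  Only genet-days with positive
    outcross siring mass enter (the log transform excludes zeros).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from floralsync._pgam import PenalizedAdditiveFit, fit_additive_model

__all__ = [
    "SexRatioTrendModel",
    "PTOTrendModel",
    "SiringSuccessModel",
    "TrendFitResults",
    "SiringModelResults",
]


@dataclass
class TrendFitResults:
    """Smooth-trend fit plus its linear mixed counterpart.

    ``smooth_fit``/``linear_fit`` are the underlying penalized fits; the
    scalar fields mirror the usual mixed-GAM report: intercept (+- s.e.) on
    the link scale, effective degrees of freedom and the approximate test
    of the smooth term, both models' AIC, and the random-intercept variance.
    """

    response: str
    family: str
    smooth_fit: PenalizedAdditiveFit
    linear_fit: PenalizedAdditiveFit
    nobs: int
    n_groups: int
    dropped_inner_group: bool = False

    @property
    def intercept(self) -> float:
        return self.smooth_fit.intercept

    @property
    def intercept_se(self) -> float:
        return self.smooth_fit.intercept_se

    @property
    def edf(self) -> float:
        return self.smooth_fit.edf_smooth

    @property
    def smooth_stat(self) -> float:
        return self.smooth_fit.term_stat

    @property
    def smooth_p(self) -> float:
        return self.smooth_fit.term_p

    @property
    def aic(self) -> float:
        return self.smooth_fit.aic

    @property
    def linear_aic(self) -> float:
        return self.linear_fit.aic

    @property
    def re_variance(self) -> float | None:
        return self.smooth_fit.re_variance

    @property
    def prefers_smooth(self) -> bool:
        """True when the spline model beats the linear one on AIC."""
        return self.aic < self.linear_aic

    def predict_curve(self, days: np.ndarray) -> np.ndarray:
        """Population-level fitted trend on the response scale."""
        return self.smooth_fit.predict_curve(np.asarray(days, dtype=float))

    def peak_day(self, grid: np.ndarray | None = None) -> float:
        """Day at which the fitted trend is maximal."""
        if grid is None:
            grid = np.linspace(self._day_min, self._day_max, 400)
        curve = self.predict_curve(grid)
        return float(grid[int(np.argmax(curve))])

    _day_min: float = 0.0
    _day_max: float = 1.0

    def summary(self) -> str:
        lines = [
            f"Seasonal trend of {self.response} ({self.family}, logit link)"
            if self.family == "binomial"
            else f"Seasonal trend of {self.response} ({self.family}, identity link)",
            f"  n = {self.nobs} observations, {self.n_groups} MLL random intercepts",
            f"  intercept        {self.intercept: .3f} +/- {self.intercept_se:.3f}",
            f"  s(day) edf       {self.edf: .2f}",
            f"  s(day) {self.smooth_fit.term_stat_name:<9} {self.smooth_stat: .2f}"
            f"  (p = {self.smooth_p:.3g})",
            f"  AIC smooth       {self.aic: .2f}",
            f"  AIC linear       {self.linear_aic: .2f}"
            f"   -> {'smooth' if self.prefers_smooth else 'linear'} model preferred",
        ]
        if self.re_variance is not None:
            lines.append(f"  MLL intercept var {self.re_variance: .4f}")
        if self.dropped_inner_group:
            lines.append("  note: inflorescence-level grouping dropped "
                         "(one observation per inflorescence)")
        return "\n".join(lines)


class _TrendModelBase:
    _family: str
    _response: str

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)

    def fit(self, df: int = 10) -> TrendFitResults:
        day, y, trials, groups, dropped = self._prepare()
        if len(day) < 20 or len(np.unique(day)) < 10:
            raise ValueError(
                "need >= 20 observations spanning >= 10 distinct days")
        common = dict(y=y, x=day, groups=groups, family=self._family,
                      trials=trials, df=df)
        smooth_fit = fit_additive_model(smooth=True, **common)
        linear_fit = fit_additive_model(smooth=False, **common)
        res = TrendFitResults(
            response=self._response,
            family=self._family,
            smooth_fit=smooth_fit,
            linear_fit=linear_fit,
            nobs=len(day),
            n_groups=smooth_fit.n_groups,
            dropped_inner_group=dropped,
        )
        res._day_min = float(day.min())
        res._day_max = float(day.max())
        return res


class SexRatioTrendModel(_TrendModelBase):
    """Binomial trend of inflorescence sex ratio on first flowering day.

    ``data`` needs columns first_flowering_day, n_male, n_total, mll_id and
    (optionally) inflorescence_id.  The response is n_male of n_total with
    a logit link, as for a proportion assembled from two counts.
    """

    _family = "binomial"
    _response = "inflorescence sex ratio"

    def _prepare(self):
        d = self.data
        day = d["first_flowering_day"].to_numpy(dtype=float)
        trials = d["n_total"].to_numpy(dtype=float)
        y = d["n_male"].to_numpy(dtype=float) / trials
        groups = d["mll_id"].to_numpy()
        dropped = False
        if "inflorescence_id" in d.columns:
            # the nested inner grouping is unidentifiable when (as here)
            # each inflorescence contributes a single record
            if d["inflorescence_id"].nunique() > 0.9 * len(d):
                dropped = True
        return day, y, trials, groups, dropped


class PTOTrendModel(_TrendModelBase):
    """Gaussian trend of daily genet-level PTO on day.

    ``data`` needs columns day, K_day, mll_id (one row per genet-day on
    which the genet flowered).
    """

    _family = "gaussian"
    _response = "pollen-transfer opportunity"

    def _prepare(self):
        d = self.data
        return (
            d["day"].to_numpy(dtype=float),
            d["K_day"].to_numpy(dtype=float),
            None,
            d["mll_id"].to_numpy(),
            False,
        )


# ---------------------------------------------------------------------------


@dataclass
class SiringModelResults:
    """Stepwise linear mixed models of log10 siring success.

    ``models`` maps model name ('date', 'pto', 'date+pto') to a dict with a
    coefficient table (estimate, se, t, p per term), the model's Wald F
    over its slope terms with (numerator, denominator) degrees of freedom,
    the F-test p-value, AIC and the random-intercept variance.  ``selected``
    is the AIC-best model.  ``nobs``/``n_genets`` report the sample actually
    modelled (genet-days with positive outcross siring).
    """

    models: dict
    selected: str
    nobs: int
    n_genets: int
    exclude_selfed: bool

    def coef(self, model: str, term: str) -> dict:
        return self.models[model]["coefficients"].loc[term].to_dict()

    def summary(self) -> str:
        lines = [
            "Linear mixed models of log10 siring success "
            f"(n = {self.nobs} genet-days, {self.n_genets} sire genets, "
            f"selfed seeds {'excluded' if self.exclude_selfed else 'included'})",
        ]
        for name, m in self.models.items():
            tag = " *selected*" if name == self.selected else ""
            lines.append(f"model [{name}]  AIC {m['aic']:.2f}  "
                         f"F = {m['F']:.3g} ({m['df_num']:.0f}, "
                         f"{m['df_den']:.1f}), p = {m['F_p']:.3g}{tag}")
            tab = m["coefficients"]
            for term, row in tab.iterrows():
                lines.append(
                    f"    {term:<10} {row['estimate']: .4g} "
                    f"+/- {row['se']:.3g}  t = {row['t']: .2f}  "
                    f"p = {row['p']:.3g}")
        return "\n".join(lines)


class SiringSuccessModel:
    """Mixed-effects regression of siring success on date and PTO.

    Parameters
    ----------
    siring : DataFrame
        Daily siring success per MLL (columns mll_id, day, RS), normally
        from :func:`floralsync.matemetrics.siring_success` with selfed mass
        excluded.
    pto_daily : DataFrame
        Daily genet PTO (mll_id, day, K_day); merged onto siring records by
        (mll_id, day).
    exclude_selfed : bool
        Recorded in the results so the sample definition is explicit; the
        exclusion itself happens upstream when building ``siring``.
    offset : float or None
        If set, model log10(RS + offset) and keep zero-RS genet-days.  By
        default zeros are excluded (sires only), matching the log10
        transform of positive siring mass.
    """

    def __init__(
        self,
        siring: pd.DataFrame,
        pto_daily: pd.DataFrame,
        exclude_selfed: bool = True,
        offset: float | None = None,
    ):
        self.exclude_selfed = exclude_selfed
        self.offset = offset
        tab = siring.merge(pto_daily, on=["mll_id", "day"], how="left")
        tab["K_day"] = tab["K_day"].fillna(0.0)
        if offset is None:
            tab = tab[tab["RS"] > 0].copy()
            tab["log_rs"] = np.log10(tab["RS"])
        else:
            tab["log_rs"] = np.log10(tab["RS"] + offset)
        self.data = tab.reset_index(drop=True)

    def fit(self) -> SiringModelResults:
        d = self.data
        n_genets = d["mll_id"].nunique()
        if n_genets < 5:
            raise ValueError(
                f"only {n_genets} sire genets with positive siring mass; "
                "need >= 5 for the mixed model")
        specs = {
            "date": ["day"],
            "pto": ["K_day"],
            "date+pto": ["day", "K_day"],
        }
        models = {}
        for name, terms in specs.items():
            models[name] = self._fit_one(d, terms)
        selected = min(models, key=lambda k: models[k]["aic"])
        return SiringModelResults(
            models=models,
            selected=selected,
            nobs=len(d),
            n_genets=n_genets,
            exclude_selfed=self.exclude_selfed,
        )

    @staticmethod
    def _fit_one(d: pd.DataFrame, terms: list[str]) -> dict:
        y = d["log_rs"].to_numpy(dtype=float)
        exog = sm.add_constant(d[terms].to_numpy(dtype=float))
        names = ["intercept"] + terms
        groups = d["mll_id"].to_numpy()
        n = len(d)
        g = len(np.unique(groups))
        k = len(terms)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, exog, groups=groups)
                fit = model.fit(reml=False, method=["lbfgs", "powell"])
            re_var = float(np.squeeze(np.asarray(fit.cov_re)))
            cov_fe = np.asarray(fit.cov_params())[:k + 1, :k + 1]
            llf = float(fit.llf)
            boundary = (
                not np.isfinite(llf)
                or re_var <= 1e-8 * max(np.var(y), 1e-12)
                or not np.all(np.isfinite(np.diag(cov_fe)))
            )
        except np.linalg.LinAlgError:
            # singular Hessian at the variance boundary
            fit = None
            boundary = True
        if boundary:
            # random-intercept variance on the 0 boundary: the fitted model
            # *is* the fixed-effects model, so report that fit cleanly
            ols = sm.OLS(y, exog).fit()
            params = np.asarray(ols.params)
            cov_fe = np.asarray(ols.cov_params())
            llf = float(ols.llf)
            re_var = 0.0
            converged = True
        else:
            params = np.asarray(fit.fe_params)
            converged = bool(fit.converged)
        se = np.sqrt(np.diag(cov_fe))
        tvals = params / se
        # between-within (containment) denominator df: slopes vary within
        # genets across days, so df = n - #groups - #slopes
        df_den = max(n - g - k, 1)
        pvals = 2 * sps.t.sf(np.abs(tvals), df_den)
        coefs = pd.DataFrame(
            {"estimate": params, "se": se, "t": tvals, "p": pvals},
            index=names)
        # Wald F over the slope terms, from the fixed-effects covariance
        b = params[1:]
        V = cov_fe[1:, 1:]
        fstat = float(b @ np.linalg.solve(V, b)) / k
        f_p = float(sps.f.sf(fstat, k, df_den))
        # parameters: fixed effects + residual variance + RE variance if kept
        n_params = (k + 1) + 1 + (0 if boundary else 1)
        aic = -2.0 * llf + 2.0 * n_params
        return {
            "coefficients": coefs,
            "F": fstat,
            "df_num": float(k),
            "df_den": float(df_den),
            "F_p": f_p,
            "aic": float(aic),
            "re_variance": re_var,
            "re_boundary": bool(boundary),
            "converged": converged,
        }
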