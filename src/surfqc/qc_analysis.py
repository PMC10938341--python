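"""QC-impact statistical battery: mixed models, partial-correlation maps, thresholding sweeps.

Every model is a linear mixed-effects model with a site random intercept,
fitted by REML (statsmodels MixedLM), degrading to OLS when only one site is
present. The standard fixed-effect set is {quality metric, age, age^2, sex}
for quality-morphometry maps and {diagnosis, age, age^2, sex} for
case-control comparisons; age is mean-centred before squaring.

Effect sizes:

* partial r = t / sqrt(t^2 + df) with df = n - (number of fixed-effect
  parameters), the residual-df convention — the strength of the
  quality-phenotype association adjusted for the covariates;
* Cohen's d for a binary term from its t statistic,
  d = t (n1 + n2) / (sqrt(n1 n2) sqrt(df)).

Sign convention: quality columns are harmonized to a higher-is-worse scale
before fitting (higher-is-better metrics are negated), so a positive partial
r always reads "worse quality, larger phenotype value". Per-map multiple
comparisons use Benjamini-Hochberg FDR across the regions of one
(analysis x phenotype x metric) family.

The module is organised around Model objects whose ``fit()`` returns a
Results object carrying the effects table, diagnostics and a ``summary()``;
the plain functions at the bottom are thin wrappers over them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigError,
    DegenerateInputError,
    DesignError,
    DomainError,
    SchemaError,
    StrategyError,
)
from .fs_io import CohortTable
from .qc_metrics import QCMetricSpec, apply_quality_filter
from .reliability import spearman_rho

logger = logging.getLogger(__name__)

GLOBAL_MEASURES = ("cGMV", "sGMV", "TBV", "WMV", "ventricles", "meanCT")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def partial_r_from_t(t: float, df: float) -> float:
    """Partial correlation implied by a t statistic at df residual degrees of freedom."""
    if df < 1:
        raise DomainError("df must be >= 1")
    if not np.isfinite(t):
        return float("nan")
    return float(t / np.sqrt(t * t + df))


def cohens_d_from_t(t: float, n1: int, n2: int, df: float) -> float:
    """Two-sample Cohen's d from the t statistic of a binary model term."""
    if n1 <= 0 or n2 <= 0:
        raise DomainError("both group sizes must be positive")
    return float(t * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(df)))


def fdr_bh(p_values, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags (q < level).

    NaN p-values are excluded from the family and get NaN q / False flags.
    """
    p = np.asarray(p_values, float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, bool)
    if finite.any():
        _, qv, _, _ = multipletests(p[finite], alpha=level, method="fdr_bh")
        q[finite] = qv
        flags[finite] = qv < level
    return q, flags


# ---------------------------------------------------------------------------
# Mixed-model machinery
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """A fitted-model recipe: response, fixed terms, site random intercept.

    ``metric`` adds the (direction-harmonized) quality column as a fixed
    effect; ``include_diagnosis`` adds the binary diagnosis term;
    ``interaction`` adds quality x diagnosis. ``extra_covariates`` appends
    additional columns (e.g. eTIV) untransformed.
    """

    response: str
    metric: QCMetricSpec | None = None
    include_diagnosis: bool = False
    interaction: bool = False
    extra_covariates: Sequence[str] = ()
    group: str = "site"
    center_age: bool = True


@dataclass
class LMMFit:
    """Fixed-effect estimates from one mixed-model (or degraded OLS) fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: float
    n_used: int
    group_var: float
    resid_var: float
    method: str  # 'mixedlm' or 'ols'
    converged: bool
    singular: bool


def _design_matrix(cohort: CohortTable, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Build the shared fixed-effects design (without response) and the grouping."""
    df = cohort.df
    s = cohort.schema
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    if spec.metric is not None:
        if spec.metric.name not in df.columns:
            raise SchemaError(f"metric column {spec.metric.name!r} not in cohort")
        X["quality"] = spec.metric.worseness(df[spec.metric.name])
    age = df[s.age].astype(float)
    age_c = age - age.mean() if spec.center_age else age
    X["age"] = age_c
    X["age2"] = age_c**2
    if s.sex in df.columns:
        X["sex"] = df[s.sex].astype(float)
    if spec.include_diagnosis:
        if s.diagnosis not in df.columns:
            raise SchemaError("diagnosis column required")
        X["diagnosis"] = df[s.diagnosis].astype(float)
    if spec.interaction:
        if spec.metric is None or not spec.include_diagnosis:
            raise ConfigError("interaction requires both a metric and diagnosis")
        X["quality_x_diagnosis"] = X["quality"] * X["diagnosis"]
    for col in spec.extra_covariates:
        if col not in df.columns:
            raise SchemaError(f"covariate column {col!r} not in cohort")
        X[col] = df[col].astype(float)
    return X, df[s.site]


def _fit_arrays(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray) -> LMMFit:
    """Fit a random-intercept LMM by REML; OLS when a single group level."""
    n, p = X.shape
    names = list(X.columns)
    if np.ptp(y) == 0:
        # degenerate response: everything but the intercept is zero
        params = pd.Series(0.0, index=names)
        params["const"] = float(y[0])
        zero = pd.Series(np.nan, index=names)
        return LMMFit(
            params=params,
            bse=zero,
            tvalues=pd.Series(0.0, index=names),
            pvalues=pd.Series(1.0, index=names),
            df_resid=n - p,
            n_used=n,
            group_var=0.0,
            resid_var=0.0,
            method="degenerate",
            converged=False,
            singular=True,
        )
    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(Xv) < p:
        raise DesignError(f"design matrix is rank deficient (columns {names})")
    df_resid = n - p
    n_groups = len(pd.unique(groups))
    singular = False
    if n_groups < 2:
        logger.warning("single grouping level: degrading to ordinary least squares")
        res = sm.OLS(y, Xv).fit()
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        group_var, resid_var = 0.0, float(res.scale)
        method, converged = "ols", True
    else:
        with warnings.catch_warnings(record=True) as caught, np.errstate(invalid="ignore"):
            warnings.simplefilter("always")
            model = sm.MixedLM(y, Xv, groups=groups)
            res = model.fit(reml=True)
            converged = bool(res.converged)
            singular = any("singular" in str(w.message).lower() for w in caught)
            params = pd.Series(res.fe_params, index=names)
            bse = pd.Series(res.bse_fe, index=names)
            group_var = float(np.atleast_2d(res.cov_re)[0, 0])
            resid_var = float(res.scale)
        if group_var <= 1e-10 * max(resid_var, 1e-30):
            singular = True
        method = "mixedlm"
        if not np.isfinite(bse.to_numpy()).all():
            # boundary fit (site variance ~ 0): standard errors undefined in
            # the mixed parameterisation; the model reduces to OLS there
            ols = sm.OLS(y, Xv).fit()
            params = pd.Series(ols.params, index=names)
            bse = pd.Series(ols.bse, index=names)
            group_var, resid_var = 0.0, float(ols.scale)
            singular, method = True, "ols"
    tvals = params / bse
    pvals = pd.Series(
        2 * stats.t.sf(np.abs(tvals.to_numpy()), df_resid), index=names
    )
    return LMMFit(
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        df_resid=df_resid,
        n_used=n,
        group_var=group_var,
        resid_var=resid_var,
        method=method,
        converged=converged,
        singular=singular,
    )


def fit_lmm(spec: ModelSpec, cohort: CohortTable) -> LMMFit:
    """Fit one random-intercept linear mixed model described by ``spec``."""
    if spec.response not in cohort.df.columns:
        raise SchemaError(f"response column {spec.response!r} not in cohort")
    X, groups = _design_matrix(cohort, spec)
    y = cohort.df[spec.response].astype(float)
    mask = y.notna() & X.notna().all(axis=1)
    if mask.sum() < 10:
        raise DegenerateInputError(f"only {int(mask.sum())} complete rows for {spec.response!r}")
    return _fit_arrays(
        y[mask].to_numpy(), X.loc[mask], groups[mask].to_numpy()
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


def _summary_table(title: str, effects: pd.DataFrame, notes: Sequence[str] = ()) -> str:
    lines = [title, "=" * len(title), effects.to_string(index=False)]
    lines += [f"  {n}" for n in notes]
    return "\n".join(lines)


@dataclass
class EffectResults:
    """Results of a single-response model: per-term estimates and effect sizes."""

    effects: pd.DataFrame
    fit: LMMFit
    response: str

    def summary(self) -> str:
        notes = [
            f"n = {self.fit.n_used}, df = {self.fit.df_resid:g}, "
            f"method = {self.fit.method}, site variance = {self.fit.group_var:.4g}"
        ]
        if self.fit.singular:
            notes.append("note: singular/degenerate random-effect fit")
        return _summary_table(f"Model for {self.response}", self.effects, notes)


class DemographicQualityModel:
    """Demographic predictors of a quality metric.

    Fits metric ~ age + age^2 + sex + diagnosis with a site random intercept
    and reports Cohen's d for the binary terms (sex, diagnosis). Use
    ``extra_covariates=('eTIV',)`` to add intracranial volume.
    """

    def __init__(
        self,
        cohort: CohortTable,
        metric: QCMetricSpec,
        extra_covariates: Sequence[str] = (),
    ):
        self.cohort = cohort
        self.metric = metric
        self.extra_covariates = extra_covariates

    def fit(self) -> EffectResults:
        spec = ModelSpec(
            response=self.metric.name,
            include_diagnosis=True,
            extra_covariates=self.extra_covariates,
        )
        fit = fit_lmm(spec, self.cohort)
        df = self.cohort.df
        s = self.cohort.schema
        rows = []
        for term in fit.params.index:
            if term == "const":
                continue
            d = np.nan
            if term in ("sex", "diagnosis"):
                col = s.sex if term == "sex" else s.diagnosis
                counts = df[col].value_counts()
                if len(counts) == 2:
                    d = cohens_d_from_t(
                        fit.tvalues[term], int(counts.iloc[0]), int(counts.iloc[1]), fit.df_resid
                    )
            rows.append(
                {
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.bse[term],
                    "t": fit.tvalues[term],
                    "p": fit.pvalues[term],
                    "cohens_d": d,
                }
            )
        return EffectResults(effects=pd.DataFrame(rows), fit=fit, response=self.metric.name)


@dataclass
class RegionalQualityResults:
    """Per-region quality-phenotype partial correlations with FDR flags.

    ``effects`` columns: region, phenotype, metric, n_used, estimate, t, df,
    partial_r, p, q, significant. ``thresholded_map()`` keeps only regions
    surviving FDR (the display convention for significance-thresholded brain
    maps); ``unthresholded`` is the full table.
    """

    effects: pd.DataFrame
    skipped: list[str]
    metric: str
    phenotype: str
    fdr_level: float

    @property
    def n_significant(self) -> int:
        return int(self.effects["significant"].sum())

    def thresholded_map(self) -> pd.DataFrame:
        return self.effects.loc[self.effects["significant"]].copy()

    def partial_r_range(self) -> tuple[float, float]:
        sig = self.thresholded_map()["partial_r"]
        if sig.empty:
            return (float("nan"), float("nan"))
        return (float(sig.min()), float(sig.max()))

    def summary(self) -> str:
        lo, hi = self.partial_r_range()
        notes = [
            f"{self.n_significant}/{len(self.effects)} regions pass {self.fdr_level:.0%} FDR",
            f"significant partial r range: {lo:.3f} to {hi:.3f}",
            f"skipped regions: {len(self.skipped)}",
        ]
        head = f"Regional {self.phenotype} ~ {self.metric} associations"
        cols = ["region", "partial_r", "t", "p", "q", "significant", "n_used"]
        return _summary_table(head, self.effects[cols], notes)

    def to_csv(self, path, thresholded: bool = False) -> None:
        (self.thresholded_map() if thresholded else self.effects).to_csv(path, index=False)


class RegionalQualityModel:
    """Quality-morphometry association maps.

    For each region of the phenotype, fits
    value ~ quality + age + age^2 + sex (site random intercept), converts the
    quality t statistic to a partial correlation, and applies BH-FDR across
    the regions. Regions with fewer than ``min_n`` complete rows are skipped
    and reported.
    """

    def __init__(
        self,
        cohort: CohortTable,
        metric: QCMetricSpec,
        phenotype: str = "CT",
        fdr_level: float = 0.05,
        min_n: int = 30,
        regions: Sequence[str] | None = None,
    ):
        self.cohort = cohort
        self.metric = metric
        self.phenotype = phenotype
        self.fdr_level = fdr_level
        self.min_n = min_n
        self.regions = regions

    def fit(self) -> RegionalQualityResults:
        cols = list(self.regions) if self.regions else self.cohort.region_columns(self.phenotype)
        if not cols:
            raise SchemaError(f"no region columns for phenotype {self.phenotype!r}")
        spec = ModelSpec(response=cols[0], metric=self.metric)
        X, groups = _design_matrix(self.cohort, spec)
        base_mask = X.notna().all(axis=1)
        rows, skipped = [], []
        for col in cols:
            y = self.cohort.df[col].astype(float)
            mask = base_mask & y.notna()
            n = int(mask.sum())
            if n < self.min_n:
                skipped.append(col)
                continue
            fit = _fit_arrays(y[mask].to_numpy(), X.loc[mask], groups[mask].to_numpy())
            t = float(fit.tvalues["quality"])
            rows.append(
                {
                    "region": col,
                    "phenotype": self.phenotype,
                    "metric": self.metric.name,
                    "n_used": n,
                    "estimate": float(fit.params["quality"]),
                    "t": t,
                    "df": fit.df_resid,
                    "partial_r": partial_r_from_t(t, fit.df_resid),
                    "p": float(fit.pvalues["quality"]),
                }
            )
        effects = pd.DataFrame(rows)
        if not effects.empty:
            q, flags = fdr_bh(effects["p"].to_numpy(), self.fdr_level)
            effects["q"] = q
            effects["significant"] = flags
        return RegionalQualityResults(
            effects=effects,
            skipped=skipped,
            metric=self.metric.name,
            phenotype=self.phenotype,
            fdr_level=self.fdr_level,
        )


@dataclass
class Strategy:
    """A QC-handling strategy for case-control comparison.

    kind 'none' ignores quality; 'covariate' adds the metric as a fixed
    effect; 'threshold' excludes poor-quality rows at ``cutoff`` (absolute)
    or ``k`` MADs (mode='mad_k'); 'hybrid' thresholds on ``threshold_metric``
    and covaries for ``covariate_metric``.
    """

    kind: Literal["none", "covariate", "threshold", "hybrid"] = "none"
    covariate_metric: QCMetricSpec | None = None
    threshold_metric: QCMetricSpec | None = None
    cutoff: float | None = None
    mode: Literal["absolute", "mad_k"] = "absolute"
    k: float | None = None

    def validate(self) -> None:
        if self.kind in ("covariate", "hybrid") and self.covariate_metric is None:
            raise StrategyError(f"strategy {self.kind!r} needs covariate_metric")
        if self.kind in ("threshold", "hybrid") and self.threshold_metric is None:
            raise StrategyError(f"strategy {self.kind!r} needs threshold_metric")
        if self.kind in ("threshold", "hybrid"):
            if self.mode == "absolute" and self.cutoff is None:
                raise StrategyError("absolute threshold strategy needs cutoff")
            if self.mode == "mad_k" and self.k is None:
                raise StrategyError("mad_k threshold strategy needs k")


@dataclass
class CaseControlResults:
    """Per-region diagnosis effects (Cohen's d) under one QC strategy."""

    effects: pd.DataFrame
    strategy: Strategy
    phenotype: str
    fdr_level: float
    n_cases: int
    n_controls: int
    n_excluded: int

    @property
    def n_significant(self) -> int:
        return int(self.effects["significant"].sum())

    def summary(self) -> str:
        notes = [
            f"strategy = {self.strategy.kind}; cases = {self.n_cases}, "
            f"controls = {self.n_controls}, excluded by QC = {self.n_excluded}",
            f"{self.n_significant}/{len(self.effects)} regions pass {self.fdr_level:.0%} FDR",
            f"mean d = {self.effects['cohens_d'].mean():.4f}",
        ]
        cols = ["region", "cohens_d", "t", "p", "q", "significant", "n_used"]
        return _summary_table(
            f"Case-control {self.phenotype} comparison", self.effects[cols], notes
        )


class CaseControlModel:
    """Case-control morphometry comparison under a QC-handling strategy.

    Per region: value ~ diagnosis + age + age^2 + sex (+ quality covariate if
    the strategy covaries), site random intercept, on the (possibly
    quality-thresholded) cohort. Cohen's d comes from the diagnosis t
    statistic; subthreshold regions keep their d so full maps can be drawn.
    A covariate with zero variance is dropped with a warning (reducing to the
    'none' design) rather than crashing the map.
    """

    def __init__(
        self,
        cohort: CohortTable,
        phenotype: str = "CT",
        strategy: Strategy | None = None,
        fdr_level: float = 0.05,
        min_n: int = 30,
        regions: Sequence[str] | None = None,
    ):
        self.cohort = cohort
        self.phenotype = phenotype
        self.strategy = strategy or Strategy("none")
        self.fdr_level = fdr_level
        self.min_n = min_n
        self.regions = regions

    def _apply_strategy(self) -> tuple[CohortTable, QCMetricSpec | None, int]:
        st = self.strategy
        st.validate()
        cohort, n_excluded = self.cohort, 0
        if st.kind in ("threshold", "hybrid"):
            res = apply_quality_filter(
                cohort, st.threshold_metric, cutoff=st.cutoff, mode=st.mode, k=st.k
            )
            cohort, n_excluded = res.retained, res.report.n_excluded
        covar = st.covariate_metric if st.kind in ("covariate", "hybrid") else None
        dx = cohort.df[cohort.schema.diagnosis]
        if (dx == 1).sum() == 0 or (dx == 0).sum() == 0:
            raise StrategyError("quality filtering emptied a diagnostic group")
        return cohort, covar, n_excluded

    def fit(self) -> CaseControlResults:
        cohort, covar, n_excluded = self._apply_strategy()
        if covar is not None and np.ptp(covar.worseness(cohort.df[covar.name].dropna())) == 0:
            logger.warning(
                "quality covariate %r has zero variance; dropping it", covar.name
            )
            covar = None
        cols = list(self.regions) if self.regions else cohort.region_columns(self.phenotype)
        spec = ModelSpec(response=cols[0], metric=covar, include_diagnosis=True)
        X, groups = _design_matrix(cohort, spec)
        base_mask = X.notna().all(axis=1)
        dx = cohort.df[cohort.schema.diagnosis]
        rows = []
        for col in cols:
            y = cohort.df[col].astype(float)
            mask = base_mask & y.notna()
            n = int(mask.sum())
            if n < self.min_n:
                continue
            n1 = int((dx[mask] == 1).sum())
            n0 = int((dx[mask] == 0).sum())
            fit = _fit_arrays(y[mask].to_numpy(), X.loc[mask], groups[mask].to_numpy())
            t = float(fit.tvalues["diagnosis"])
            rows.append(
                {
                    "region": col,
                    "phenotype": self.phenotype,
                    "n_used": n,
                    "n_cases": n1,
                    "n_controls": n0,
                    "estimate": float(fit.params["diagnosis"]),
                    "t": t,
                    "df": fit.df_resid,
                    "cohens_d": cohens_d_from_t(t, n1, n0, fit.df_resid),
                    "p": float(fit.pvalues["diagnosis"]),
                }
            )
        effects = pd.DataFrame(rows)
        if not effects.empty:
            q, flags = fdr_bh(effects["p"].to_numpy(), self.fdr_level)
            effects["q"] = q
            effects["significant"] = flags
        dxall = cohort.df[cohort.schema.diagnosis]
        return CaseControlResults(
            effects=effects,
            strategy=self.strategy,
            phenotype=self.phenotype,
            fdr_level=self.fdr_level,
            n_cases=int((dxall == 1).sum()),
            n_controls=int((dxall == 0).sum()),
            n_excluded=n_excluded,
        )


class InteractionModel:
    """Diagnosis x quality interaction per region.

    Adds the quality x diagnosis product to the case-control design and
    reports the interaction term's estimate, t, p and FDR q per region. A
    positive interaction (on the higher-is-worse quality scale) means the
    quality-phenotype slope is steeper in cases than controls.
    """

    def __init__(
        self,
        cohort: CohortTable,
        metric: QCMetricSpec,
        phenotype: str = "CT",
        fdr_level: float = 0.05,
        min_n: int = 30,
        regions: Sequence[str] | None = None,
    ):
        self.cohort = cohort
        self.metric = metric
        self.phenotype = phenotype
        self.fdr_level = fdr_level
        self.min_n = min_n
        self.regions = regions

    def fit(self) -> pd.DataFrame:
        if np.ptp(self.metric.worseness(self.cohort.df[self.metric.name].dropna())) == 0:
            raise DesignError(f"metric column {self.metric.name!r} is constant")
        cols = list(self.regions) if self.regions else self.cohort.region_columns(self.phenotype)
        spec = ModelSpec(
            response=cols[0], metric=self.metric, include_diagnosis=True, interaction=True
        )
        X, groups = _design_matrix(self.cohort, spec)
        base_mask = X.notna().all(axis=1)
        rows = []
        for col in cols:
            y = self.cohort.df[col].astype(float)
            mask = base_mask & y.notna()
            if int(mask.sum()) < self.min_n:
                continue
            fit = _fit_arrays(y[mask].to_numpy(), X.loc[mask], groups[mask].to_numpy())
            term = "quality_x_diagnosis"
            rows.append(
                {
                    "region": col,
                    "phenotype": self.phenotype,
                    "metric": self.metric.name,
                    "n_used": fit.n_used,
                    "estimate": float(fit.params[term]),
                    "se": float(fit.bse[term]),
                    "t": float(fit.tvalues[term]),
                    "df": fit.df_resid,
                    "p": float(fit.pvalues[term]),
                }
            )
        effects = pd.DataFrame(rows)
        if not effects.empty:
            q, flags = fdr_bh(effects["p"].to_numpy(), self.fdr_level)
            effects["q"] = q
            effects["significant"] = flags
        return effects


@dataclass
class SweepResults:
    """Attenuation curves from re-running the regional maps at tightening cutoffs."""

    points: pd.DataFrame  # cutoff, n_retained, n_significant, mean_abs_partial_r, flagged
    per_cutoff: dict[float, RegionalQualityResults]

    def summary(self) -> str:
        return _summary_table("Quality threshold sweep", self.points)


class ThresholdSweep:
    """Re-run the regional quality map at cutoffs of increasing stringency.

    ``cutoffs`` are absolute metric cutoffs ordered loose -> stringent (e.g.
    FSQC 3, 2.5, 2, 1.5) or MAD multiples when ``mode='mad_k'`` (Euler k =
    3 ... 0.5). A sweep point excluding more than 95% of rows is flagged and
    not fitted.
    """

    def __init__(
        self,
        cohort: CohortTable,
        metric: QCMetricSpec,
        cutoffs: Sequence[float],
        phenotype: str = "CT",
        mode: Literal["absolute", "mad_k"] = "absolute",
        fdr_level: float = 0.05,
        min_n: int = 30,
        regions: Sequence[str] | None = None,
    ):
        self.cohort = cohort
        self.metric = metric
        self.cutoffs = list(cutoffs)
        self.phenotype = phenotype
        self.mode = mode
        self.fdr_level = fdr_level
        self.min_n = min_n
        self.regions = regions

    def fit(self) -> SweepResults:
        rows, per_cutoff = [], {}
        for cut in self.cutoffs:
            kwargs = {"cutoff": cut} if self.mode == "absolute" else {"k": cut}
            filt = apply_quality_filter(self.cohort, self.metric, mode=self.mode, **kwargs)
            n_ret = filt.report.n_retained
            if n_ret < 0.05 * filt.report.n_input:
                rows.append(
                    {
                        "cutoff": cut,
                        "n_retained": n_ret,
                        "n_significant": np.nan,
                        "mean_abs_partial_r": np.nan,
                        "flagged": True,
                    }
                )
                continue
            res = RegionalQualityModel(
                filt.retained,
                self.metric,
                self.phenotype,
                self.fdr_level,
                self.min_n,
                self.regions,
            ).fit()
            per_cutoff[cut] = res
            rows.append(
                {
                    "cutoff": cut,
                    "n_retained": n_ret,
                    "n_significant": res.n_significant,
                    "mean_abs_partial_r": float(res.effects["partial_r"].abs().mean()),
                    "flagged": False,
                }
            )
        return SweepResults(points=pd.DataFrame(rows), per_cutoff=per_cutoff)


# ---------------------------------------------------------------------------
# Cross-metric and global correlations
# ---------------------------------------------------------------------------


def metric_correlation_matrix(
    cohort: CohortTable, metrics: Sequence[QCMetricSpec]
) -> pd.DataFrame:
    """Spearman correlations between QC metrics on pairwise-complete rows.

    Signs are reported raw; the attached ``direction`` row lets callers
    display absolute values for higher-is-better metrics when comparing
    magnitudes across metrics.
    """
    if len(metrics) < 2:
        raise ConfigError("need >= 2 metrics")
    names = [m.name for m in metrics]
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(metrics):
        for b in metrics[i + 1 :]:
            pair = cohort.df[[a.name, b.name]].dropna()
            try:
                rho, _ = spearman_rho(pair[a.name], pair[b.name])
            except DegenerateInputError:
                rho = np.nan
            out.loc[a.name, b.name] = out.loc[b.name, a.name] = rho
    out.attrs["direction"] = {m.name: m.direction for m in metrics}
    return out


def global_quality_correlations(
    cohort: CohortTable,
    metric: QCMetricSpec,
    global_columns: Sequence[str] = GLOBAL_MEASURES,
) -> pd.DataFrame:
    """Spearman rho between a quality metric and each global brain measure.

    Significance at the Bonferroni level 0.05 / (number of comparisons);
    missing columns are listed as skipped rather than raised.
    """
    present = [c for c in global_columns if c in cohort.df.columns]
    skipped = [c for c in global_columns if c not in cohort.df.columns]
    level = 0.05 / max(len(present), 1)
    rows = []
    worse = metric.worseness(cohort.df[metric.name])
    for col in present:
        pair = pd.DataFrame({"q": worse, "g": cohort.df[col]}).dropna()
        rho, p = spearman_rho(pair["q"], pair["g"])
        rows.append(
            {"measure": col, "rho": rho, "p": p, "significant": p < level, "n": len(pair)}
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_level"] = level
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def demographic_quality_model(
    cohort: CohortTable, metric: QCMetricSpec, extra_covariates: Sequence[str] = ()
) -> EffectResults:
    return DemographicQualityModel(cohort, metric, extra_covariates).fit()


def regional_quality_associations(
    cohort: CohortTable, metric: QCMetricSpec, phenotype: str = "CT", **kwargs
) -> RegionalQualityResults:
    return RegionalQualityModel(cohort, metric, phenotype, **kwargs).fit()


def threshold_sweep(
    cohort: CohortTable,
    metric: QCMetricSpec,
    cutoffs: Sequence[float],
    phenotype: str = "CT",
    **kwargs,
) -> SweepResults:
    return ThresholdSweep(cohort, metric, cutoffs, phenotype, **kwargs).fit()


def case_control_comparison(
    cohort: CohortTable, phenotype: str = "CT", strategy: Strategy | None = None, **kwargs
) -> CaseControlResults:
    return CaseControlModel(cohort, phenotype, strategy, **kwargs).fit()


def quality_diagnosis_interaction(
    cohort: CohortTable, metric: QCMetricSpec, phenotype: str = "CT", **kwargs
) -> pd.DataFrame:
    return InteractionModel(cohort, metric, phenotype, **kwargs).fit()
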