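"""Group-level comparison of phenological trends with linear mixed models.

The question: do species sharing a wintering range (North Africa, Sahel,
Tropical Africa) shift their passage dates at the same rate?  Annual
metric values from many species are pooled in a linear mixed model with
wintering group, year, and their interaction as fixed effects and a
random intercept per species (species differ widely in mean passage date;
the random intercept soaks that up).  The marginal slope of a group is
the model-implied yearly change for that group: the year coefficient plus
that group's interaction coefficient, with its standard error from the
fixed-effects covariance.  Pairwise slope contrasts are Wald z-tests, and
letter groupings over a sweep of significance levels summarize which
groups separate (see :mod:`phenopass.cld`).

p-values for marginal slopes and contrasts use the Wald z reference
distribution; with the study-scale numbers of species and years this is a
good approximation and avoids contested mixed-model degrees-of-freedom
corrections.  Year is centred (default at the first study year, 2002) for
numerical conditioning only — slopes are unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm

from .cld import LetterGrouping, PairBracket, alpha_sweep_grouping
from .trends import METRIC_COLUMNS, fit_annual_trend

__all__ = [
    "LmmFit",
    "GroupComparison",
    "SexAnalysis",
    "fit_group_lmm",
    "marginal_slopes",
    "pairwise_slope_tests",
    "compare_groups",
    "sex_group_analysis",
    "GroupTrendComparator",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_YEAR_CENTER = 2002
#: sweep used to bracket non-significant pairwise contrasts
DEFAULT_ALPHA_GRID = (0.01, 0.05, 0.06, 0.10, 0.20, 0.25, 0.50)


class ConvergenceError(RuntimeError):
    pass


def _fit_mixedlm(model: sm.MixedLM, reml: bool):
    """Fit with a cascade of optimizers; variance components near zero can
    make a single method fail on an exactly singular inner solve."""
    last_exc: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=[method], maxiter=2000)
            if res.converged:
                return res
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise ConvergenceError(
        f"mixed model did not converge with any optimizer"
        f"{f' (last error: {last_exc})' if last_exc else ''}"
    )


@dataclass
class LmmFit:
    """Random-intercept mixed-model fit for one response metric."""

    response: str
    group_levels: list[str]
    reference: str
    year_center: float
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    tvalues: pd.Series
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_species: int
    reml: bool
    group_label: str = "wintering_group"

    def _slope_contrast(self, group: str) -> np.ndarray:
        if group not in self.group_levels:
            raise KeyError(f"group {group!r} not in fitted levels {self.group_levels}")
        c = pd.Series(0.0, index=self.fe_params.index)
        c["year"] = 1.0
        inter = f"{self.group_label}[{group}]:year"
        if inter in c.index:
            c[inter] = 1.0
        return c.to_numpy()


def _design_matrix(
    df: pd.DataFrame, group_col: str, year_col: str, year_center: float,
    levels: list[str],
) -> pd.DataFrame:
    yc = df[year_col].to_numpy(dtype=float) - year_center
    X = {"Intercept": np.ones(len(df))}
    for g in levels[1:]:
        X[f"{group_col}[{g}]"] = (df[group_col] == g).to_numpy(dtype=float)
    X["year"] = yc
    for g in levels[1:]:
        X[f"{group_col}[{g}]:year"] = X[f"{group_col}[{g}]"] * yc
    return pd.DataFrame(X, index=df.index)


def fit_group_lmm(
    data: pd.DataFrame,
    response: str,
    group_col: str = "wintering_group",
    species_col: str = "species",
    year_col: str = "year",
    reference: str | None = None,
    year_center: float = DEFAULT_YEAR_CENTER,
    reml: bool = True,
) -> LmmFit:
    """REML fit of ``response ~ group * year + (1 | species)``.

    ``data`` holds one row per species-year with a defined response value
    (NaN rows are dropped here).  With a single group level the model
    reduces to intercept + year.  Raises :class:`ConvergenceError` when
    the optimizer fails and ``ValueError`` (naming the group) for singular
    designs — a group contributing fewer than two species-years, or fewer
    than two distinct species when groups are being compared.
    """
    df = data.dropna(subset=[response]).copy()
    if df.empty:
        raise ValueError(f"no usable rows for response {response!r}")
    levels = sorted(df[group_col].astype(str).unique())
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not among groups {levels}")
        levels = [reference] + [g for g in levels if g != reference]
    if df[year_col].nunique() < 2:
        raise ValueError("need at least two distinct years")
    for g in levels:
        sub = df.loc[df[group_col] == g]
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than two species-years")
        if len(levels) > 1 and sub[species_col].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than two species")

    X = _design_matrix(df, group_col, year_col, year_center, levels)
    model = sm.MixedLM(df[response].to_numpy(dtype=float), X,
                       groups=df[species_col].to_numpy())
    res = _fit_mixedlm(model, reml)
    fe = res.fe_params
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fe), : len(fe)],
        index=fe.index, columns=fe.index,
    )
    return LmmFit(
        response=response,
        group_levels=levels,
        reference=levels[0],
        year_center=year_center,
        fe_params=fe,
        fe_cov=cov,
        tvalues=res.tvalues[fe.index],
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
        residual_var=float(res.scale),
        n_obs=len(df),
        n_species=int(df[species_col].nunique()),
        reml=reml,
        group_label=group_col,
    )


def _wald(estimate: float, se: float) -> tuple[float, float]:
    if se == 0:
        return (np.inf if estimate != 0 else 0.0), (0.0 if estimate != 0 else 1.0)
    z = estimate / se
    return z, 2.0 * stats.norm.sf(abs(z))


def marginal_slopes(fit: LmmFit) -> pd.DataFrame:
    """Model-implied yearly trend per group (days/year), SE, Wald z and p.

    For the reference group the slope is the year coefficient itself; for
    the others it is year + that group's interaction coefficient, with
    variance ``c' Sigma c`` from the fixed-effects covariance.
    """
    rows = []
    for g in fit.group_levels:
        c = fit._slope_contrast(g)
        slope = float(c @ fit.fe_params.to_numpy())
        se = float(np.sqrt(c @ fit.fe_cov.to_numpy() @ c))
        z, p = _wald(slope, se)
        rows.append({"group": g, "slope": slope, "se": se, "z": z, "p_value": p})
    return pd.DataFrame(rows)


def pairwise_slope_tests(fit: LmmFit) -> pd.DataFrame:
    """Wald z-tests of all pairwise differences between group trend slopes."""
    if len(fit.group_levels) < 2:
        raise ValueError("need at least two groups for pairwise contrasts")
    rows = []
    for a, b in combinations(fit.group_levels, 2):
        c = fit._slope_contrast(a) - fit._slope_contrast(b)
        diff = float(c @ fit.fe_params.to_numpy())
        se = float(np.sqrt(c @ fit.fe_cov.to_numpy() @ c))
        z, p = _wald(diff, se)
        rows.append({"group_a": a, "group_b": b, "estimate": diff,
                     "se": se, "z": z, "p_value": p})
    return pd.DataFrame(rows)


def overall_year_trend(
    data: pd.DataFrame,
    response: str,
    **kwargs,
) -> tuple[float, float]:
    """Year coefficient and its t-value from the additive (no-interaction) model.

    This is the across-species common trend: response ~ group + year with
    the species random intercept.  With one group the group term drops.
    """
    df = data.dropna(subset=[response]).copy()
    group_col = kwargs.get("group_col", "wintering_group")
    year_col = kwargs.get("year_col", "year")
    species_col = kwargs.get("species_col", "species")
    year_center = kwargs.get("year_center", DEFAULT_YEAR_CENTER)
    reml = kwargs.get("reml", True)
    levels = sorted(df[group_col].astype(str).unique())
    X = _design_matrix(df, group_col, year_col, year_center, levels)
    X = X[[c for c in X.columns if not c.endswith(":year")]]
    model = sm.MixedLM(df[response].to_numpy(dtype=float), X,
                       groups=df[species_col].to_numpy())
    res = _fit_mixedlm(model, reml)
    return float(res.fe_params["year"]), float(res.tvalues["year"])


@dataclass
class GroupComparison:
    """Bundle of everything the group-level analysis produces for one metric."""

    metric: str
    fit: LmmFit
    slopes: pd.DataFrame
    contrasts: pd.DataFrame
    groupings: list[LetterGrouping]
    brackets: list[PairBracket]
    overall_year_slope: float
    overall_year_t: float
    dropped_groups: tuple[str, ...] = ()


def default_drop_groups(metric: str) -> tuple[str, ...]:
    """Start and window comparisons drop the North Africa group: its
    passage typically begins before the station opens, so starts (and
    hence windows) are truncated and undefined for most of its species."""
    return ("North Africa",) if metric in ("start", "window") else ()


def _metrics_long(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    col = METRIC_COLUMNS[metric]
    df = metrics.loc[~metrics["excluded"]].copy()
    df["value"] = pd.to_numeric(df[col], errors="coerce")
    return df.dropna(subset=["value"])


def compare_groups(
    metrics: pd.DataFrame,
    metric: str = "peak",
    drop_groups: tuple[str, ...] | str = "auto",
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    reference: str | None = None,
    year_center: float = DEFAULT_YEAR_CENTER,
    reml: bool = True,
) -> GroupComparison:
    """Full group-level comparison of one metric's trends.

    ``metrics`` is the tidy phenology table joined with a
    ``wintering_group`` column.  ``drop_groups='auto'`` applies the
    truncation-driven rule of :func:`default_drop_groups`.
    """
    if drop_groups == "auto":
        drop_groups = default_drop_groups(metric)
    df = _metrics_long(metrics, metric)
    df = df.loc[~df["wintering_group"].isin(drop_groups)]
    fit = fit_group_lmm(df, "value", reference=reference,
                        year_center=year_center, reml=reml)
    fit.response = metric
    slopes = marginal_slopes(fit)
    contrasts = pairwise_slope_tests(fit)
    pmap = {(r["group_a"], r["group_b"]): r["p_value"]
            for _, r in contrasts.iterrows()}
    groupings, brackets = alpha_sweep_grouping(fit.group_levels, pmap, list(alpha_grid))
    oy_slope, oy_t = overall_year_trend(df, "value", year_center=year_center, reml=reml)
    return GroupComparison(
        metric=metric, fit=fit, slopes=slopes, contrasts=contrasts,
        groupings=groupings, brackets=brackets,
        overall_year_slope=oy_slope, overall_year_t=oy_t,
        dropped_groups=tuple(drop_groups),
    )


@dataclass
class SexAnalysis:
    """Sex-specific trends for sexually dimorphic species.

    ``species_trends`` is the per-species per-sex OLS table of peak-date
    trends; ``by_sex`` compares wintering groups within each sex;
    ``within_group`` compares the sexes within each wintering group.
    """

    species_trends: pd.DataFrame
    by_sex: dict[str, GroupComparison] = field(default_factory=dict)
    within_group: dict[str, GroupComparison] = field(default_factory=dict)


def sex_group_analysis(
    metrics_by_sex: pd.DataFrame,
    species_meta: pd.DataFrame,
    metric: str = "peak",
    groups: tuple[str, ...] = ("Sahel", "Tropical"),
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    year_center: float = DEFAULT_YEAR_CENTER,
    reml: bool = True,
) -> SexAnalysis:
    """Sex-specific trend analysis restricted to dimorphic species.

    ``metrics_by_sex`` is a phenology table computed separately per sex
    (columns of the tidy metrics table plus ``sex``).  Between-group
    comparisons use only the given groups (by default Sahel vs Tropical —
    North Africa contributes a single dimorphic species, which would make
    the species random effect singular); the within-group comparison
    contrasts males and females via a sex × year interaction.
    """
    dimorphic = set(species_meta.loc[species_meta["dimorphic"], "species"])
    df = metrics_by_sex.loc[
        metrics_by_sex["species"].isin(dimorphic)
        & metrics_by_sex["sex"].isin(["male", "female"])
    ].copy()
    if "wintering_group" not in df.columns:
        df = df.merge(species_meta[["species", "wintering_group"]], on="species")

    long = _metrics_long(df, metric)

    rows = []
    for (sp, sex), sub in long.groupby(["species", "sex"], sort=True):
        est = fit_annual_trend(sub["year"].to_numpy(), sub["value"].to_numpy(),
                               species=sp, metric=metric)
        rows.append({"species": sp, "sex": sex, "slope": est.slope,
                     "se": est.se, "p_value": est.p_value,
                     "n_years": est.n_years, "defined": est.defined})
    species_trends = pd.DataFrame(rows).merge(
        species_meta[["species", "wintering_group"]], on="species", how="left"
    )

    result = SexAnalysis(species_trends=species_trends)

    between = long.loc[long["wintering_group"].isin(groups)]
    for sex in ("male", "female"):
        sub = between.loc[between["sex"] == sex]
        fit = fit_group_lmm(sub, "value", year_center=year_center, reml=reml)
        fit.response = f"{metric} ({sex})"
        slopes = marginal_slopes(fit)
        contrasts = pairwise_slope_tests(fit)
        pmap = {(r["group_a"], r["group_b"]): r["p_value"]
                for _, r in contrasts.iterrows()}
        groupings, brackets = alpha_sweep_grouping(
            fit.group_levels, pmap, list(alpha_grid))
        oy_slope, oy_t = overall_year_trend(sub, "value",
                                            year_center=year_center, reml=reml)
        result.by_sex[sex] = GroupComparison(
            metric=metric, fit=fit, slopes=slopes, contrasts=contrasts,
            groupings=groupings, brackets=brackets,
            overall_year_slope=oy_slope, overall_year_t=oy_t,
        )

    for grp in groups:
        sub = between.loc[between["wintering_group"] == grp]
        fit = fit_group_lmm(sub, "value", group_col="sex",
                            year_center=year_center, reml=reml)
        fit.response = f"{metric} ({grp})"
        slopes = marginal_slopes(fit)
        contrasts = pairwise_slope_tests(fit)
        pmap = {(r["group_a"], r["group_b"]): r["p_value"]
                for _, r in contrasts.iterrows()}
        groupings, brackets = alpha_sweep_grouping(
            fit.group_levels, pmap, list(alpha_grid))
        oy_slope, oy_t = overall_year_trend(
            sub, "value", group_col="sex", year_center=year_center, reml=reml)
        result.within_group[grp] = GroupComparison(
            metric=metric, fit=fit, slopes=slopes, contrasts=contrasts,
            groupings=groupings, brackets=brackets,
            overall_year_slope=oy_slope, overall_year_t=oy_t,
        )
    return result


class GroupTrendComparator(BaseEstimator):
    """Mixed-model comparison of group-level phenological trends.

    Parameters mirror :func:`compare_groups`; ``fit`` takes the tidy
    phenology metrics table already joined with ``wintering_group``.

    Attributes
    ----------
    comparison_ : GroupComparison
        The fitted bundle (model fit, marginal slopes, contrasts, letter
        groupings, alpha brackets, overall year trend).
    marginal_slopes_ : DataFrame
        Per-group slope ± SE with Wald p.
    contrasts_ : DataFrame
        Pairwise slope differences with Wald p.
    """

    def __init__(
        self,
        metric: str = "peak",
        drop_groups: tuple[str, ...] | str = "auto",
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        reference: str | None = None,
        year_center: float = DEFAULT_YEAR_CENTER,
        reml: bool = True,
    ):
        self.metric = metric
        self.drop_groups = drop_groups
        self.alpha_grid = alpha_grid
        self.reference = reference
        self.year_center = year_center
        self.reml = reml

    def fit(self, X: pd.DataFrame, y=None):
        self.comparison_ = compare_groups(
            X,
            metric=self.metric,
            drop_groups=self.drop_groups,
            alpha_grid=tuple(self.alpha_grid),
            reference=self.reference,
            year_center=self.year_center,
            reml=self.reml,
        )
        self.marginal_slopes_ = self.comparison_.slopes
        self.contrasts_ = self.comparison_.contrasts
        return self
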