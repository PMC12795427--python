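"""Longitudinal and correlation statistics for the retina-behaviour study.

* Mixed-intercepts (random intercept per animal) models of layer thickness
  or vessel density against group (genotype x sex) and week, with pairwise
  contrasts on the estimated marginal means.  Week is treated as
  categorical by default; no multiplicity correction is applied (matching
  an exploratory design), Benjamini-Hochberg is available but off.
* Probe-day statistics: unpaired t-tests (pooled variance by default),
  one-sample chance-level tests (25% target-quadrant abidance, 1.5
  crossings are the conventional chance constants), Cohen's d.
* Pearson correlation with the two-sided t-based p-value, the paired
  simple regression (slope, intercept, R^2 = r^2, MSE), and the analytic
  power of the correlation test via the Fisher z approximation.
* Retina-behaviour orchestration: eyes averaged per mouse first, one
  datapoint per mouse, correlations per group (tg, tg-f, tg-m, ntg,
  ntg-f, ntg-m) and per parameter pair.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelFit",
    "TTestResult",
    "CorrResult",
    "fit_mixed_intercepts",
    "pairwise_emmeans",
    "day5_tests",
    "chance_level_test",
    "cohens_d",
    "pearson_corr",
    "pearson_power",
    "correlate_retina_behavior",
    "benjamini_hochberg",
]

GROUP_ORDER = ("tg:m", "tg:f", "ntg:m", "ntg:f")


class DegenerateDataError(ValueError):
    """The data do not support the requested statistic."""


# ---------------------------------------------------------------------------
# mixed-intercepts model


@dataclass
class ModelFit:
    """Fitted mixed-intercepts model in cell-mean form.

    The fixed-effect design is the full group x week cell-mean
    parameterisation (one column per cell), which makes estimated marginal
    means and their contrasts direct linear forms of the coefficients.
    """

    params: pd.Series  # one coefficient per (group, week) cell
    cov_params: pd.DataFrame
    group_levels: list[str]
    week_levels: list[int]
    random_intercept_var: float
    residual_var: float
    df_resid: float
    n_obs: int
    converged: bool
    method: str  # "mixedlm", "ols", or "exact"

    def cell_name(self, group: str, week: int) -> str:
        return f"{group}@{week}"

    def emmean(self, group: str, week: int) -> float:
        return float(self.params[self.cell_name(group, week)])


def _prepare_long(data: pd.DataFrame, parameter: str | None) -> pd.DataFrame:
    df = data.copy()
    if parameter is not None and "layer" in df.columns:
        df = df[df["layer"] == parameter]
    if "value" not in df.columns:
        for cand in ("thickness_um", "density_pct"):
            if cand in df.columns:
                df = df.rename(columns={cand: "value"})
                break
    if "group" not in df.columns:
        df["group"] = df["genotype"].astype(str) + ":" + df["sex"].astype(str)
    if "animal" not in df.columns:
        df = df.rename(columns={"animal_id": "animal"})
    return df.dropna(subset=["value"]).reset_index(drop=True)


def fit_mixed_intercepts(
    data: pd.DataFrame,
    parameter: str | None = None,
    reml: bool = True,
    allow_degenerate: bool = False,
) -> ModelFit:
    """Fit a random-intercept-per-animal model with group x week cell means.

    ``data`` is long format with columns ``animal`` (or ``animal_id``),
    ``genotype``, ``sex`` (or a pre-built ``group``), ``week`` and ``value``
    (or ``thickness_um`` / ``density_pct``); ``parameter`` filters the
    ``layer`` column when present.  Repeated eyes enter as repeated
    measures within mouse.

    With a single timepoint the random intercept is unidentifiable; this is
    an error unless ``allow_degenerate=True``, in which case an ordinary
    least-squares fit (random variance 0) is returned — in the balanced
    two-group case its contrasts coincide with the pooled t-test.
    """
    df = _prepare_long(data, parameter)
    weeks = sorted(df["week"].unique())
    groups = [g for g in GROUP_ORDER if g in set(df["group"])]
    groups += [g for g in sorted(set(df["group"])) if g not in groups]
    if df["animal"].nunique() < 2:
        raise DegenerateDataError("need at least 2 animals")
    if len(weeks) < 2 and not allow_degenerate:
        raise DegenerateDataError(
            "a single timepoint cannot identify the random intercept; "
            "pass allow_degenerate=True for a fixed-effects fit"
        )

    cells = [f"{g}@{w}" for g in groups for w in weeks]
    X = pd.DataFrame(0.0, index=df.index, columns=cells)
    key = df["group"].astype(str) + "@" + df["week"].astype(str)
    for c in cells:
        X.loc[key == c, c] = 1.0
    present = [c for c in cells if X[c].sum() > 0]
    X = X[present]
    y = df["value"].to_numpy(dtype=float)

    # exact path: zero within-cell variance (noise-free synthetic data)
    cell_means = df.groupby(key.rename("cell"))["value"].agg(["mean", "var", "count"])
    within_var = np.nansum(cell_means["var"].fillna(0.0) * (cell_means["count"] - 1))
    if within_var < 1e-16:
        params = pd.Series(
            {c: cell_means.loc[c, "mean"] for c in present}, dtype=float
        )
        cov = pd.DataFrame(0.0, index=present, columns=present)
        return ModelFit(
            params=params,
            cov_params=cov,
            group_levels=groups,
            week_levels=weeks,
            random_intercept_var=0.0,
            residual_var=0.0,
            df_resid=float(len(df) - len(present)),
            n_obs=len(df),
            converged=True,
            method="exact",
        )

    one_per_animal = df.groupby("animal").size().max() == 1
    if len(weeks) < 2 or one_per_animal:
        ols = sm.OLS(y, X.to_numpy()).fit()
        params = pd.Series(ols.params, index=present)
        cov = pd.DataFrame(ols.cov_params(), index=present, columns=present)
        return ModelFit(
            params=params,
            cov_params=cov,
            group_levels=groups,
            week_levels=weeks,
            random_intercept_var=0.0,
            residual_var=float(ols.scale),
            df_resid=float(ols.df_resid),
            n_obs=len(df),
            converged=True,
            method="ols",
        )

    model = MixedLM(y, X.to_numpy(), groups=df["animal"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=500)
    params = pd.Series(res.fe_params, index=present)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(present), : len(present)],
        index=present,
        columns=present,
    )
    n_animals = df["animal"].nunique()
    return ModelFit(
        params=params,
        cov_params=cov,
        group_levels=groups,
        week_levels=weeks,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        df_resid=float(len(df) - n_animals - len(present) + 1),
        n_obs=len(df),
        converged=bool(res.converged),
        method="mixedlm",
    )


Contrast = tuple[tuple[str, int], tuple[str, int]]


def pairwise_emmeans(
    fit: ModelFit,
    contrasts: list[Contrast] | None = None,
) -> pd.DataFrame:
    """Pairwise comparisons of estimated marginal means.

    ``contrasts`` is a list of ``((group_a, week_a), (group_b, week_b))``
    cell pairs; by default all between-group pairs within each week plus
    first-to-last week within each group.  p-values come from the t
    approximation on the contrast SE with residual-based degrees of
    freedom; no multiplicity correction is applied.
    """
    if not fit.converged:
        raise DegenerateDataError("model did not converge; contrasts suppressed")
    if contrasts is None:
        contrasts = []
        for w in fit.week_levels:
            for ga, gb in itertools.combinations(fit.group_levels, 2):
                contrasts.append(((ga, w), (gb, w)))
        if len(fit.week_levels) >= 2:
            w0, w1 = fit.week_levels[0], fit.week_levels[-1]
            for g in fit.group_levels:
                contrasts.append(((g, w1), (g, w0)))

    rows = []
    for (ga, wa), (gb, wb) in contrasts:
        ca, cb = fit.cell_name(ga, wa), fit.cell_name(gb, wb)
        for c in (ca, cb):
            if c not in fit.params.index:
                raise DegenerateDataError(f"contrast references empty cell {c}")
        est = fit.params[ca] - fit.params[cb]
        var = (
            fit.cov_params.loc[ca, ca]
            + fit.cov_params.loc[cb, cb]
            - 2.0 * fit.cov_params.loc[ca, cb]
        )
        se = math.sqrt(max(var, 0.0))
        if se == 0.0:
            t = 0.0 if est == 0 else math.copysign(math.inf, est)
            p = 1.0 if est == 0 else 0.0
        else:
            t = est / se
            p = 2.0 * sps.t.sf(abs(t), fit.df_resid)
        rows.append(
            {
                "contrast": f"{ca} - {cb}",
                "estimate": float(est),
                "se": se,
                "t": float(t),
                "p": float(p),
                "df": fit.df_resid,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probe-day tests


@dataclass
class TTestResult:
    label: str
    t: float
    p: float
    df: float
    estimate: float  # mean difference (two-sample) or mean - chance
    degenerate: bool = False


def day5_tests(
    metrics: pd.DataFrame,
    parameter: str,
    group_col: str = "group",
    welch: bool = False,
) -> list[TTestResult]:
    """Unpaired two-sided t-tests of ``parameter`` between every pair of
    groups (pooled variance unless ``welch``)."""
    out = []
    groups = list(dict.fromkeys(metrics[group_col]))
    for ga, gb in itertools.combinations(groups, 2):
        a = metrics.loc[metrics[group_col] == ga, parameter].dropna().to_numpy()
        b = metrics.loc[metrics[group_col] == gb, parameter].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise DegenerateDataError("each group needs n >= 2")
        degenerate = False
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
            degenerate = True
            df = len(a) + len(b) - 2
        else:
            t, p = sps.ttest_ind(a, b, equal_var=not welch)
            if welch:
                df = sps.ttest_ind(a, b, equal_var=False).df
            else:
                df = len(a) + len(b) - 2
        out.append(
            TTestResult(
                label=f"{ga} vs {gb}",
                t=float(t),
                p=float(p),
                df=float(df),
                estimate=float(a.mean() - b.mean()),
                degenerate=degenerate,
            )
        )
    return out


def chance_level_test(values, chance: float) -> TTestResult:
    """Two-sided one-sample t-test of the mean against a chance constant
    (25% for target-quadrant abidance, 1.5 for zone crossings)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise DegenerateDataError("chance-level test needs n >= 2")
    if v.std(ddof=1) == 0:
        return TTestResult(
            label=f"mean vs {chance}",
            t=0.0 if v.mean() == chance else math.copysign(math.inf, v.mean() - chance),
            p=1.0 if v.mean() == chance else 0.0,
            df=float(len(v) - 1),
            estimate=float(v.mean() - chance),
            degenerate=True,
        )
    t, p = sps.ttest_1samp(v, chance)
    return TTestResult(
        label=f"mean vs {chance}",
        t=float(t),
        p=float(p),
        df=float(len(v) - 1),
        estimate=float(v.mean() - chance),
    )


def cohens_d(group_a, group_b) -> float:
    """Cohen's d, ``(mean_a - mean_b) / pooled SD`` with (n-1) weights;
    positive iff group a has the larger mean."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("Cohen's d needs n >= 2 per group")
    pooled = math.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        raise DegenerateDataError("zero pooled SD; d undefined")
    return float((a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# correlation / regression / power


@dataclass
class CorrResult:
    r: float
    p: float
    n: int
    r_squared: float
    mse: float
    slope: float
    intercept: float


def pearson_corr(x, y) -> CorrResult:
    """Pearson correlation with p from the t distribution (n - 2 df) plus
    the simple least-squares regression on the same pairs.

    ``R^2 = r^2`` by construction; MSE is the mean squared residual of the
    fitted line (1/n normalisation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise DegenerateDataError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    lr = sps.linregress(x, y)
    resid = y - (lr.slope * x + lr.intercept)
    return CorrResult(
        r=float(r),
        p=float(p),
        n=n,
        r_squared=float(r) ** 2,
        mse=float(np.mean(resid**2)),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
    )


def pearson_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided Pearson correlation test.

    Fisher z approximation: the test statistic is approximately normal
    with mean ``atanh(rho) * sqrt(n - 3)`` under the alternative, so

    ``power = Phi(effect - z_{1-alpha/2}) + Phi(-effect - z_{1-alpha/2})``.

    At ``rho = 0`` the power equals ``alpha``.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n < 4:
        raise ValueError("power calculation needs n >= 4")
    effect = math.atanh(rho) * math.sqrt(n - 3)
    z_crit = sps.norm.ppf(1 - alpha / 2.0)
    return float(sps.norm.cdf(effect - z_crit) + sps.norm.cdf(-effect - z_crit))


# ---------------------------------------------------------------------------
# retina-behaviour orchestration

_GROUPINGS: dict[str, tuple[str | None, str | None]] = {
    "tg": ("tg", None),
    "tg_f": ("tg", "f"),
    "tg_m": ("tg", "m"),
    "ntg": ("ntg", None),
    "ntg_f": ("ntg", "f"),
    "ntg_m": ("ntg", "m"),
}


def correlate_retina_behavior(
    retina: pd.DataFrame,
    behavior: pd.DataFrame,
    groupings: dict[str, tuple[str | None, str | None]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Correlate retinal parameters with behavioural parameters per group.

    ``retina``: long format with ``animal_id, genotype, sex, eye, parameter,
    value`` (``eye`` may be missing/NaN for animal-level parameters such as
    weight).  ``behavior``: ``animal_id, parameter, value``.  Eyes are
    averaged per mouse first, so each mouse contributes one datapoint.
    Pairs within groups of fewer than 3 mice are skipped with a reason.

    Returns one table per grouping with columns ``retina_parameter,
    behavior_parameter, r, p, n, r_squared, mse, slope, intercept, note``.
    """
    groupings = _GROUPINGS if groupings is None else groupings
    ret = retina.copy()
    per_mouse = (
        ret.groupby(["animal_id", "genotype", "sex", "parameter"], dropna=False)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    beh = behavior.copy()

    out: dict[str, pd.DataFrame] = {}
    for gname, (genotype, sex) in groupings.items():
        sel = per_mouse
        if genotype is not None:
            sel = sel[sel["genotype"] == genotype]
        if sex is not None:
            sel = sel[sel["sex"] == sex]
        rows = []
        for rp in sorted(sel["parameter"].unique()):
            rvals = sel[sel["parameter"] == rp][["animal_id", "value"]]
            for bp in sorted(beh["parameter"].unique()):
                bvals = beh[beh["parameter"] == bp][["animal_id", "value"]]
                merged = rvals.merge(
                    bvals, on="animal_id", suffixes=("_ret", "_beh")
                ).dropna()
                row = {"retina_parameter": rp, "behavior_parameter": bp}
                if len(merged) < 3:
                    row.update({"n": len(merged), "note": "skipped: n < 3"})
                else:
                    try:
                        c = pearson_corr(merged["value_ret"], merged["value_beh"])
                        row.update(
                            {
                                "r": c.r,
                                "p": c.p,
                                "n": c.n,
                                "r_squared": c.r_squared,
                                "mse": c.mse,
                                "slope": c.slope,
                                "intercept": c.intercept,
                                "note": "",
                            }
                        )
                    except DegenerateDataError as exc:
                        row.update({"n": len(merged), "note": f"skipped: {exc}"})
                rows.append(row)
        out[gname] = pd.DataFrame(rows)
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (available but not applied by
    default anywhere in the pipeline)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]
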