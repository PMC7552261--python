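"""Herd variability analysis of sensor-derived panting.

Hourly panting minutes per animal are modelled with REML linear mixed
models (factor + hour + interaction fixed, animal random intercept) to
contrast genotype (Bos indicus fraction) and coat-colour groups across the
day; within-group individual variability is summarised as the coefficient
of variation of average daily panting totals, as top/bottom-decile
profiles, and as herd-level panting against thermal-index classes with a
panting-onset threshold scan.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .streams import PANTING, StateStream

logger = logging.getLogger(__name__)


def hourly_panting_table(streams: dict[str, StateStream]) -> pd.DataFrame:
    """One row per animal-date-hour with the panting minute count.

    Only clock hours with full 60-minute coverage are emitted; a partially
    covered hour would understate panting and is treated as absent.
    """
    rows = []
    for animal_id, stream in streams.items():
        start = stream.start
        n = len(stream)
        if start.hour == 0 and start.minute == 0 and n > 0 and n % 1440 == 0:
            # midnight-aligned whole days: plain reshape
            days = n // 1440
            counts = (
                (stream.states == PANTING).reshape(days, 24, 60).sum(axis=2)
            )
            dates = np.repeat(
                [(start + pd.Timedelta(days=d)).date() for d in range(days)], 24
            )
            g = pd.DataFrame(
                {
                    "animal_id": animal_id,
                    "date": dates,
                    "hour": np.tile(np.arange(24), days),
                    "panting_min": counts.ravel(),
                }
            )
        else:
            minutes = stream.minutes
            df = pd.DataFrame(
                {
                    "date": minutes.date,
                    "hour": minutes.hour,
                    "panting": (stream.states == PANTING).astype(np.int32),
                }
            )
            g = df.groupby(["date", "hour"], sort=True).agg(
                panting_min=("panting", "sum"), coverage=("panting", "size")
            )
            g = g[g["coverage"] == 60].drop(columns="coverage").reset_index()
            g.insert(0, "animal_id", animal_id)
        rows.append(g)
    out = pd.concat(rows, ignore_index=True)
    out["panting_min"] = out["panting_min"].astype(np.int64)
    return out


def average_hourly_panting(summaries: pd.DataFrame) -> pd.DataFrame:
    """Average hourly panting minutes per animal across days (the mixed-
    model outcome): one row per animal-hour."""
    return (
        summaries.groupby(["animal_id", "hour"])["panting_min"]
        .mean()
        .rename("panting_min")
        .reset_index()
    )


def daily_totals(summaries: pd.DataFrame) -> pd.DataFrame:
    """Average total panting duration per day for each animal, using only
    days with full 24-hour coverage."""
    per_day = summaries.groupby(["animal_id", "date"]).agg(
        total=("panting_min", "sum"), hours=("hour", "size")
    )
    full = per_day[per_day["hours"] == 24]
    if full.empty:
        raise ValueError("no animal-days with full 24-hour coverage")
    return (
        full.groupby("animal_id")["total"].mean().rename("avg_daily_min").reset_index()
    )


# ---------------------------------------------------------------------------
# group-by-hour mixed model
# ---------------------------------------------------------------------------

@dataclass
class GroupHourFit:
    """REML mixed-model contrasts of a grouping factor across hours."""

    factor: str
    estimates: pd.DataFrame  # columns: level, hour, predicted_mean_min, se
    avg_sed: float
    sed_by_hour: pd.Series
    sigma_animal2: float
    sigma_resid2: float
    converged: bool
    fallback_cell_means: bool = False


def _fit_mixedlm(model):
    """REML-fit a MixedLM, falling back through optimisers when the
    default gradient method hits a singular information matrix."""
    last_exc = None
    for method in (None, "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kwargs = {} if method is None else {"method": method}
                return model.fit(reml=True, **kwargs)
        except np.linalg.LinAlgError as exc:
            last_exc = exc
    raise last_exc


def fit_group_model(
    summaries: pd.DataFrame,
    attributes: pd.DataFrame,
    factor: str,
) -> GroupHourFit:
    """Fit hourly panting ~ factor * hour with an animal random intercept.

    The outcome is the per-animal average hourly panting minutes (averaged
    over days); *factor* is ``"genotype"`` or ``"coat"``.  Fitted by REML.
    Returns population predicted means per level-hour cell and the average
    standard error of difference (SED) between levels within an hour.  On
    non-convergence, per-cell raw means are returned and flagged.
    """
    if factor not in attributes.columns:
        raise ValueError(f"unknown grouping factor {factor!r}")
    y = average_hourly_panting(summaries).merge(
        attributes[["animal_id", factor]], on="animal_id"
    )
    levels = np.sort(y[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    per_level_animals = y.groupby(factor)["animal_id"].nunique()
    if (per_level_animals < 2).any():
        raise ValueError(f"factor {factor!r} needs >= 2 animals per level")

    hours = np.sort(y["hour"].unique())
    grid = pd.DataFrame(
        [(l, h) for l in levels for h in hours], columns=[factor, "hour"]
    )

    formula = f"panting_min ~ C({factor}) * C(hour)"
    converged = True
    fallback = False
    try:
        model = smf.mixedlm(formula, y, groups=y["animal_id"])
        fit = _fit_mixedlm(model)
        converged = bool(fit.converged)
    except Exception as exc:  # pragma: no cover - numerical failure path
        logger.warning("mixed model failed (%s); falling back to cell means", exc)
        fit = None
        converged = False

    if fit is not None and converged:
        design = model.data.design_info
        from patsy import dmatrix

        X = np.asarray(dmatrix(design, grid))
        beta = fit.fe_params.to_numpy()
        cov = fit.cov_params().iloc[: len(beta), : len(beta)].to_numpy()
        pred = X @ beta
        grid["predicted_mean_min"] = pred
        grid["se"] = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        # SED between the two (or each pair of) levels within each hour
        seds = {}
        for h in hours:
            rows = [X[(grid["hour"] == h) & (grid[factor] == l)][0] for l in levels]
            pair_seds = []
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    c = rows[i] - rows[j]
                    pair_seds.append(float(np.sqrt(c @ cov @ c)))
            seds[int(h)] = float(np.mean(pair_seds))
        sed_by_hour = pd.Series(seds, name="sed")
        sigma_a2 = float(fit.cov_re.iloc[0, 0])
        sigma_e2 = float(fit.scale)
    else:
        fallback = True
        cell = (
            y.groupby([factor, "hour"])["panting_min"].mean().rename(
                "predicted_mean_min"
            )
        )
        grid = grid.merge(cell.reset_index(), on=[factor, "hour"], how="left")
        grid["se"] = np.nan
        sed_by_hour = pd.Series({int(h): np.nan for h in hours}, name="sed")
        sigma_a2 = np.nan
        sigma_e2 = np.nan

    grid = grid.rename(columns={factor: "level"})
    return GroupHourFit(
        factor=factor,
        estimates=grid,
        avg_sed=float(sed_by_hour.mean()),
        sed_by_hour=sed_by_hour,
        sigma_animal2=sigma_a2,
        sigma_resid2=sigma_e2,
        converged=converged,
        fallback_cell_means=fallback,
    )


def screen_single_factors(
    summaries: pd.DataFrame,
    attributes: pd.DataFrame,
    factors: tuple[str, ...] = ("sex", "weight_kg", "docility"),
) -> pd.DataFrame:
    """Single-factor mixed-model Wald screening of animal attributes.

    Each attribute is fitted alone (plus an animal random intercept) and a
    Wald test of its fixed effect is reported.  These p-values are emitted
    for completeness only; the group analysis is fixed to genotype, coat
    and hour.
    """
    rows = []
    for f in factors:
        y = average_hourly_panting(summaries).merge(
            attributes[["animal_id", f]], on="animal_id"
        )
        term = f if pd.api.types.is_numeric_dtype(y[f]) else f"C({f})"
        fit = _fit_mixedlm(
            smf.mixedlm(f"panting_min ~ {term}", y, groups=y["animal_id"])
        )
        names = [n for n in fit.fe_params.index if n != "Intercept"]
        b = fit.fe_params[names].to_numpy()
        cov = fit.cov_params().loc[names, names].to_numpy()
        chi2 = float(b @ np.linalg.pinv(cov) @ b)  # Wald test of the factor
        p = float(stats.chi2.sf(chi2, df=len(names)))
        rows.append({"factor": f, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# within-group variability
# ---------------------------------------------------------------------------

def within_group_cv(
    summaries: pd.DataFrame, attributes: pd.DataFrame, grouping: str
) -> pd.Series:
    """Coefficient of variation (%) of average daily panting totals across
    animals within each level of *grouping* (sample SD, n-1)."""
    totals = daily_totals(summaries).merge(
        attributes[["animal_id", grouping]], on="animal_id"
    )
    out = {}
    for level, grp in totals.groupby(grouping):
        if len(grp) < 2:
            raise ValueError(f"group {level!r} needs >= 2 animals for a CV")
        mean = grp["avg_daily_min"].mean()
        if mean == 0:
            logger.warning("CV undefined for group %r (zero mean)", level)
            out[level] = np.nan
            continue
        out[level] = 100.0 * grp["avg_daily_min"].std(ddof=1) / mean
    return pd.Series(out, name="cv_pct")


@dataclass
class DecileContrast:
    group: str
    level: object
    top_ids: list
    bottom_ids: list
    profiles: pd.DataFrame  # columns: hour, top_mean, bottom_mean, herd_mean
    t_stat: float
    p_value: float


def top_bottom_deciles(
    summaries: pd.DataFrame,
    attributes: pd.DataFrame,
    grouping: str,
    fraction: float = 0.10,
    skip_small: bool = False,
) -> list[DecileContrast]:
    """Contrast the top and bottom decile of panting animals within each
    group level.

    Animals are ranked within group by average total panting duration per
    day; ceil(fraction * n) animals are taken at each extreme (ties broken
    by animal_id, ascending, so selection is deterministic).  Mean hourly
    profiles are emitted together with a Welch t-test on the daily totals.
    Undersized levels (decile < 2 animals) raise, or are skipped with a
    warning when *skip_small* is set.
    """
    totals = daily_totals(summaries).merge(
        attributes[["animal_id", grouping]], on="animal_id"
    )
    out = []
    for level, grp in totals.groupby(grouping):
        n = len(grp)
        k = math.ceil(fraction * n)
        if k < 2:
            if skip_small:
                logger.warning(
                    "skipping decile contrast for %s level %r (%d animals)",
                    grouping, level, n,
                )
                continue
            raise ValueError(
                f"group {level!r} has {n} animals; decile of {k} is too small "
                "for a t-test"
            )
        ranked = grp.sort_values(
            ["avg_daily_min", "animal_id"], ascending=[True, True]
        )
        bottom = ranked.head(k)
        top = ranked.tail(k)
        hourly = summaries.merge(
            attributes[["animal_id", grouping]], on="animal_id"
        )
        hourly = hourly[hourly[grouping] == level]
        prof = pd.DataFrame(
            {
                "herd_mean": hourly.groupby("hour")["panting_min"].mean(),
                "top_mean": hourly[hourly["animal_id"].isin(top["animal_id"])]
                .groupby("hour")["panting_min"]
                .mean(),
                "bottom_mean": hourly[
                    hourly["animal_id"].isin(bottom["animal_id"])
                ]
                .groupby("hour")["panting_min"]
                .mean(),
            }
        ).reset_index()
        t = stats.ttest_ind(
            top["avg_daily_min"], bottom["avg_daily_min"], equal_var=False
        )
        out.append(
            DecileContrast(
                group=grouping,
                level=level,
                top_ids=sorted(top["animal_id"].tolist()),
                bottom_ids=sorted(bottom["animal_id"].tolist()),
                profiles=prof,
                t_stat=float(t.statistic),
                p_value=float(t.pvalue),
            )
        )
    return out


# ---------------------------------------------------------------------------
# panting versus thermal index
# ---------------------------------------------------------------------------

@dataclass
class IndexResponse:
    index: str
    class_table: pd.DataFrame  # columns: class_lo, class_label, mean, n, sd
    avg_sed: float
    quad_coef: tuple[float, float, float]  # intercept, linear, quadratic
    threshold: int | None
    threshold_alpha: float


def herd_hourly_panting(
    summaries: pd.DataFrame,
    attributes: pd.DataFrame | None = None,
    genotype=None,
) -> pd.DataFrame:
    """Herd-level mean panting minutes per (date, hour): animals are
    averaged within the hour (optionally restricted to one genotype)."""
    df = summaries
    if genotype is not None:
        if attributes is None:
            raise ValueError("attributes required to filter by genotype")
        keep = attributes.loc[attributes["genotype"] == genotype, "animal_id"]
        df = df[df["animal_id"].isin(keep)]
        if df.empty:
            raise ValueError(f"no panting records for genotype {genotype!r}")
    return (
        df.groupby(["date", "hour"])["panting_min"].mean().rename("panting").reset_index()
    )


def panting_vs_index(
    herd_hourly: pd.DataFrame,
    index_hourly: pd.DataFrame,
    index: str = "thi",
    class_width: int = 5,
    alpha: float = 0.05,
    min_points: int = 2,
    p_adjust: str | None = None,
) -> IndexResponse:
    """Relate herd-level hourly panting to a thermal index.

    (a) Hourly observations are binned into *class_width*-unit index
    classes (50-54, 55-59, ...) and summarised as the class mean with an
    average SED based on the pooled within-class variance.
    (b) An ordinary least-squares quadratic of panting on the hourly index
    value is fitted (refused below 3 occupied classes).
    (c) The panting-onset threshold is the lowest integer index value
    whose hourly panting mean is significantly above the base (lowest
    observed) integer class, scanning upward with t-tests at *alpha* on
    the standard error of difference from the pooled within-class
    variance (optionally Bonferroni-adjusted via
    ``p_adjust="bonferroni"``).
    """
    joined = herd_hourly.merge(
        index_hourly[["date", "hour", index]], on=["date", "hour"]
    ).dropna(subset=[index, "panting"])
    if joined.empty:
        raise ValueError("no overlapping hours between panting and index series")
    vals = joined[index].to_numpy(dtype=float)
    pant = joined["panting"].to_numpy(dtype=float)

    lo = (np.floor(vals / class_width) * class_width).astype(int)
    tab = (
        pd.DataFrame({"class_lo": lo, "panting": pant})
        .groupby("class_lo")["panting"]
        .agg(["mean", "size", "std"])
        .reset_index()
        .rename(columns={"size": "n", "std": "sd"})
    )
    tab["class_label"] = [
        f"{c}-{c + class_width - 1}" for c in tab["class_lo"]
    ]
    # pooled within-class variance -> average SED between class means
    good = tab["n"] > 1
    if good.any():
        s2 = float(
            ((tab.loc[good, "n"] - 1) * tab.loc[good, "sd"] ** 2).sum()
            / (tab.loc[good, "n"] - 1).sum()
        )
        nh = stats.hmean(tab["n"])
        avg_sed = float(np.sqrt(2.0 * s2 / nh))
    else:  # pragma: no cover - degenerate single-point classes
        avg_sed = np.nan

    if len(tab) < 3:
        raise ValueError("quadratic fit refused: fewer than 3 index classes")
    quad = np.polynomial.polynomial.polyfit(vals, pant, 2)

    ints = np.round(vals).astype(int)
    by_int = pd.DataFrame({"iv": ints, "panting": pant})
    stats_int = by_int.groupby("iv")["panting"].agg(["mean", "size", "std"])
    usable = stats_int[stats_int["size"] >= min_points]
    threshold = None
    if len(usable) >= 2:
        # pooled within-class variance -> SED-based t tests against the base
        multi = stats_int[stats_int["size"] > 1]
        df_resid = float((multi["size"] - 1).sum())
        s2 = float(
            ((multi["size"] - 1) * multi["std"] ** 2).sum() / df_resid
        )
        base = usable.index.min()
        base_mean = usable.loc[base, "mean"]
        base_n = usable.loc[base, "size"]
        candidates = usable.index[usable.index > base]
        n_tests = len(candidates)
        for iv in candidates:
            diff = usable.loc[iv, "mean"] - base_mean
            sed = np.sqrt(s2 * (1.0 / usable.loc[iv, "size"] + 1.0 / base_n))
            p = 2.0 * stats.t.sf(abs(diff) / sed, df_resid)
            if p_adjust == "bonferroni":
                p = min(1.0, p * n_tests)
            if p < alpha and diff > 0:
                threshold = int(iv)
                break
    return IndexResponse(
        index=index,
        class_table=tab[["class_lo", "class_label", "mean", "n", "sd"]],
        avg_sed=avg_sed,
        quad_coef=(float(quad[0]), float(quad[1]), float(quad[2])),
        threshold=threshold,
        threshold_alpha=alpha,
    )
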