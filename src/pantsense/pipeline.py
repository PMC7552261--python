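"""End-to-end orchestration of the validation (Experiment-1 style) and
variability (Experiment-2 style) analyses."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, streams, thermal, variability
from .streams import StateStream, fill_transform

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration, echoed verbatim into every report."""

    variant: str = "both"  # raw | fill | both (validation)
    exp2_variant: str = "fill"  # stream variant feeding the variability analysis
    fill_before_exclusion: bool = True
    decile_fraction: float = 0.10
    index_class_width: int = 5
    heat_threshold: float = 90.0
    heat_min_days: int = 3
    threshold_alpha: float = 0.05
    threshold_p_adjust: str | None = None
    restrict_to_heat_events: bool = False
    ccc_boot_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("raw", "fill", "both"):
            raise ValueError(f"variant must be raw|fill|both, got {self.variant!r}")
        if self.exp2_variant not in ("raw", "fill"):
            raise ValueError("exp2_variant must be raw|fill")
        if not 0 < self.decile_fraction < 0.5:
            raise ValueError("decile_fraction must be in (0, 0.5)")
        if self.index_class_width < 1:
            raise ValueError("index_class_width must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ValidationReport:
    """Experiment-1 statistics for one stream variant."""

    variant: str
    n_aligned: int
    n_kept: int
    n_excluded_total: int
    n_excluded_sensor: int
    n_excluded_observer: int
    n_observed_panting: int
    n_observed_nonpanting: int
    agreement_by_ps: dict
    glmm: agreement.AgreementGlmmResult | None
    sensitivity_overall: agreement.Proportion | None
    sensitivity_by_ps: dict
    specificity: agreement.Proportion | None
    ppv: agreement.Proportion | None
    regression: agreement.RegressionResult | None
    ccc: agreement.CccResult | None
    duration_pairs: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def prop(p):
            return None if p is None else {"pct": p.pct, "ci": list(p.ci), "k": p.k, "n": p.n}

        d = {
            "variant": self.variant,
            "n_aligned": self.n_aligned,
            "n_kept": self.n_kept,
            "n_excluded_total": self.n_excluded_total,
            "n_excluded_sensor": self.n_excluded_sensor,
            "n_excluded_observer": self.n_excluded_observer,
            "n_observed_panting": self.n_observed_panting,
            "n_observed_nonpanting": self.n_observed_nonpanting,
            "agreement_by_ps": {k: prop(v) for k, v in self.agreement_by_ps.items()},
            "sensitivity_overall": prop(self.sensitivity_overall),
            "sensitivity_by_ps": {k: prop(v) for k, v in self.sensitivity_by_ps.items()},
            "specificity": prop(self.specificity),
            "ppv": prop(self.ppv),
        }
        if self.glmm is not None:
            d["glmm_predicted_agreement"] = self.glmm.predicted
            d["glmm_sigma_animal"] = self.glmm.sigma_animal
            d["glmm_converged"] = self.glmm.converged
        if self.regression is not None:
            d["pearson_r"] = self.regression.r
            d["pearson_r_ci"] = list(self.regression.r_ci)
            d["r2"] = self.regression.r2
            d["regression_slope"] = self.regression.slope
            d["regression_intercept"] = self.regression.intercept
        if self.ccc is not None:
            d["ccc"] = self.ccc.ccc
            d["ccc_ci"] = list(self.ccc.ccc_ci)
            d["cb"] = self.ccc.cb
            d["cb_ci"] = list(self.ccc.cb_ci)
        return d


def _variant_streams(
    sensor_streams: dict[str, StateStream], variant: str
) -> dict[str, StateStream]:
    if variant == "raw":
        return sensor_streams
    return {a: fill_transform(s) for a, s in sensor_streams.items()}


def validate_variant(
    observed: pd.DataFrame,
    sensor_streams: dict[str, StateStream],
    variant: str,
    config: RunConfig | None = None,
    fit_glmm: bool = True,
) -> ValidationReport:
    """Run the full validation-statistics suite for one variant.

    The fill transformation (when requested) is applied to the complete
    per-animal sensor stream *before* alignment and undefined-exclusion,
    so smoothing never acts across artificially adjacent minutes.
    """
    config = config or RunConfig()
    streams_v = _variant_streams(sensor_streams, variant)
    sensor_frame = pd.concat([s.to_frame() for s in streams_v.values()], ignore_index=True)
    aligned = streams.align_streams(observed, sensor_frame)
    kept, n_total, n_sensor, n_observer = streams.exclude_undefined(aligned)

    agree = agreement.agreement_by_ps(kept)
    glmm = None
    if fit_glmm:
        try:
            glmm = agreement.fit_agreement_glmm(kept)
        except ValueError as exc:
            logger.warning("agreement GLMM skipped: %s", exc)

    overall = agreement.confusion_counts(kept)
    sens_by_ps = {}
    for ps_level in sorted(kept.loc[kept["observed_ps"] >= 1, "observed_ps"].unique()):
        c = agreement.confusion_counts(kept, ps=int(ps_level))
        sens_by_ps[int(ps_level)] = agreement.sensitivity(c)

    pairs = agreement.duration_pairs(kept)
    reg = ccc = None
    if len(pairs) >= 3:
        try:
            reg = agreement.pearson_r(pairs["observed_min"], pairs["sensor_min"])
            ccc = agreement.lin_ccc(
                pairs["observed_min"], pairs["sensor_min"], seed=config.ccc_boot_seed
            )
        except ValueError as exc:
            logger.warning("duration concordance skipped: %s", exc)

    n_pant = int((kept["observed_ps"] >= 1).sum())
    return ValidationReport(
        variant=variant,
        n_aligned=len(aligned),
        n_kept=len(kept),
        n_excluded_total=n_total,
        n_excluded_sensor=n_sensor,
        n_excluded_observer=n_observer,
        n_observed_panting=n_pant,
        n_observed_nonpanting=len(kept) - n_pant,
        agreement_by_ps=agree,
        glmm=glmm,
        sensitivity_overall=agreement.sensitivity(overall),
        sensitivity_by_ps=sens_by_ps,
        specificity=agreement.specificity(overall),
        ppv=agreement.ppv(overall),
        regression=reg,
        ccc=ccc,
        duration_pairs=pairs,
    )


def run_experiment1(
    observed: pd.DataFrame,
    sensor_streams: dict[str, StateStream],
    config: RunConfig | None = None,
    fit_glmm: bool = True,
) -> dict[str, ValidationReport]:
    """Validation statistics for the requested variant(s)."""
    config = config or RunConfig()
    variants = ("raw", "fill") if config.variant == "both" else (config.variant,)
    return {
        v: validate_variant(observed, sensor_streams, v, config, fit_glmm=fit_glmm)
        for v in variants
    }


@dataclass
class VariabilityResult:
    """Experiment-2 outputs."""

    variant: str
    heat_events: list
    analysis_days: list
    genotype_fit: variability.GroupHourFit
    coat_fit: variability.GroupHourFit
    cv_genotype: pd.Series
    cv_coat: pd.Series
    deciles_genotype: list
    deciles_coat: list
    thi_response: variability.IndexResponse
    hli_response: variability.IndexResponse
    factor_screen: pd.DataFrame | None
    hourly_table: pd.DataFrame = field(repr=False, default=None)


def run_experiment2(
    sensor_streams: dict[str, StateStream],
    attributes: pd.DataFrame,
    weather: pd.DataFrame,
    config: RunConfig | None = None,
    screen_factors: bool = False,
) -> VariabilityResult:
    """Variability analysis on the configured stream variant.

    Weather must already carry ``thi``/``hli`` columns (see
    :func:`pantsense.thermal.index_series`).
    """
    config = config or RunConfig()
    streams_v = _variant_streams(sensor_streams, config.exp2_variant)

    maxima = thermal.daily_maxima(weather)
    events = thermal.detect_heat_events(
        maxima["thi"], maxima["hli"], config.heat_threshold, config.heat_min_days
    )
    hourly = variability.hourly_panting_table(streams_v)
    if config.restrict_to_heat_events:
        if not events:
            raise ValueError("no heat events detected; cannot restrict analysis")
        keep_days = {
            d
            for e in events
            for d in pd.date_range(e.start_day, e.end_day).date
        }
        hourly = hourly[hourly["date"].isin(keep_days)]
    analysis_days = sorted(set(hourly["date"]))

    geno_fit = variability.fit_group_model(hourly, attributes, "genotype")
    coat_fit = variability.fit_group_model(hourly, attributes, "coat")
    cv_geno = variability.within_group_cv(hourly, attributes, "genotype")
    cv_coat = variability.within_group_cv(hourly, attributes, "coat")
    dec_geno = variability.top_bottom_deciles(
        hourly, attributes, "genotype", config.decile_fraction, skip_small=True
    )
    dec_coat = variability.top_bottom_deciles(
        hourly, attributes, "coat", config.decile_fraction, skip_small=True
    )

    idx_hourly = thermal.hourly_means_by_day(weather)
    if config.restrict_to_heat_events:
        idx_hourly = idx_hourly[idx_hourly["date"].isin(set(analysis_days))]
    herd = variability.herd_hourly_panting(hourly)
    thi_resp = variability.panting_vs_index(
        herd,
        idx_hourly,
        "thi",
        config.index_class_width,
        config.threshold_alpha,
        p_adjust=config.threshold_p_adjust,
    )
    hli_resp = variability.panting_vs_index(
        herd,
        idx_hourly,
        "hli",
        config.index_class_width,
        config.threshold_alpha,
        p_adjust=config.threshold_p_adjust,
    )
    screen = (
        variability.screen_single_factors(hourly, attributes)
        if screen_factors
        else None
    )
    return VariabilityResult(
        variant=config.exp2_variant,
        heat_events=events,
        analysis_days=analysis_days,
        genotype_fit=geno_fit,
        coat_fit=coat_fit,
        cv_genotype=cv_geno,
        cv_coat=cv_coat,
        deciles_genotype=dec_geno,
        deciles_coat=dec_coat,
        thi_response=thi_resp,
        hli_response=hli_resp,
        factor_screen=screen,
        hourly_table=hourly,
    )


def write_experiment1_report(reports: dict, config: RunConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "reports": {v: r.to_dict() for v, r in reports.items()},
    }
    path = outdir / "validation_report.json"
    path.write_text(json.dumps(payload, indent=2))
    for v, r in reports.items():
        if r.duration_pairs is not None:
            r.duration_pairs.to_csv(outdir / f"duration_pairs_{v}.csv", index=False)
    return path


def write_experiment2_report(result: VariabilityResult, config: RunConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.genotype_fit.estimates.to_csv(outdir / "genotype_hour_estimates.csv", index=False)
    result.coat_fit.estimates.to_csv(outdir / "coat_hour_estimates.csv", index=False)
    pd.concat(
        {"genotype": result.cv_genotype, "coat": result.cv_coat}
    ).rename_axis(["grouping", "level"]).to_csv(outdir / "cv_table.csv")
    for name, decs in (("genotype", result.deciles_genotype), ("coat", result.deciles_coat)):
        for d in decs:
            d.profiles.to_csv(outdir / f"decile_profiles_{name}_{d.level}.csv", index=False)
    result.thi_response.class_table.to_csv(outdir / "thi_class_table.csv", index=False)
    result.hli_response.class_table.to_csv(outdir / "hli_class_table.csv", index=False)
    payload = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "variant": result.variant,
        "heat_events": [
            {"start": str(e.start_day), "end": str(e.end_day), "n_days": e.n_days}
            for e in result.heat_events
        ],
        "n_analysis_days": len(result.analysis_days),
        "genotype_avg_sed": result.genotype_fit.avg_sed,
        "coat_avg_sed": result.coat_fit.avg_sed,
        "cv_genotype": result.cv_genotype.to_dict(),
        "cv_coat": result.cv_coat.to_dict(),
        "decile_t": {
            str(d.level): {"t": d.t_stat, "p": d.p_value}
            for d in result.deciles_genotype + result.deciles_coat
        },
        "thi_threshold": result.thi_response.threshold,
        "hli_threshold": result.hli_response.threshold,
        "thi_quadratic": list(result.thi_response.quad_coef),
        "hli_quadratic": list(result.hli_response.quad_coef),
    }
    path = outdir / "variability_report.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
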