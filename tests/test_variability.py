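"""Herd variability analysis: mixed models, CV, deciles, index response."""

import numpy as np
import pandas as pd
import pytest

from pantsense import variability as V
from pantsense.simulate import matrix_to_streams
from pantsense.streams import OTHER, PANTING, StateStream, panting_minutes


def summaries_from(records):
    """(animal_id, date, hour, panting_min) rows."""
    return pd.DataFrame(
        records, columns=["animal_id", "date", "hour", "panting_min"]
    )


def full_day_summaries(totals_by_animal, days=("2019-01-10",), spread_hour=12):
    """24-hour coverage per animal-day with the daily total placed in one
    hour (keeps daily totals exact and coverage complete)."""
    rows = []
    for animal, total in totals_by_animal.items():
        for d in days:
            date = pd.Timestamp(d).date()
            for h in range(24):
                rows.append((animal, date, h, total if h == spread_hour else 0))
    return summaries_from(rows)


def attrs_frame(mapping, column="genotype"):
    return pd.DataFrame(
        {"animal_id": list(mapping), column: list(mapping.values())}
    )


# ---------------------------------------------------------------------------
# hourly table
# ---------------------------------------------------------------------------

def test_hourly_table_counts_and_conservation(tiny_sim):
    streams = tiny_sim.truth.streams()
    table = V.hourly_panting_table(streams)
    assert set(table.columns) == {"animal_id", "date", "hour", "panting_min"}
    assert table["panting_min"].between(0, 60).all()
    # conservation against direct window counts
    for animal_id, stream in list(streams.items())[:3]:
        total = panting_minutes(
            stream, stream.start, stream.start + pd.Timedelta(minutes=len(stream))
        )
        assert table.loc[table["animal_id"] == animal_id, "panting_min"].sum() == total


def test_hourly_table_all_panting_hour_and_partial_hour():
    start = pd.Timestamp("2019-01-10 08:00")
    s = StateStream("A1", start, np.full(90, PANTING, dtype=np.int8))
    table = V.hourly_panting_table({"A1": s})
    # 08:00-09:00 fully covered -> 60; 09:00-09:30 partial -> absent
    assert len(table) == 1
    assert table.iloc[0]["hour"] == 8 and table.iloc[0]["panting_min"] == 60


# ---------------------------------------------------------------------------
# group-hour mixed model
# ---------------------------------------------------------------------------

def _balanced_summaries(rng, gap=0.0, animal_sd=0.0, noise_sd=0.3, n_per_level=6):
    rows = []
    attrs = {}
    hours = range(24)
    base_by_hour = {h: 5.0 + 10.0 * np.exp(-((h - 13) ** 2) / 18.0) for h in hours}
    date = pd.Timestamp("2019-01-10").date()
    for lvl_i, level in enumerate(("BI50", "LT40_BI")):
        for a in range(n_per_level):
            animal = f"{level}_{a}"
            attrs[animal] = level
            u = rng.normal(0, animal_sd)
            for h in hours:
                y = base_by_hour[h] + gap * lvl_i + u + rng.normal(0, noise_sd)
                rows.append((animal, date, h, y))
    return summaries_from(rows), attrs_frame(attrs)


def test_group_model_matches_cell_means_when_balanced(rng):
    """Without animal variance the REML fit's population predictions equal
    the raw cell means (balanced design)."""
    summaries, attrs = _balanced_summaries(rng, gap=3.0)
    fit = V.fit_group_model(summaries, attrs, "genotype")
    assert fit.converged and not fit.fallback_cell_means
    merged = summaries.merge(attrs, on="animal_id")
    cells = merged.groupby(["genotype", "hour"])["panting_min"].mean()
    for _, row in fit.estimates.iterrows():
        assert row["predicted_mean_min"] == pytest.approx(
            cells.loc[(row["level"], row["hour"])], abs=1e-3
        )
    assert fit.avg_sed > 0


def test_group_model_recovers_designed_gap(rng):
    """A designed 3 min/h genotype gap with animal heterogeneity is
    recovered within +-0.5."""
    summaries, attrs = _balanced_summaries(
        rng, gap=3.0, animal_sd=2.0, noise_sd=1.0, n_per_level=15
    )
    fit = V.fit_group_model(summaries, attrs, "genotype")
    est = fit.estimates.pivot(index="hour", columns="level", values="predicted_mean_min")
    gap = (est["LT40_BI"] - est["BI50"]).mean()
    assert gap == pytest.approx(3.0, abs=0.5)
    assert fit.sigma_animal2 > 1.0  # heterogeneity attributed to animals


def test_group_model_input_validation(rng):
    summaries, attrs = _balanced_summaries(rng)
    only_one = attrs[attrs["genotype"] == "BI50"]
    with pytest.raises(ValueError, match="2 levels"):
        V.fit_group_model(
            summaries[summaries["animal_id"].isin(only_one["animal_id"])],
            only_one,
            "genotype",
        )
    with pytest.raises(ValueError, match="unknown grouping factor"):
        V.fit_group_model(summaries, attrs, "breed")


# ---------------------------------------------------------------------------
# CV and deciles
# ---------------------------------------------------------------------------

def test_cv_identical_animals_is_zero():
    summaries = full_day_summaries({"A1": 20.0, "A2": 20.0, "A3": 20.0})
    attrs = attrs_frame({"A1": "g", "A2": "g", "A3": "g"})
    assert V.within_group_cv(summaries, attrs, "genotype")["g"] == pytest.approx(0.0)


def test_cv_hand_example():
    """Two animals at 10 and 30 min/day: CV = 100 sqrt(200)/20 ~ 70.7%."""
    summaries = full_day_summaries({"A1": 10.0, "A2": 30.0})
    attrs = attrs_frame({"A1": "g", "A2": "g"})
    cv = V.within_group_cv(summaries, attrs, "genotype")["g"]
    assert cv == pytest.approx(100.0 * np.sqrt(200.0) / 20.0, abs=1e-9)


def test_cv_brute_force_groups(rng):
    totals = {f"A{i}": float(rng.uniform(5, 120)) for i in range(14)}
    groups = {a: ("x" if i % 2 else "y") for i, a in enumerate(totals)}
    summaries = full_day_summaries(totals)
    cv = V.within_group_cv(summaries, attrs_frame(groups), "genotype")
    for g in ("x", "y"):
        vals = np.array([t for a, t in totals.items() if groups[a] == g])
        assert cv[g] == pytest.approx(100 * vals.std(ddof=1) / vals.mean())


def test_cv_excludes_partial_days():
    summaries = full_day_summaries({"A1": 10.0, "A2": 30.0})
    # add a partial (non-24 h) day that would otherwise distort totals
    extra = summaries_from([("A1", pd.Timestamp("2019-01-11").date(), 12, 60.0)])
    cv = V.within_group_cv(
        pd.concat([summaries, extra]), attrs_frame({"A1": "g", "A2": "g"}), "genotype"
    )
    assert cv["g"] == pytest.approx(100.0 * np.sqrt(200.0) / 20.0)


def test_deciles_selection_and_contrast(rng):
    totals = {f"A{i:02d}": float(i) for i in range(20)}  # linear gradient
    summaries = full_day_summaries(totals)
    attrs = attrs_frame({a: "g" for a in totals})
    (contrast,) = V.top_bottom_deciles(summaries, attrs, "genotype")
    assert contrast.top_ids == ["A18", "A19"]
    assert contrast.bottom_ids == ["A00", "A01"]
    assert set(contrast.top_ids).isdisjoint(contrast.bottom_ids)
    assert contrast.t_stat > 0
    prof = contrast.profiles.set_index("hour")
    assert prof.loc[12, "top_mean"] == pytest.approx(18.5)
    assert prof.loc[12, "bottom_mean"] == pytest.approx(0.5)
    assert prof.loc[12, "herd_mean"] == pytest.approx(9.5)


def test_deciles_tie_break_deterministic():
    totals = {f"A{i:02d}": 10.0 for i in range(20)}  # all tied
    summaries = full_day_summaries(totals)
    attrs = attrs_frame({a: "g" for a in totals})
    (c1,) = V.top_bottom_deciles(summaries, attrs, "genotype")
    (c2,) = V.top_bottom_deciles(summaries, attrs, "genotype")
    assert c1.top_ids == c2.top_ids == ["A18", "A19"]
    assert c1.bottom_ids == ["A00", "A01"]


def test_deciles_too_small_group_errors():
    summaries = full_day_summaries({"A1": 5.0, "A2": 6.0})
    with pytest.raises(ValueError, match="too small"):
        V.top_bottom_deciles(summaries, attrs_frame({"A1": "g", "A2": "g"}), "genotype")


# ---------------------------------------------------------------------------
# panting versus thermal index
# ---------------------------------------------------------------------------

def _hourly_panel(index_vals, panting_vals):
    dates = pd.Timestamp("2019-01-10").date()
    hours = np.arange(len(index_vals)) % 24
    days = [
        (pd.Timestamp("2019-01-10") + pd.Timedelta(days=int(i // 24))).date()
        for i in range(len(index_vals))
    ]
    herd = pd.DataFrame({"date": days, "hour": hours, "panting": panting_vals})
    idx = pd.DataFrame({"date": days, "hour": hours, "thi": index_vals})
    return herd, idx


def test_quadratic_fit_exact_recovery(rng):
    thi = rng.uniform(55, 90, 24 * 6)
    pant = 0.02 * thi**2 - 2.2 * thi + 71.84
    herd, idx = _hourly_panel(thi, pant)
    res = V.panting_vs_index(herd, idx, "thi")
    c0, c1, c2 = res.quad_coef
    assert c0 == pytest.approx(71.84, abs=1e-8)
    assert c1 == pytest.approx(-2.2, abs=1e-8)
    assert c2 == pytest.approx(0.02, abs=1e-8)


def test_class_means_brute_force(rng):
    thi = rng.uniform(52, 88, 24 * 5)
    pant = rng.uniform(0, 30, 24 * 5)
    herd, idx = _hourly_panel(thi, pant)
    res = V.panting_vs_index(herd, idx, "thi", class_width=5)
    tab = res.class_table.set_index("class_lo")
    for lo in tab.index:
        mask = (np.floor(thi / 5) * 5).astype(int) == lo
        assert tab.loc[lo, "mean"] == pytest.approx(pant[mask].mean())
        assert tab.loc[lo, "n"] == mask.sum()
    assert tab.loc[55, "class_label"] == "55-59"


def test_flat_panting_has_no_threshold(rng):
    thi = rng.uniform(55, 90, 24 * 5)
    pant = 8.0 + rng.normal(0, 0.3, thi.size)
    herd, idx = _hourly_panel(thi, pant)
    res = V.panting_vs_index(herd, idx, "thi")
    assert res.threshold is None
    assert abs(res.quad_coef[2]) < 0.01


def test_designed_breakpoint_detected(rng):
    thi = rng.uniform(55, 90, 24 * 10)
    pant = 5.0 + 1.0 * np.clip(thi - 64.0, 0, None) + rng.normal(0, 0.5, thi.size)
    herd, idx = _hourly_panel(thi, pant)
    res = V.panting_vs_index(herd, idx, "thi")
    assert res.threshold is not None and abs(res.threshold - 64) <= 2


def test_too_few_classes_refused():
    herd, idx = _hourly_panel(np.full(48, 70.0), np.full(48, 10.0))
    with pytest.raises(ValueError, match="fewer than 3"):
        V.panting_vs_index(herd, idx, "thi")


def test_herd_hourly_panting_averages_animals():
    rows = [
        ("A1", pd.Timestamp("2019-01-10").date(), 12, 20.0),
        ("A2", pd.Timestamp("2019-01-10").date(), 12, 10.0),
        ("A1", pd.Timestamp("2019-01-10").date(), 13, 6.0),
    ]
    herd = V.herd_hourly_panting(summaries_from(rows))
    h12 = herd[herd["hour"] == 12]["panting"].iloc[0]
    assert h12 == pytest.approx(15.0)


def test_factor_screen_reports_pvalues(rng):
    summaries, attrs = _balanced_summaries(rng, animal_sd=1.0, noise_sd=1.0)
    attrs = attrs.assign(
        sex=rng.choice(["steer", "heifer"], len(attrs)),
        weight_kg=rng.normal(342, 25, len(attrs)),
        docility=rng.integers(1, 6, len(attrs)),
    )
    out = V.screen_single_factors(summaries, attrs)
    assert set(out["factor"]) == {"sex", "weight_kg", "docility"}
    assert out["p_value"].between(0, 1).all()
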