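"""Validation statistics: confusion metrics, agreement, concordance, kappa."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from pantsense import agreement as ag
from pantsense.streams import OTHER, PANTING
from conftest import make_observed, make_sensor
from pantsense.streams import align_streams, exclude_undefined


def kept_frame(rows):
    """Evaluated-minute frame from (animal_id, observed_ps, sensor_state)."""
    return pd.DataFrame(
        {
            "animal_id": [r[0] for r in rows],
            "minute": pd.date_range("2019-01-10 08:00", periods=len(rows), freq="min"),
            "observed_state": np.int8(
                [PANTING if r[1] >= 1 else OTHER for r in rows]
            ),
            "observed_ps": pd.array([r[1] for r in rows], dtype="Int8"),
            "sensor_state": np.int8([r[2] for r in rows]),
        }
    )


# ---------------------------------------------------------------------------
# confusion counts and rates
# ---------------------------------------------------------------------------

def test_confusion_counts_perfect_and_inverted():
    rows = [("A", 2, PANTING), ("A", 0, OTHER), ("A", 1, PANTING)]
    c = ag.confusion_counts(kept_frame(rows))
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 1, 0)
    inverted = [("A", 2, OTHER), ("A", 0, PANTING)]
    c2 = ag.confusion_counts(kept_frame(inverted))
    assert (c2.tp, c2.tn) == (0, 0) and (c2.fp, c2.fn) == (1, 1)


def test_confusion_counts_random_vs_crosstab(rng):
    rows = [
        ("A", int(ps), int(sen))
        for ps, sen in zip(
            rng.integers(0, 3, 500), rng.choice([OTHER, PANTING], 500)
        )
    ]
    df = kept_frame(rows)
    c = ag.confusion_counts(df)
    obs = df["observed_ps"] >= 1
    sen = df["sensor_state"] == PANTING
    assert c.tp == (obs & sen).sum()
    assert c.fn == (obs & ~sen).sum()
    assert c.fp == (~obs & sen).sum()
    assert c.tn == (~obs & ~sen).sum()
    assert c.total == 500


def test_ps_stratum_contains_only_that_score():
    rows = [("A", 1, PANTING), ("A", 2, OTHER), ("A", 0, OTHER), ("A", 2, PANTING)]
    c = ag.confusion_counts(kept_frame(rows), ps=2)
    assert c.total == 2 and c.tp == 1 and c.fn == 1
    with pytest.raises(ValueError, match="stratum 3"):
        ag.confusion_counts(kept_frame(rows), ps=3)


def test_rates_exhaustive_small_tables():
    """Sensitivity/specificity/PPV match direct counting on every
    confusion table with at most 8 minutes."""
    for tp, fp, tn, fn in itertools.product(range(9), repeat=4):
        if not 0 < tp + fp + tn + fn <= 8:
            continue
        c = ag.ConfusionCounts(tp, fp, tn, fn)
        sens, spec, p = ag.sensitivity(c), ag.specificity(c), ag.ppv(c)
        if tp + fn == 0:
            assert sens is None
        else:
            assert sens.pct == pytest.approx(100 * tp / (tp + fn))
            assert sens.ci[0] <= sens.pct <= sens.ci[1]
            assert 0 <= sens.ci[0] and sens.ci[1] <= 100
        if tn + fp == 0:
            assert spec is None
        else:
            assert spec.pct == pytest.approx(100 * tn / (tn + fp))
        if tp + fp == 0:
            assert p is None
        else:
            assert p.pct == pytest.approx(100 * tp / (tp + fp))


def test_wilson_ci_known_value():
    """39/100 positives: Wilson interval lies inside (29, 50)."""
    lo, hi = ag.wilson_ci_pct(39, 100)
    assert 29 < lo < 39 < hi < 50


# ---------------------------------------------------------------------------
# agreement by PS
# ---------------------------------------------------------------------------

def test_agreement_by_ps():
    rows = (
        [("A", 0, OTHER)] * 3          # PS0 all correct
        + [("A", 1, PANTING), ("A", 1, OTHER)]  # PS1 half correct
        + [("A", 2, PANTING)] * 4      # PS2 all correct
    )
    out = ag.agreement_by_ps(kept_frame(rows))
    assert out[0].pct == pytest.approx(100.0)
    assert out[1].pct == pytest.approx(50.0)
    assert out[2].pct == pytest.approx(100.0)
    assert out[0].n == 3 and out[1].n == 2 and out[2].n == 4


# ---------------------------------------------------------------------------
# agreement GLMM
# ---------------------------------------------------------------------------

def _glm_reference(df):
    """Per-PS agreement proportions via statsmodels GLM (no random term)."""
    import statsmodels.api as sm

    y = ag._agree_indicator(df).astype(float)
    out = {}
    for lvl in np.sort(df["observed_ps"].unique()):
        out[int(lvl)] = float(y[(df["observed_ps"] == lvl).to_numpy()].mean())
    return out


def test_glmm_collapses_to_glm_without_animal_variance(rng):
    """With zero true animal variance and balanced data the mixed model's
    population predictions equal the empirical per-PS proportions."""
    rows = []
    probs = {0: 0.8, 1: 0.5, 2: 0.7}
    for animal in range(8):
        for ps, p in probs.items():
            for k in range(40):
                agree = rng.random() < p
                sensor = (
                    (PANTING if ps >= 1 else OTHER)
                    if agree
                    else (OTHER if ps >= 1 else PANTING)
                )
                rows.append((f"A{animal}", ps, sensor))
    df = kept_frame(rows)
    res = ag.fit_agreement_glmm(df)
    emp = _glm_reference(df)
    for lvl, p in res.predicted.items():
        assert p == pytest.approx(emp[lvl], abs=1e-3)
    assert res.sigma_animal < 0.3


def test_glmm_recovers_designed_agreement(rng):
    """Designed per-PS agreement 0.75/0.45/0.68 with animal heterogeneity
    is recovered within +-0.05 (50 animals x 200 minutes)."""
    target = {0: 0.75, 1: 0.45, 2: 0.68}
    beta = {k: np.log(v / (1 - v)) for k, v in target.items()}
    rows = []
    for animal in range(50):
        u = rng.normal(0, 0.6)
        ps_seq = rng.integers(0, 3, 200)
        for ps in ps_seq:
            p = expit(beta[int(ps)] + u)
            agree = rng.random() < p
            sensor = (
                (PANTING if ps >= 1 else OTHER)
                if agree
                else (OTHER if ps >= 1 else PANTING)
            )
            rows.append((f"A{animal}", int(ps), sensor))
    res = ag.fit_agreement_glmm(kept_frame(rows))
    assert res.converged
    for lvl, tgt in target.items():
        assert res.predicted[lvl] == pytest.approx(tgt, abs=0.05)
    assert 0.3 < res.sigma_animal < 1.0


def test_glmm_requires_two_animals_and_levels():
    rows = [("A", 0, OTHER), ("A", 1, PANTING)] * 10
    with pytest.raises(ValueError, match="two animals"):
        ag.fit_agreement_glmm(kept_frame(rows))
    rows2 = [("A", 1, PANTING), ("B", 1, OTHER)] * 10
    with pytest.raises(ValueError, match="PS levels"):
        ag.fit_agreement_glmm(kept_frame(rows2))


# ---------------------------------------------------------------------------
# duration concordance
# ---------------------------------------------------------------------------

def test_duration_pairs_sums(rng):
    rows = []
    expected = {}
    for animal in ("A1", "A2", "A3"):
        ps_seq = rng.integers(0, 3, 30)
        sen_seq = rng.choice([OTHER, PANTING], 30)
        rows += [(animal, int(p), int(s)) for p, s in zip(ps_seq, sen_seq)]
        expected[animal] = ((ps_seq >= 1).sum(), (sen_seq == PANTING).sum())
    pairs = ag.duration_pairs(kept_frame(rows)).set_index("animal_id")
    for animal, (obs, sen) in expected.items():
        assert pairs.loc[animal, "observed_min"] == obs
        assert pairs.loc[animal, "sensor_min"] == sen


def test_pearson_r_trivial_and_brute_force(rng):
    x = np.arange(10.0)
    res = ag.pearson_r(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0) and res.intercept == pytest.approx(0.0)
    res2 = ag.pearson_r(x, -x)
    assert res2.r == pytest.approx(-1.0)
    a, b = rng.normal(size=30), rng.normal(size=30)
    res3 = ag.pearson_r(a, b)
    assert res3.r == pytest.approx(np.corrcoef(a, b)[0, 1])
    assert res3.r_ci[0] < res3.r < res3.r_ci[1]
    assert res3.r2 == pytest.approx(res3.r**2)


def test_pearson_r_degenerate_errors():
    with pytest.raises(ValueError):
        ag.pearson_r([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        ag.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_ccc_perfect_and_shift():
    x = np.arange(10.0)
    res = ag.lin_ccc(x, x, n_boot=100)
    assert res.ccc == pytest.approx(1.0) and res.cb == pytest.approx(1.0)
    shifted = ag.lin_ccc(x, x + 5.0, n_boot=100)
    assert shifted.r == pytest.approx(1.0)
    assert shifted.cb < 1.0
    assert shifted.ccc == pytest.approx(shifted.cb, abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-50, 50, allow_nan=False),
            st.floats(-50, 50, allow_nan=False),
        ),
        min_size=3,
        max_size=40,
    )
)
def test_ccc_identity_property(pairs):
    """CCC = r x C_b to 1e-12; |CCC| <= |r| <= 1; C_b in (0, 1]."""
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if x.var(ddof=1) <= 0 or y.var(ddof=1) <= 0:
        return
    res = ag.lin_ccc(x, y, n_boot=10)
    assert res.ccc == pytest.approx(res.r * res.cb, abs=1e-12)
    assert abs(res.ccc) <= abs(res.r) + 1e-12 <= 1 + 1e-9
    assert 0 < res.cb <= 1 + 1e-12


def test_ccc_bootstrap_ci_seeded():
    rng = np.random.default_rng(5)
    x = rng.normal(20, 8, 40)
    y = 0.5 * x + rng.normal(0, 2, 40)
    a = ag.lin_ccc(x, y, seed=7)
    b = ag.lin_ccc(x, y, seed=7)
    assert a.cb_ci == b.cb_ci
    assert a.cb_ci[0] <= a.cb <= a.cb_ci[1]
    assert a.ccc_ci[0] < a.ccc < a.ccc_ci[1]


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def test_kappa_perfect_and_undefined():
    a = np.array([0, 1, 2, 1, 0])
    assert ag.cohens_kappa(a, a) == pytest.approx(1.0)
    assert ag.cohens_kappa([1, 1, 1], [1, 1, 1]) is None


def test_kappa_independent_raters_near_zero(rng):
    a = rng.integers(0, 3, 20000)
    b = rng.integers(0, 3, 20000)
    assert abs(ag.cohens_kappa(a, b)) < 0.02


def test_kappa_matches_sklearn_oracle(rng):
    from sklearn.metrics import cohen_kappa_score

    for _ in range(20):
        a = rng.integers(0, 4, 200)
        b = np.where(rng.random(200) < 0.6, a, rng.integers(0, 4, 200))
        assert ag.cohens_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )


def test_kappa_shape_mismatch():
    with pytest.raises(ValueError):
        ag.cohens_kappa([1, 2], [1, 2, 3])
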