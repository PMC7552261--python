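"""Method-comparison statistics for sensor-vs-observer panting validation.

Panting is the positive class; any other defined behaviour state counts as
non-panting.  The module computes minute-by-minute confusion statistics
(sensitivity, specificity, positive predictive value, each with Wilson
95% CIs), per-panting-score agreement (empirical and predicted from a
binomial-logit mixed model with an animal random intercept), per-animal
panting-duration concordance (Pearson r, least-squares regression, Lin's
concordance correlation coefficient and its bias-correction factor C_b),
and Cohen's kappa for inter-observer reliability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.numdiff import approx_hess1

from .streams import PANTING

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# proportions and confusion counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Proportion:
    """A percentage with its Wilson 95% confidence interval."""

    pct: float
    ci: tuple[float, float]
    k: int
    n: int


def wilson_ci_pct(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for k/n, on the percentage scale.

    Clamped so it always contains the point estimate and stays in
    [0, 100] despite floating-point round-off at the boundaries.
    """
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    point = k / n
    lo = min(max(lo, 0.0), point)
    hi = max(min(hi, 1.0), point)
    return 100.0 * lo, 100.0 * hi


def _proportion(k: int, n: int) -> Proportion:
    return Proportion(100.0 * k / n, wilson_ci_pct(k, n), int(k), int(n))


@dataclass(frozen=True)
class ConfusionCounts:
    """Minute-level confusion counts with panting as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    stratum: str = "overall"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(kept: pd.DataFrame, ps: int | None = None) -> ConfusionCounts:
    """Cross-tabulate sensor panting against observed panting.

    ``ps=None`` uses every evaluated minute.  A PS stratum keeps only the
    observed minutes carrying that panting score; strata for PS >= 1 thus
    contain only observed-positive minutes (used for per-PS sensitivity).
    """
    df = kept
    if ps is not None:
        df = df[df["observed_ps"] == ps]
        if df.empty:
            raise ValueError(f"no evaluated minutes in PS stratum {ps}")
    obs_pos = (df["observed_ps"] >= 1).to_numpy()
    sen_pos = (df["sensor_state"] == PANTING).to_numpy()
    return ConfusionCounts(
        tp=int((obs_pos & sen_pos).sum()),
        fp=int((~obs_pos & sen_pos).sum()),
        tn=int((~obs_pos & ~sen_pos).sum()),
        fn=int((obs_pos & ~sen_pos).sum()),
        stratum="overall" if ps is None else f"PS{ps}",
    )


def sensitivity(c: ConfusionCounts) -> Proportion | None:
    """TP / (TP + FN) x 100; None when no observed-positive minutes exist."""
    n = c.tp + c.fn
    if n == 0:
        logger.warning("sensitivity undefined in stratum %s (no positives)", c.stratum)
        return None
    return _proportion(c.tp, n)


def specificity(c: ConfusionCounts) -> Proportion | None:
    """TN / (TN + FP) x 100; None when no observed-negative minutes exist."""
    n = c.tn + c.fp
    if n == 0:
        logger.warning("specificity undefined in stratum %s (no negatives)", c.stratum)
        return None
    return _proportion(c.tn, n)


def ppv(c: ConfusionCounts) -> Proportion | None:
    """TP / (TP + FP) x 100; None when the sensor never reported panting."""
    n = c.tp + c.fp
    if n == 0:
        logger.warning("PPV undefined in stratum %s (no sensor positives)", c.stratum)
        return None
    return _proportion(c.tp, n)


# ---------------------------------------------------------------------------
# agreement by panting score
# ---------------------------------------------------------------------------

def _agree_indicator(kept: pd.DataFrame) -> np.ndarray:
    """Minute-level agreement: for PS0 minutes the sensor must report
    non-panting, for PS >= 1 minutes it must report panting."""
    obs_pos = (kept["observed_ps"] >= 1).to_numpy()
    sen_pos = (kept["sensor_state"] == PANTING).to_numpy()
    return np.where(obs_pos, sen_pos, ~sen_pos)


def agreement_by_ps(kept: pd.DataFrame) -> dict[int, Proportion]:
    """Empirical percentage agreement per observed panting score."""
    agree = _agree_indicator(kept)
    out: dict[int, Proportion] = {}
    for ps_level, idx in kept.groupby("observed_ps").indices.items():
        out[int(ps_level)] = _proportion(int(agree[idx].sum()), len(idx))
    return out


# ---------------------------------------------------------------------------
# binomial-logit mixed model for agreement (PS fixed, animal random)
# ---------------------------------------------------------------------------

@dataclass
class AgreementGlmmResult:
    """Predicted (population-level) agreement per PS from the mixed model."""

    predicted: dict[int, float]
    se: dict[int, float]
    empirical: dict[int, float]
    sigma_animal: float
    converged: bool
    loglik: float
    message: str = ""
    params: np.ndarray = field(default=None, repr=False)


def _gh_loglik(params, X, y, group_slices, nodes, weights):
    """Marginal log-likelihood of a logistic random-intercept model,
    integrating the animal effect by Gauss-Hermite quadrature."""
    beta, sigma = params[:-1], params[-1]
    eta = X @ beta
    # eta_ik = eta_i + sqrt(2) * sigma * node_k  (n_obs x K)
    shift = np.sqrt(2.0) * sigma * nodes
    ll = 0.0
    logp = (
        y[:, None] * (eta[:, None] + shift[None, :])
        - np.logaddexp(0.0, eta[:, None] + shift[None, :])
    )
    for lo, hi in group_slices:
        per_node = logp[lo:hi].sum(axis=0)
        ll += special.logsumexp(per_node + np.log(weights)) - 0.5 * np.log(np.pi)
    return ll


def fit_agreement_glmm(
    kept: pd.DataFrame, n_quad: int = 25
) -> AgreementGlmmResult:
    """Fit agreement ~ PS with an animal random intercept (logit link).

    The agreement indicator (see :func:`agreement_by_ps`) is modelled as
    binomial with a fixed panting-score factor and a Gaussian random
    intercept per animal, fitted by maximum likelihood with Gauss-Hermite
    quadrature.  Returns back-transformed population-level (random effect
    at zero) predicted agreement per PS with delta-method standard errors.
    On non-convergence the empirical proportions are still reported.
    """
    animals = kept["animal_id"].unique()
    ps_levels = np.sort(kept["observed_ps"].unique())
    if len(animals) < 2:
        raise ValueError("agreement GLMM needs at least two animals")
    if len(ps_levels) < 2:
        raise ValueError("agreement GLMM needs at least two PS levels")

    df = kept.sort_values("animal_id", kind="stable")
    y = _agree_indicator(df).astype(float)
    # cell-mean coding: one column per PS level, so each beta is the
    # logit of that level's population agreement
    X = (df["observed_ps"].to_numpy()[:, None] == ps_levels[None, :]).astype(float)
    codes = pd.factorize(df["animal_id"].to_numpy())[0]
    counts = np.bincount(codes)
    bounds_idx = np.concatenate(([0], np.cumsum(counts)))
    group_slices = list(zip(bounds_idx[:-1], bounds_idx[1:]))
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    emp = {
        int(l): float(y[df["observed_ps"].to_numpy() == l].mean())
        for l in ps_levels
    }
    p0 = np.clip([emp[int(l)] for l in ps_levels], 1e-3, 1 - 1e-3)
    x0 = np.concatenate((special.logit(p0), [0.5]))

    def nll(p):
        return -_gh_loglik(p, X, y, group_slices, nodes, weights)

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None)] * len(ps_levels) + [(0.0, 10.0)],
    )
    beta = res.x[:-1]
    pred = special.expit(beta)
    # delta-method SEs on the probability scale
    se = np.full(len(ps_levels), np.nan)
    try:
        hess = approx_hess1(res.x, nll)
        cov = np.linalg.inv(hess)
        grad = pred * (1.0 - pred)
        se = grad * np.sqrt(np.clip(np.diag(cov)[: len(ps_levels)], 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate Hessian
        logger.warning("agreement GLMM: singular Hessian, SEs unavailable")
    if not res.success:
        logger.warning("agreement GLMM did not converge: %s", res.message)
    return AgreementGlmmResult(
        predicted={int(l): float(p) for l, p in zip(ps_levels, pred)},
        se={int(l): float(s) for l, s in zip(ps_levels, se)},
        empirical=emp,
        sigma_animal=float(res.x[-1]),
        converged=bool(res.success),
        loglik=float(-res.fun),
        message=str(res.message),
        params=res.x,
    )


# ---------------------------------------------------------------------------
# per-animal duration concordance
# ---------------------------------------------------------------------------

def duration_pairs(kept: pd.DataFrame) -> pd.DataFrame:
    """Per-animal totals of observed (PS >= 1) and sensor panting minutes
    over the evaluated minutes.  The raw/fill variant is a property of the
    sensor states joined upstream.  Animals with no evaluated minutes are
    simply absent."""
    g = kept.groupby("animal_id")
    out = pd.DataFrame(
        {
            "observed_min": g.apply(
                lambda d: int((d["observed_ps"] >= 1).sum()), include_groups=False
            ),
            "sensor_min": g.apply(
                lambda d: int((d["sensor_state"] == PANTING).sum()),
                include_groups=False,
            ),
        }
    ).reset_index()
    return out


@dataclass
class RegressionResult:
    r: float
    r_ci: tuple[float, float]
    r2: float
    slope: float
    intercept: float


def pearson_r(observed, sensor, alpha: float = 0.05) -> RegressionResult:
    """Pearson r with Fisher-z CI, plus the least-squares line of sensor
    duration on observed duration (the scatter-plot orientation)."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(sensor, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 duration pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in duration pairs")
    pr = stats.pearsonr(x, y)
    ci = pr.confidence_interval(confidence_level=1 - alpha)
    reg = stats.linregress(x, y)
    return RegressionResult(
        r=float(pr.statistic),
        r_ci=(float(ci.low), float(ci.high)),
        r2=float(pr.statistic) ** 2,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
    )


@dataclass
class CccResult:
    ccc: float
    ccc_ci: tuple[float, float]
    cb: float
    cb_ci: tuple[float, float]
    r: float


def _ccc_cb(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    mx, my = x.mean(), y.mean()
    sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    v = np.sqrt(sx2 / sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    cb = 2.0 / (v + 1.0 / v + u**2)
    r = sxy / np.sqrt(sx2 * sy2)
    return float(ccc), float(cb), float(r)


def lin_ccc(
    observed,
    sensor,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> CccResult:
    """Lin's concordance correlation coefficient and bias-correction factor.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) measures agreement
    with the identity line and factorises as CCC = r * C_b, where
    C_b = 2 / (v + 1/v + u^2) penalises scale (v = s_x/s_y) and location
    (u) shifts.  The CCC interval uses Lin's asymptotic z-transformation;
    C_b has no standard closed-form interval, so a seeded nonparametric
    bootstrap is used.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(sensor, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 duration pairs")
    if x.var(ddof=1) <= 0.0 or y.var(ddof=1) <= 0.0:
        raise ValueError("zero variance in duration pairs")
    ccc, cb, r = _ccc_cb(x, y)

    # Lin (1989) variance of z = atanh(CCC), written via C_b = CCC / r so
    # the degenerate r -> 0 limit stays finite
    u = (x.mean() - y.mean()) / (x.var(ddof=1) * y.var(ddof=1)) ** 0.25
    r2 = r**2
    c2 = ccc**2
    if 1.0 - c2 < 1e-12:
        ccc_ci = (float(ccc), float(ccc))
    else:
        denom = (1.0 - c2) ** 2
        var_z = (
            (1 - r2) * cb**2 / denom
            + 2 * r2 * cb**3 * (1 - ccc) * u**2 / denom
            - r2 * cb**4 * u**4 / (2 * denom)
        ) / (n - 2)
        z = np.arctanh(ccc)
        half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var_z, 0.0))
        ccc_ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))

    rng = np.random.default_rng(seed)
    cbs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            cbs[b] = np.nan
            continue
        cbs[b] = _ccc_cb(xb, yb)[1]
    lo, hi = np.nanpercentile(cbs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CccResult(ccc, ccc_ci, cb, (float(lo), float(hi)), r)


# ---------------------------------------------------------------------------
# inter-observer reliability
# ---------------------------------------------------------------------------

def cohens_kappa(rater_a, rater_b) -> float | None:
    """Cohen's kappa for two raters scoring the same minutes.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    product of the marginal category frequencies.  Undefined (None) when
    both raters used a single identical category throughout.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape:
        raise ValueError("raters must score identical minutes")
    n = a.size
    if n == 0:
        raise ValueError("no ratings")
    cats = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for c in cats:
        p_e += float(np.mean(a == c)) * float(np.mean(b == c))
    if p_e >= 1.0:
        logger.warning("kappa undefined: a single category in both raters")
        return None
    return (p_o - p_e) / (1.0 - p_e)
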