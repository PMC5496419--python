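"""Statistical machinery against closed forms and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from traumascore.registry import PatientRecord, Registry
from traumascore.stats import (
    SeparationError,
    auc,
    binned_mortality,
    delong_compare,
    describe_cohort,
    fit_logistic,
    hosmer_lemeshow,
    operating_point,
    univariate_or,
)


# ---------------------------------------------------------------- logistic

def test_intercept_only_closed_form():
    # 30% events at every level of x: the MLE slope is exactly 0 and the
    # intercept the marginal log-odds log(0.3/0.7)
    x = np.repeat(np.linspace(-1, 1, 10), 10)
    y = np.tile([1.0] * 3 + [0.0] * 7, 10)
    model = fit_logistic(pd.DataFrame({"x": x}), y)
    assert model.intercept == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)
    assert model.coefficients["x"] == pytest.approx(0.0, abs=1e-6)
    assert model.converged


def test_perfect_separation_detected():
    x = np.concatenate([np.linspace(-2, -0.1, 20), np.linspace(0.1, 2, 20)])
    y = (x > 0).astype(float)
    with pytest.raises(SeparationError):
        fit_logistic(pd.DataFrame({"x": x}), y)


def test_constant_covariate_and_single_class_rejected():
    y = np.array([0.0, 1.0] * 10)
    with pytest.raises(ValueError, match="constant"):
        fit_logistic(pd.DataFrame({"x": np.ones(20)}), y)
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(pd.DataFrame({"x": np.arange(20.0)}), np.ones(20))


def test_covariance_symmetric_psd_and_se_consistent(complete_cohort, rng):
    df = complete_cohort.df
    y = (~df["died"].astype(bool)).astype(float)
    model = fit_logistic(df[["gcs", "sbp", "spo2"]], y)
    cov = model.covariance.to_numpy()
    np.testing.assert_allclose(cov, cov.T, atol=1e-12)
    assert (np.linalg.eigvalsh(cov) > -1e-12).all()
    for i, name in enumerate(model.covariance.columns):
        assert model.standard_errors[name] == pytest.approx(math.sqrt(cov[i, i]))


# ------------------------------------------------------------- odds ratios

def test_two_by_two_odds_ratio_cross_product():
    # exposed: 10 events / 90 non-events; unexposed: 50 / 50
    x = np.array([1.0] * 100 + [0.0] * 100)
    y = np.array([1.0] * 10 + [0.0] * 90 + [1.0] * 50 + [0.0] * 50)
    result = univariate_or(x, y)
    assert result.odds_ratio == pytest.approx((10 / 90) / (50 / 50), rel=1e-4)
    assert result.ci_low <= result.odds_ratio <= result.ci_high


def test_affine_reparameterisation_identity(rng):
    x = rng.normal(size=400)
    y = (rng.random(400) < 1 / (1 + np.exp(-x))).astype(float)
    or1 = univariate_or(x, y).odds_ratio
    or2 = univariate_or(2 * x, y).odds_ratio
    assert or2 == pytest.approx(or1 ** 0.5, rel=1e-6)


def test_categorical_ors_match_contingency_oracle(rng):
    codes = rng.integers(0, 5, 2000)
    base = np.array([0.75, 0.45, 0.25, 0.12, 0.04])  # death probability by code
    died = (rng.random(2000) < base[codes]).astype(float)
    results = univariate_or(codes, died, categorical=True, reference=4)
    for level, res in results.items():
        a = ((codes == level) & (died == 1)).sum()
        b = ((codes == level) & (died == 0)).sum()
        c = ((codes == 4) & (died == 1)).sum()
        d = ((codes == 4) & (died == 0)).sum()
        assert res.odds_ratio == pytest.approx((a / b) / (c / d), rel=1e-6)


# -------------------------------------------------------------------- AUC

def test_auc_trivial_cases():
    y = np.array([1.0, 1.0, 0.0, 0.0])
    assert auc([4, 3, 2, 1], y) == 1.0
    assert auc([1, 2, 3, 4], y) == 0.0
    assert auc([1, 1, 1, 1], y) == 0.5


def _auc_pair_counting(s, y):
    s, y = np.asarray(s, float), np.asarray(y, float)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_equals_pair_counting_oracle(rng):
    for _ in range(10):
        s = np.round(rng.normal(size=200), 1)  # rounding forces ties
        y = (rng.random(200) < 0.3).astype(float)
        if y.min() == y.max():
            continue
        assert auc(s, y) == pytest.approx(_auc_pair_counting(s, y), abs=1e-12)


def test_auc_invariant_under_strictly_increasing_transforms(rng):
    s = rng.normal(size=300)
    y = (rng.random(300) < 0.25).astype(float)
    base = auc(s, y)
    assert auc(np.exp(s), y) == pytest.approx(base, abs=1e-12)
    assert auc(3.0 * s + 7.0, y) == pytest.approx(base, abs=1e-12)
    assert auc(s, y) + auc(-s, y) == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------------ DeLong

def test_delong_identical_scores_degenerate():
    rng = np.random.default_rng(5)
    s = rng.normal(size=100)
    y = (rng.random(100) < 0.4).astype(float)
    r = delong_compare(s, s, y)
    assert r.difference == 0.0 and r.p == 1.0


def test_delong_antisymmetry(rng):
    lat = rng.normal(size=300)
    y = (rng.random(300) < 1 / (1 + np.exp(-lat))).astype(float)
    a = lat + rng.normal(size=300)
    b = lat + rng.normal(size=300)
    r1 = delong_compare(a, b, y)
    r2 = delong_compare(b, a, y)
    assert r1.difference == pytest.approx(-r2.difference, abs=1e-15)
    assert r1.p == pytest.approx(r2.p, abs=1e-12)
    assert r1.difference == pytest.approx(r1.auc_a - r1.auc_b, abs=1e-15)


def _delong_oracle(a, b, y):
    """O(n^2) placement-value DeLong implementation."""
    a, b, y = map(np.asarray, (a, b, y))
    pos, neg = y == 1, y == 0
    m, n = pos.sum(), neg.sum()

    def placements(s):
        sp, sn = s[pos], s[neg]
        v10 = np.array([((x > sn) + 0.5 * (x == sn)).mean() for x in sp])
        v01 = np.array([((sp > x) + 0.5 * (sp == x)).mean() for x in sn])
        return v10, v01

    va10, va01 = placements(a)
    vb10, vb01 = placements(b)
    auc_a, auc_b = va10.mean(), vb10.mean()
    s10 = np.cov(np.vstack([va10, vb10]))
    s01 = np.cov(np.vstack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    z = (auc_a - auc_b) / math.sqrt(var)
    return auc_a - auc_b, z, 2 * sps.norm.sf(abs(z))


def test_delong_matches_quadratic_oracle(rng):
    lat = rng.normal(size=150)
    y = (rng.random(150) < 1 / (1 + np.exp(-lat))).astype(float)
    a = np.round(lat + rng.normal(size=150), 1)
    b = np.round(lat + rng.normal(size=150), 1)
    r = delong_compare(a, b, y)
    diff, z, p = _delong_oracle(a, b, y)
    assert r.difference == pytest.approx(diff, abs=1e-12)
    assert r.z == pytest.approx(z, abs=1e-9)
    assert r.p == pytest.approx(p, abs=1e-9)


def test_delong_length_mismatch_and_single_class():
    with pytest.raises(ValueError):
        delong_compare([1, 2], [1, 2, 3], [1, 0, 1])
    with pytest.raises(ValueError):
        delong_compare([1, 2], [2, 1], [1, 1])


# --------------------------------------------------------- Hosmer-Lemeshow

def test_hl_zero_when_perfectly_calibrated():
    # two risk groups whose event proportions equal their predictions
    p = np.array([0.2] * 10 + [0.8] * 10)
    y = np.array([1.0] * 2 + [0.0] * 8 + [1.0] * 8 + [0.0] * 2)
    res = hosmer_lemeshow(p, y, n_groups=2)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)


def test_hl_matches_hand_arithmetic_two_groups():
    p = np.array([0.2] * 10 + [0.8] * 10)
    y = np.array([1.0] * 3 + [0.0] * 7 + [1.0] * 7 + [0.0] * 3)
    res = hosmer_lemeshow(p, y, n_groups=2)
    # group 1: O=3, E=2, pbar=0.2 -> 1/(2*0.8) = 0.625; group 2 symmetric
    assert res.chi2 == pytest.approx(1.25, abs=1e-10)
    assert res.df == 0 and math.isnan(res.p)
    assert res.observed.tolist() == [3, 7]
    assert res.expected.tolist() == pytest.approx([2.0, 8.0])


def test_hl_rejects_miscalibrated_predictions(rng):
    lat = rng.normal(size=3000)
    y = (rng.random(3000) < 1 / (1 + np.exp(-lat))).astype(float)
    miscal = 1 / (1 + np.exp(-2.5 * lat))  # overconfident
    res = hosmer_lemeshow(miscal, y)
    assert res.p < 1e-6
    assert res.df == res.n_groups - 2


def test_hl_input_validation():
    with pytest.raises(ValueError):
        hosmer_lemeshow([0.0, 0.5], [0, 1])
    with pytest.raises(ValueError):
        hosmer_lemeshow([0.4, 0.5], [0, 1], n_groups=1)


# --------------------------------------------------------- operating point

def test_operating_point_perfect_and_constant_scores():
    y = np.array([1.0] * 5 + [0.0] * 15)
    perfect = np.concatenate([np.zeros(5), np.ones(15)])  # survival-oriented
    op = operating_point(perfect, y)
    assert op.sensitivity == 1.0 and op.specificity == 1.0
    constant = np.ones(20)
    op2 = operating_point(constant, y)
    assert op2.sensitivity == 1.0 and op2.specificity == 0.0 and op2.all_positive


def _operating_point_oracle(s, y, target):
    s, y = np.asarray(s, float), np.asarray(y, float)
    best = (np.inf, 1.0, 0.0)
    for t in list(np.unique(s)) + [s.max() + 1]:
        sens = (s[y == 1] < t).mean()
        spec = (s[y == 0] >= t).mean()
        if sens >= target and spec > best[2]:
            best = (t, sens, spec)
    return best


@pytest.mark.parametrize("target", [0.80, 0.85, 0.90])
def test_operating_point_matches_brute_force_on_t_nts(complete_cohort, target):
    from traumascore.scores import TraumaScorer

    scored = TraumaScorer().transform(complete_cohort.df)
    died = scored["died"].astype(float).to_numpy()
    s = scored["t_nts"].to_numpy(dtype=float)
    op = operating_point(s, died, target)
    t, sens, spec = _operating_point_oracle(s, died, target)
    assert op.threshold == t
    assert op.sensitivity == pytest.approx(sens) and op.specificity == pytest.approx(spec)
    assert op.sensitivity >= target and op.specificity > 0


# --------------------------------------------------------- binned mortality

def test_binned_mortality_aggregation_and_empty_bins():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 0.0, 1.0, 1.0])
    one = binned_mortality(v, y, [0, 10])
    assert one["count"].tolist() == [4] and one["mortality"].iloc[0] == 0.75
    many = binned_mortality(v, y, [0, 2, 5, 10])
    assert many["count"].tolist() == [1, 3, 0]
    assert math.isnan(many["mortality"].iloc[2])
    with pytest.raises(ValueError):
        binned_mortality(v, y, [2, 3])  # values fall outside
    with pytest.raises(ValueError):
        binned_mortality(v, y, [0, 0, 10])


def test_binned_mortality_bimodal_sbp_shape(complete_cohort):
    df = complete_cohort.df
    res = binned_mortality(df["sbp"], df["died"].astype(float), [0, 70, 90, 110, 150, 400])
    # hypertensive band (>=150, NTS code 3) deadlier than the normotensive
    # code-4 band, and mortality rises monotonically as SBP falls below 110
    assert res["mortality"].iloc[4] > res["mortality"].iloc[3]
    assert res["mortality"].iloc[0] > res["mortality"].iloc[1] > res["mortality"].iloc[2]


# ------------------------------------------------------------ describe

def _tiny_registry(ages, died=None, n=None):
    n = n or len(ages)
    died = died or [False] * n
    recs = [
        PatientRecord(age=int(a), sex="male", mechanism="blunt", gcs=15, sbp=130.0,
                      rr=20.0, spo2=98.0, iss=9, died=d)
        for a, d in zip(ages, died)
    ]
    return Registry.from_records(recs)


def test_describe_identical_cohorts_all_null(complete_cohort):
    table = describe_cohort(complete_cohort, complete_cohort)
    assert (table["p"].dropna() >= 0.99).all()


def test_describe_detects_location_shift(rng):
    a = _tiny_registry(np.round(rng.normal(60, 10, 1000)))
    b = _tiny_registry(np.round(rng.normal(70, 10, 1000)))  # shift = 1 SD
    table = describe_cohort(a, b).set_index("variable")
    assert table.loc["age", "p"] < 0.001


def test_describe_median_iqr_matches_quantile_oracle(rng):
    ages = np.round(rng.normal(60, 15, 501)).clip(15, 100)
    reg = _tiny_registry(ages)
    table = describe_cohort(reg, reg).set_index("variable")
    q1, med, q3 = np.percentile(ages, [25, 50, 75])
    assert table.loc["age", "summary_a"] == f"{med:g} ({q1:g}-{q3:g})"
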