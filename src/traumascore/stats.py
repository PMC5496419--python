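"""Statistical machinery for score derivation and validation.

Logistic regression (via IRLS), univariate odds ratios, the midrank AUC,
DeLong's test for paired ROC curves, the Hosmer-Lemeshow calibration
statistic, 95%-sensitivity operating points, binned mortality and a
two-cohort descriptive comparison.

Outcome orientation: the regression outcome is SURVIVAL (1 = survived),
which makes the published odds ratios (> 1 for higher GCS/SBP/SpO2 codes)
and the Ps equation's signs consistent.  Triage positivity for
survival-oriented scores is ``score < threshold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "LogisticModel",
    "OddsRatioResult",
    "RocComparison",
    "CalibrationResult",
    "OperatingPoint",
    "SeparationError",
    "fit_logistic",
    "univariate_or",
    "auc",
    "delong_compare",
    "hosmer_lemeshow",
    "operating_point",
    "binned_mortality",
    "describe_cohort",
]

_Z975 = sps.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """The likelihood is unbounded: a covariate perfectly separates the outcome."""


@dataclass
class LogisticModel:
    """A fitted binary logistic regression.

    ``coefficients``/``standard_errors`` are keyed by covariate name; the
    intercept is stored separately (its SE under the key ``const``).
    ``covariance`` is the inverse observed information, rows/columns
    ``const`` + covariates.
    """

    intercept: float
    coefficients: dict
    standard_errors: dict
    covariance: pd.DataFrame
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int

    @property
    def names(self) -> list:
        return list(self.coefficients)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            lp += beta * X[name].to_numpy(dtype=float)
        return lp

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class RocComparison:
    auc_a: float
    auc_b: float
    difference: float
    z: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CalibrationResult:
    n_groups: int
    observed: np.ndarray
    expected: np.ndarray
    group_sizes: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    all_positive: bool = False


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y).astype(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    return y


def fit_logistic(design: pd.DataFrame, outcome) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    ``design`` holds named covariates (no intercept column: one is added).
    Raises :class:`SeparationError` on perfect separation and ValueError on
    degenerate inputs (single-class outcome, constant covariates).
    """
    y = _as_binary(outcome)
    X = pd.DataFrame(design).astype(float)
    if len(X) != len(y):
        raise ValueError("design and outcome lengths differ")
    stds = X.std(axis=0)
    constant = [c for c in X.columns if stds[c] == 0]
    if constant:
        raise ValueError(f"constant covariate columns besides the intercept: {constant}")
    Xc = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc
    mu = np.asarray(res.fittedvalues)
    if np.abs(res.params).max() > 1e2 or mu.min() < 1e-10 or mu.max() > 1 - 1e-10:
        raise SeparationError("estimates diverged; data are (quasi-)separated")
    params = res.params
    se = res.bse
    cov = pd.DataFrame(res.cov_params(), index=params.index, columns=params.index)
    names = [c for c in params.index if c != "const"]
    return LogisticModel(
        intercept=float(params["const"]),
        coefficients={n: float(params[n]) for n in names},
        standard_errors={n: float(se[n]) for n in params.index},
        covariance=cov,
        converged=bool(res.converged),
        n_iterations=int(res.fit_history["iteration"]),
        log_likelihood=float(res.llf),
        n_obs=int(res.nobs),
    )


def univariate_or(x, outcome, *, categorical: bool = False, reference=None):
    """Single-covariate logistic odds ratios with Wald 95% CIs.

    Continuous mode returns one :class:`OddsRatioResult` per unit increase.
    Categorical mode fits indicator terms against ``reference`` and returns
    a dict level -> result.
    """
    y = _as_binary(outcome)
    x = np.asarray(x)
    if not categorical:
        model = fit_logistic(pd.DataFrame({"x": x.astype(float)}), y)
        beta, se = model.coefficients["x"], model.standard_errors["x"]
        return _wald_or(beta, se)
    levels = [lv for lv in pd.unique(x) if lv != reference]
    if reference not in set(x):
        raise ValueError(f"reference level {reference!r} absent")
    for lv in levels:
        if not ((x == lv) & (y == 1)).any() or not ((x == lv) & (y == 0)).any():
            raise SeparationError(f"level {lv!r} has a single outcome class")
    design = pd.DataFrame({f"level_{lv}": (x == lv).astype(float) for lv in sorted(levels)})
    model = fit_logistic(design, y)
    return {
        lv: _wald_or(model.coefficients[f"level_{lv}"], model.standard_errors[f"level_{lv}"])
        for lv in sorted(levels)
    }


def _wald_or(beta: float, se: float) -> OddsRatioResult:
    z = beta / se
    p = 2 * sps.norm.sf(abs(z))
    return OddsRatioResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p=float(p),
    )


def auc(scores, outcome) -> float:
    """Area under the ROC curve by the midrank (Mann-Whitney) convention.

    The probability that a random positive-outcome subject scores above a
    random negative-outcome subject, ties counted one half.
    """
    y = _as_binary(outcome)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and outcome lengths differ")
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = sps.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _placements(s: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (placement values) for one score."""
    n1, n0 = int(pos.sum()), int((~pos).sum())
    all_ranks = sps.rankdata(s)
    pos_ranks = sps.rankdata(s[pos])
    neg_ranks = sps.rankdata(s[~pos])
    v10 = (all_ranks[pos] - pos_ranks) / n0          # per-case placement
    v01 = 1.0 - (all_ranks[~pos] - neg_ranks) / n1   # per-control placement
    return v10, v01


def delong_compare(scores_a, scores_b, outcome) -> RocComparison:
    """DeLong's nonparametric comparison of two correlated AUCs.

    Scores must be paired on the same subjects.  Two-sided z-test on the
    AUC difference with a 95% Wald CI.
    """
    y = _as_binary(outcome)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("paired scores and outcome must have equal length")
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    v10 = np.vstack([_placements(a, pos)[0], _placements(b, pos)[0]])
    v01 = np.vstack([_placements(a, pos)[1], _placements(b, pos)[1]])
    aucs = v10.mean(axis=1)
    s10 = np.cov(v10) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n0 > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    diff = float(aucs[0] - aucs[1])
    if var <= 0 or np.isclose(var, 0.0, atol=1e-16):
        z = 0.0 if np.isclose(diff, 0.0) else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if np.isinf(z) and diff == 0 else float(2 * sps.norm.sf(abs(z)))
    half = _Z975 * np.sqrt(max(var, 0.0))
    return RocComparison(
        auc_a=float(aucs[0]),
        auc_b=float(aucs[1]),
        difference=diff,
        z=float(z),
        p=p,
        ci_low=diff - half,
        ci_high=diff + half,
    )


def hosmer_lemeshow(predicted, outcome, n_groups: int = 10, ties: str = "split") -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over equal-count risk groups.

    chi2 = sum_g (O_g - E_g)^2 / (E_g (1 - pbar_g)), pbar_g = E_g / n_g,
    with df = g - 2 (NaN p when fewer than 3 groups remain).

    ``ties="split"`` (default) forms g equal-count groups by rank, splitting
    tied predictions across group boundaries; this keeps g at ``n_groups``
    and the chi2_{g-2} reference well calibrated even for heavily tied
    (discrete) scores.  ``ties="merge"`` groups by quantiles of the
    predictions with tied values kept together, which can collapse g well
    below ``n_groups`` and makes the test conservative under heavy ties —
    it matches the grouping that clinical software commonly reports.
    """
    y = _as_binary(outcome)
    p = np.asarray(predicted, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("predictions must lie strictly in (0, 1)")
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if ties == "split":
        order = np.argsort(p, kind="mergesort")
        chunks = [c for c in np.array_split(order, min(n_groups, len(p))) if len(c)]
        groups = np.empty(len(p), dtype=int)
        for k, idx in enumerate(chunks):
            groups[idx] = k
        g = len(chunks)
    elif ties == "merge":
        groups = pd.qcut(p, n_groups, labels=False, duplicates="drop")
        g = int(groups.max()) + 1
    else:
        raise ValueError("ties must be 'split' or 'merge'")
    obs = np.zeros(g)
    exp = np.zeros(g)
    sizes = np.zeros(g)
    for k in range(g):
        mask = groups == k
        if not mask.any():
            raise ValueError("empty risk group after tie-merging")
        sizes[k] = mask.sum()
        obs[k] = y[mask].sum()
        exp[k] = p[mask].sum()
    pbar = exp / sizes
    chi2 = float((((obs - exp) ** 2) / (exp * (1 - pbar))).sum())
    df = g - 2
    pval = float(sps.chi2.sf(chi2, df)) if df >= 1 else float("nan")
    return CalibrationResult(
        n_groups=g, observed=obs, expected=exp, group_sizes=sizes, chi2=chi2, df=df, p=pval
    )


def operating_point(scores, outcome, target_sensitivity: float = 0.95) -> OperatingPoint:
    """Highest-specificity threshold whose sensitivity meets the target.

    ``outcome`` marks the event (death); ``scores`` are survival-oriented
    (lower = sicker), so a subject is triage-positive when
    ``score < threshold``.  Among thresholds with sensitivity >= target the
    one maximising specificity is returned; if only the all-positive rule
    qualifies, it is flagged.
    """
    y = _as_binary(outcome)
    s = np.asarray(scores, dtype=float)
    events = np.sort(s[y == 1])
    nonevents = np.sort(s[y == 0])
    candidates = np.concatenate([np.unique(s), [np.nextafter(s.max(), np.inf)]])
    sens = np.searchsorted(events, candidates, side="left") / len(events)
    spec = 1.0 - np.searchsorted(nonevents, candidates, side="left") / len(nonevents)
    ok = sens >= target_sensitivity
    if not ok.any():  # unattainable only in pathological float cases
        return OperatingPoint(threshold=np.inf, sensitivity=1.0, specificity=0.0, all_positive=True)
    idx = np.flatnonzero(ok)[np.argmax(spec[ok])]
    return OperatingPoint(
        threshold=float(candidates[idx]),
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
        all_positive=spec[idx] == 0.0,
    )


def binned_mortality(values, outcome, bin_edges) -> pd.DataFrame:
    """Per-bin count, deaths and death proportion over [edge_i, edge_{i+1}) bins.

    ``outcome`` marks death.  Mortality is NaN for empty bins; values
    outside all bins raise.
    """
    y = np.asarray(outcome).astype(float)
    v = np.asarray(values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    if (v < edges[0]).any() or (v >= edges[-1]).any():
        raise ValueError("values outside the binning range")
    idx = np.digitize(v, edges) - 1
    nbins = len(edges) - 1
    count = np.bincount(idx, minlength=nbins).astype(float)
    deaths = np.bincount(idx, weights=y, minlength=nbins)
    with np.errstate(invalid="ignore"):
        mortality = np.where(count > 0, deaths / np.where(count > 0, count, 1), np.nan)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": count.astype(int),
         "deaths": deaths.astype(int), "mortality": mortality}
    )


_CONTINUOUS = ("age", "gcs", "sbp", "rr", "spo2", "iss")
_CATEGORICAL = (("sex", "male"), ("mechanism", "blunt"), ("died", True))


def describe_cohort(a, b) -> pd.DataFrame:
    """Two-cohort descriptive comparison table.

    Continuous variables: median (IQR) and the Mann-Whitney U test (normal
    approximation with tie correction).  Categorical: n (%) and the chi2
    test.  Missing cells are dropped per variable.
    """
    rows = []
    for var in _CONTINUOUS:
        xa = a.df[var].dropna().to_numpy(dtype=float)
        xb = b.df[var].dropna().to_numpy(dtype=float)
        if len(xa) == 0 or len(xb) == 0:
            continue
        stat = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "summary_a": _median_iqr(xa),
                "summary_b": _median_iqr(xb),
                "test": "mann-whitney",
                "p": float(stat.pvalue),
            }
        )
    for var, level in _CATEGORICAL:
        ca = int((a.df[var] == level).sum())
        cb = int((b.df[var] == level).sum())
        na, nb = len(a.df), len(b.df)
        table = np.array([[ca, na - ca], [cb, nb - cb]])
        if (table.sum(axis=0) == 0).any():
            p = float("nan")
        else:
            p = float(sps.chi2_contingency(table)[1])
        rows.append(
            {
                "variable": f"{var}={level}",
                "type": "categorical",
                "summary_a": f"{ca} ({100 * ca / na:.1f}%)",
                "summary_b": f"{cb} ({100 * cb / nb:.1f}%)",
                "test": "chi2",
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"
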