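"""Synthetic trauma-registry generator.

Emulates a single-centre adult trauma cohort: mostly blunt injuries with
normal admission vitals (median GCS 15, RR 20, SpO2 98%, SBP 130 mmHg) and
an overall in-hospital mortality near 11.3%.  Covariates come from a
two-component mixture so that deranged vitals co-occur:

* a **stable** component concentrated at normal physiology, producing the
  degenerate cohort medians (GCS 15, RR 20, SpO2 98);
* an **injured** component with depressed GCS and SpO2 and dispersed SBP,
  including hypotensive and hypertensive (>= 150 mmHg) tails — the latter
  reproduces the bimodal SBP-mortality pattern seen in head-injury-heavy
  cohorts, via the NTS code 3-vs-4 gap rather than an extra model term.

Survival is drawn Bernoulli(Ps) where Ps is the published NTS logistic
model of GCS, SBP code and SpO2 code, so the generator's outcome law *is*
the model the derivation machinery should recover.  Missingness is
injected completely at random at the cohort's reported per-variable rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import CODING_TABLES, _banded
from .registry import CANONICAL_COLUMNS, Registry
from .scores import ScoreCoefficients

__all__ = ["CohortSpec", "default_cohort_spec", "simulate_registry", "inject_missingness"]

# Stable-component discrete vitals (integer support, probabilities sum to 1).
_STABLE_GCS = ((15, 0.97), (14, 0.02), (13, 0.01))
_STABLE_RR = ((16, 0.05), (18, 0.25), (20, 0.60), (22, 0.05), (24, 0.05))
_STABLE_SPO2 = ((94, 0.04), (95, 0.04), (96, 0.14), (97, 0.18), (98, 0.30), (99, 0.22), (100, 0.08))
# Injured-component GCS: head-injury-heavy, skewed low but with many alert patients.
_INJ_GCS = (
    (3, 0.18), (4, 0.07), (5, 0.06), (6, 0.06), (7, 0.06), (8, 0.06), (9, 0.05),
    (10, 0.05), (11, 0.05), (12, 0.05), (13, 0.08), (14, 0.08), (15, 0.15),
)
# Injured SBP sub-mixture: hypotensive / normotensive / hypertensive.
_INJ_SBP = ((0.25, 85.0, 20.0), (0.55, 125.0, 18.0), (0.20, 168.0, 18.0))


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings; defaults reproduce the derivation-cohort marginals.

    ``severe_fraction`` is the injured-component mixing weight, calibrated
    once so that the Bernoulli(Ps) outcome law yields ~11.3% mortality,
    then frozen.  ``quantile_targets`` documents the marginal targets the
    defaults aim at (median, q1, q3); it is descriptive, not enforced.
    """

    n: int = 3263
    male_fraction: float = 0.66
    blunt_fraction: float = 0.944
    severe_fraction: float = 0.20
    outcome_coefficients: ScoreCoefficients = field(default_factory=ScoreCoefficients)
    missingness: dict = field(
        default_factory=lambda: {"spo2": 0.032, "iss": 0.089, "sbp": 0.001, "rr": 0.001, "gcs": 0.001}
    )
    quantile_targets: dict = field(
        default_factory=lambda: {
            "age": (60, 46, 73),
            "sbp": (130, 110, 140),
            "rr": (20, 18, 20),
            "gcs": (15, 15, 15),
            "spo2": (98, 96, 99),
            "iss": (9, 4, 13),
        }
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("male_fraction", "blunt_fraction", "severe_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for var, rate in self.missingness.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missingness rate for {var} must lie in [0, 1), got {rate!r}")
        for var, (med, q1, q3) in self.quantile_targets.items():
            if not q1 <= med <= q3:
                raise ValueError(f"quantile targets for {var} must be ordered q1 <= median <= q3")


def default_cohort_spec(n: int = 3263, seed: int = 0) -> CohortSpec:
    """The frozen derivation-cohort spec (Table-2-style marginals, 11.3% mortality)."""
    return CohortSpec(n=n, seed=seed)


def _draw_discrete(rng: np.random.Generator, pmf, size: int) -> np.ndarray:
    values = np.array([v for v, _ in pmf], dtype=float)
    probs = np.array([p for _, p in pmf], dtype=float)
    return rng.choice(values, size=size, p=probs / probs.sum())


def simulate_registry(spec: CohortSpec) -> Registry:
    """Draw a complete synthetic registry, then inject MCAR missingness.

    Fully reproducible from ``spec.seed``.  With ``severe_fraction`` 0 the
    cohort is all-stable (near-zero mortality); that is flagged as a
    warning in the registry label rather than an error.
    """
    if spec.n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    injured = rng.random(n) < spec.severe_fraction

    gcs = np.where(
        injured, _draw_discrete(rng, _INJ_GCS, n), _draw_discrete(rng, _STABLE_GCS, n)
    )
    rr = np.where(
        injured,
        np.clip(np.round(rng.normal(24.0, 8.0, n)), 0, 60),
        _draw_discrete(rng, _STABLE_RR, n),
    )
    spo2 = np.where(
        injured,
        np.clip(np.round(rng.normal(78.0, 18.0, n)), 30, 100),
        _draw_discrete(rng, _STABLE_SPO2, n),
    )
    comp = rng.random(n)
    weights = np.cumsum([w for w, _, _ in _INJ_SBP])
    inj_sbp = np.empty(n)
    prev = 0.0
    for (w, mu, sd), upper in zip(_INJ_SBP, weights):
        mask = (comp >= prev) & (comp < upper)
        inj_sbp[mask] = rng.normal(mu, sd, n)[mask]
        prev = upper
    sbp = np.where(injured, np.clip(np.round(inj_sbp), 0, 260), np.clip(np.round(rng.normal(130.0, 19.0, n)), 60, 260))
    iss = np.clip(
        np.round(np.exp(rng.normal(np.where(injured, np.log(16.0), np.log(8.0)), 0.6, n))), 1, 75
    )
    age = np.clip(np.round(rng.normal(59.5, 19.0, n)), 15, 100)
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    mechanism = np.where(rng.random(n) < spec.blunt_fraction, "blunt", "penetrating")

    coef = spec.outcome_coefficients
    sbp_code = _banded(sbp, CODING_TABLES["sbp_nts"])
    spo2_code = _banded(spo2, CODING_TABLES["spo2_nts"])
    b = coef.nts_b0 + coef.nts_b_gcs * gcs + coef.nts_b_sbp * sbp_code + coef.nts_b_spo2 * spo2_code
    ps = 1.0 / (1.0 + np.exp(-b))
    died = rng.random(n) < (1.0 - ps)

    label = "synthetic-derivation"
    if spec.severe_fraction == 0:
        label += " (warning: severe_fraction 0; mortality will be near zero)"
    df = pd.DataFrame(
        {
            "age": age.astype(int),
            "sex": sex,
            "mechanism": mechanism,
            "gcs": gcs,
            "sbp": sbp,
            "rr": rr,
            "spo2": spo2,
            "iss": iss,
            "died": died,
            "spo2_nm": np.zeros(n, dtype=bool),
        },
        columns=list(CANONICAL_COLUMNS) + ["spo2_nm"],
    )
    registry = Registry(df, label)
    if any(rate > 0 for rate in spec.missingness.values()):
        registry = inject_missingness(
            registry, spec.missingness, seed=int(rng.integers(0, 2**31 - 1))
        )
        registry.label = label
    return registry


def inject_missingness(registry: Registry, rates: dict, seed: int = 0) -> Registry:
    """Mask cells completely at random at per-variable rates (new Registry)."""
    for var, rate in rates.items():
        if not 0 <= rate < 1:
            raise ValueError(f"rate for {var} must lie in [0, 1), got {rate!r}")
    rng = np.random.default_rng(seed)
    df = registry.df.copy()
    for var, rate in rates.items():
        if rate == 0:
            continue
        mask = rng.random(len(df)) < rate
        df.loc[mask, var] = np.nan
    return Registry(df, registry.label, list(registry.rejected))
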