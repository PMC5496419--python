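"""The scoring equations: RTS, NTS, Ps, T-NTS, risk strata, MGAP and GAP.

RTS = 0.9368·GCS_code + 0.7326·SBP_code + 0.2908·RR_code  (max 7.8408).

NTS = b1·GCS + b2·SBP_NTS + b3·SpO2_NTS with the published logistic
coefficients b = (0.4006, 0.2983, 0.8709); the survival probability is
Ps = 1/(1 + e^{-b}), b = b0 + NTS, b0 = −6.5406.  T-NTS drops the
coefficients entirely: GCS + SBP_NTS + SpO2_NTS, an integer in [3, 23],
with triage transfer indicated below 18.

MGAP and GAP are comparator scores; their point assignments come from
their source publications and are frozen in ``MGAP_POINTS``/``GAP_POINTS``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import coding
from .registry import PatientRecord

__all__ = [
    "ScoreCoefficients",
    "ScorePanel",
    "MissingVitalsError",
    "TRIAGE_CUTOFF",
    "RISK_STRATA",
    "rts",
    "nts",
    "ps",
    "t_nts",
    "risk_stratum",
    "triage_transfer",
    "mgap",
    "gap",
    "score_panel",
    "TraumaScorer",
]

#: T-NTS below this transfers the patient to a trauma centre.
TRIAGE_CUTOFF = 18
#: Risk strata over the T-NTS range [3, 23] (inclusive bounds).
RISK_STRATA = (("low", 18, 23), ("intermediate", 12, 17), ("high", 6, 11), ("very_high", 3, 5))

#: MGAP point table (from its source publication): GCS is added as-is,
#: age < 60 earns 5, blunt mechanism 4, SBP >=120 / 60-119 / <60 earn 5/3/0.
MGAP_POINTS = {"age_lt_60": 5, "blunt": 4, "sbp_high": (120.0, 5), "sbp_mid": (60.0, 3)}
#: GAP point table: age < 60 earns 3, SBP >120 / 60-120 / <60 earn 6/4/0.
GAP_POINTS = {"age_lt_60": 3, "sbp_high": (120.0, 6), "sbp_mid": (60.0, 4)}


class MissingVitalsError(ValueError):
    """A score was requested for a record lacking a required vital."""


@dataclass(frozen=True)
class ScoreCoefficients:
    """RTS weights and NTS logistic coefficients.

    Defaults are the published values; the derivation pipeline can override
    them from a refitted survival model so that ``nts``/``ps`` reproduce
    that model's linear predictor exactly.
    """

    rts_weights: tuple = (0.9368, 0.7326, 0.2908)
    nts_b0: float = -6.5406
    nts_b_gcs: float = 0.4006
    nts_b_sbp: float = 0.2983
    nts_b_spo2: float = 0.8709

    @classmethod
    def from_logistic_model(cls, model) -> "ScoreCoefficients":
        """Adopt intercept and slopes from a fitted survival LogisticModel
        with covariates named gcs, sbp_code_nts, spo2_code_nts."""
        return cls(
            nts_b0=model.intercept,
            nts_b_gcs=model.coefficients["gcs"],
            nts_b_sbp=model.coefficients["sbp_code_nts"],
            nts_b_spo2=model.coefficients["spo2_code_nts"],
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "rts_weights": list(self.rts_weights),
                "nts_b0": self.nts_b0,
                "nts_b_gcs": self.nts_b_gcs,
                "nts_b_sbp": self.nts_b_sbp,
                "nts_b_spo2": self.nts_b_spo2,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreCoefficients":
        d = json.loads(text)
        d["rts_weights"] = tuple(d.get("rts_weights", cls.rts_weights))
        return cls(**d)


DEFAULT_COEFFICIENTS = ScoreCoefficients()


@dataclass(frozen=True)
class ScorePanel:
    """All scores for one patient."""

    rts: float
    nts: float
    t_nts: int
    ps: float
    mgap: int
    gap: int
    risk_stratum: str


def _check_code(name: str, value) -> int:
    if value is None:
        raise MissingVitalsError(f"{name} is missing")
    if value not in (0, 1, 2, 3, 4):
        raise ValueError(f"{name} must be a code in 0..4, got {value!r}")
    return int(value)


def _check_gcs(gcs) -> int:
    if gcs is None:
        raise MissingVitalsError("gcs is missing")
    if not float(gcs).is_integer() or not 3 <= gcs <= 15:
        raise ValueError(f"GCS must be an integer in [3, 15], got {gcs!r}")
    return int(gcs)


def rts(gcs_code: int, sbp_code: int, rr_code: int, coef: ScoreCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Revised Trauma Score from its three code values (full precision)."""
    g = _check_code("gcs_code", gcs_code)
    s = _check_code("sbp_code", sbp_code)
    r = _check_code("rr_code", rr_code)
    w = coef.rts_weights
    return w[0] * g + w[1] * s + w[2] * r


def nts(gcs: int, sbp_code_nts: int, spo2_code_nts: int, coef: ScoreCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """New Trauma Score: b1·GCS + b2·SBP_NTS + b3·SpO2_NTS."""
    g = _check_gcs(gcs)
    s = _check_code("sbp_code_nts", sbp_code_nts)
    o = _check_code("spo2_code_nts", spo2_code_nts)
    return coef.nts_b_gcs * g + coef.nts_b_sbp * s + coef.nts_b_spo2 * o


def ps(gcs: int, sbp_code_nts: int, spo2_code_nts: int, coef: ScoreCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Predictive survival Ps = 1/(1 + e^{-b}), b = b0 + NTS."""
    b = coef.nts_b0 + nts(gcs, sbp_code_nts, spo2_code_nts, coef)
    return 1.0 / (1.0 + math.exp(-b))


def t_nts(gcs: int, sbp_code_nts: int, spo2_code_nts: int) -> int:
    """Triage NTS: the plain sum GCS + SBP_NTS + SpO2_NTS, in [3, 23]."""
    return _check_gcs(gcs) + _check_code("sbp_code_nts", sbp_code_nts) + _check_code("spo2_code_nts", spo2_code_nts)


def risk_stratum(value: int) -> str:
    """Risk stratum for a T-NTS: low 18-23, intermediate 12-17, high 6-11, very_high 3-5."""
    if not float(value).is_integer() or not 3 <= value <= 23:
        raise ValueError(f"T-NTS must be an integer in [3, 23], got {value!r}")
    for name, lo, hi in RISK_STRATA:
        if lo <= value <= hi:
            return name
    raise AssertionError("unreachable: strata partition [3, 23]")


def triage_transfer(value: int) -> bool:
    """Whether a T-NTS indicates transfer to a trauma centre (< 18)."""
    if not float(value).is_integer() or not 3 <= value <= 23:
        raise ValueError(f"T-NTS must be an integer in [3, 23], got {value!r}")
    return value < TRIAGE_CUTOFF


def mgap(gcs: int, age: float, mechanism: str, sbp: float) -> int:
    g = _check_gcs(gcs)
    if mechanism not in ("blunt", "penetrating"):
        raise ValueError(f"mechanism must be blunt or penetrating, got {mechanism!r}")
    if age < 0 or sbp < 0:
        raise ValueError("age and sbp must be non-negative")
    score = g
    if age < 60:
        score += MGAP_POINTS["age_lt_60"]
    if mechanism == "blunt":
        score += MGAP_POINTS["blunt"]
    if sbp >= MGAP_POINTS["sbp_high"][0]:
        score += MGAP_POINTS["sbp_high"][1]
    elif sbp >= MGAP_POINTS["sbp_mid"][0]:
        score += MGAP_POINTS["sbp_mid"][1]
    return score


def gap(gcs: int, age: float, sbp: float) -> int:
    g = _check_gcs(gcs)
    if age < 0 or sbp < 0:
        raise ValueError("age and sbp must be non-negative")
    score = g
    if age < 60:
        score += GAP_POINTS["age_lt_60"]
    if sbp > GAP_POINTS["sbp_high"][0]:
        score += GAP_POINTS["sbp_high"][1]
    elif sbp >= GAP_POINTS["sbp_mid"][0]:
        score += GAP_POINTS["sbp_mid"][1]
    return score


def score_panel(
    record: PatientRecord,
    coef: ScoreCoefficients = DEFAULT_COEFFICIENTS,
    *,
    nm_spo2_zero: bool = True,
) -> ScorePanel:
    """All six scores plus the risk stratum for one (complete) record.

    Raises :class:`MissingVitalsError` naming the first missing vital.
    """
    codes = coding.code_record(record, nm_spo2_zero=nm_spo2_zero)
    for name, value in (
        ("gcs", record.gcs),
        ("sbp", record.sbp),
        ("rr", record.rr),
        ("spo2", codes.spo2_code_nts),
    ):
        if value is None:
            raise MissingVitalsError(f"{name} is missing; score_panel needs complete vitals")
    tn = t_nts(record.gcs, codes.sbp_code_nts, codes.spo2_code_nts)
    return ScorePanel(
        rts=rts(codes.gcs_code_rts, codes.sbp_code_rts, codes.rr_code_rts, coef),
        nts=nts(record.gcs, codes.sbp_code_nts, codes.spo2_code_nts, coef),
        t_nts=tn,
        ps=ps(record.gcs, codes.sbp_code_nts, codes.spo2_code_nts, coef),
        mgap=mgap(record.gcs, record.age, record.mechanism, record.sbp),
        gap=gap(record.gcs, record.age, record.sbp),
        risk_stratum=risk_stratum(tn),
    )


class TraumaScorer(TransformerMixin, BaseEstimator):
    """Transformer appending score columns to a registry frame.

    Adds ``rts, nts, t_nts, ps, mgap, gap, stratum`` after running
    :class:`~traumascore.coding.VitalsCoder`.  Requires complete vitals
    (run imputation first); rows with missing required vitals raise unless
    ``require_complete=False``, in which case their scores are NaN.
    """

    def __init__(
        self,
        coefficients: ScoreCoefficients | None = None,
        nm_spo2_zero: bool = True,
        require_complete: bool = True,
    ):
        self.coefficients = coefficients
        self.nm_spo2_zero = nm_spo2_zero
        self.require_complete = require_complete

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        coef = self.coefficients or DEFAULT_COEFFICIENTS
        df = coding.VitalsCoder(nm_spo2_zero=self.nm_spo2_zero).transform(X)
        needed = ["gcs", "gcs_code_rts", "sbp_code_rts", "rr_code_rts", "sbp_code_nts", "spo2_code_nts"]
        incomplete = df[needed].isna().any(axis=1)
        if self.require_complete and incomplete.any():
            missing_cols = df.loc[incomplete, needed].isna().any(axis=0)
            names = [c for c in needed if missing_cols[c]]
            raise MissingVitalsError(
                f"{int(incomplete.sum())} rows lack required vitals ({', '.join(names)}); impute first"
            )
        g = df["gcs"].to_numpy(dtype=float)
        w = coef.rts_weights
        df["rts"] = (
            w[0] * df["gcs_code_rts"] + w[1] * df["sbp_code_rts"] + w[2] * df["rr_code_rts"]
        )
        lin = coef.nts_b_gcs * g + coef.nts_b_sbp * df["sbp_code_nts"] + coef.nts_b_spo2 * df["spo2_code_nts"]
        df["nts"] = lin
        df["ps"] = 1.0 / (1.0 + np.exp(-(coef.nts_b0 + lin)))
        tn = g + df["sbp_code_nts"].to_numpy(dtype=float) + df["spo2_code_nts"].to_numpy(dtype=float)
        df["t_nts"] = tn
        age = df["age"].to_numpy(dtype=float)
        sbp = df["sbp"].to_numpy(dtype=float)
        blunt = (df["mechanism"] == "blunt").to_numpy()
        df["mgap"] = (
            g
            + MGAP_POINTS["age_lt_60"] * (age < 60)
            + MGAP_POINTS["blunt"] * blunt
            + np.select([sbp >= 120, sbp >= 60], [5, 3], default=0)
        )
        df["gap"] = (
            g
            + GAP_POINTS["age_lt_60"] * (age < 60)
            + np.select([sbp > 120, sbp >= 60], [6, 4], default=0)
        )
        strata = np.select(
            [tn >= 18, tn >= 12, tn >= 6],
            ["low", "intermediate", "high"],
            default="very_high",
        ).astype(object)
        strata[np.isnan(tn)] = None
        df["stratum"] = strata
        return df
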