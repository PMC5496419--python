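"""The NTS derivation ladder on a complete (post-imputation) registry.

Reproduces the published model-building sequence:

1. univariate logistic fits of survival on GCS, SBP, RR, SpO2 (continuous)
   and on the coded GCS (categorical, reference code 4);
2. two multivariate contrasts — GCS + SBP + RR versus GCS + SBP + SpO2 —
   to decide whether RR or SpO2 carries independent information;
3. the final model: survival on the actual GCS, the NTS SBP code and the
   NTS SpO2 code, with its AUC and Hosmer-Lemeshow calibration;
4. the same model with the coded GCS, for the calibration comparison.

The outcome is survival throughout, so odds ratios above 1 mean more
favourable physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import stats
from .coding import VitalsCoder
from .registry import Registry
from .scores import ScoreCoefficients

__all__ = ["DerivationReport", "derive_nts", "NTSDeriver"]

_FINAL_COVARIATES = ["gcs", "sbp_code_nts", "spo2_code_nts"]


@dataclass
class DerivationReport:
    """Machine-readable analogue of the derivation result tables."""

    univariate: dict
    gcs_code_univariate: dict
    multivariate_rr: dict
    multivariate_spo2: dict
    final_model: stats.LogisticModel
    coded_gcs_model: stats.LogisticModel
    auc: float
    hosmer_lemeshow: stats.CalibrationResult
    coded_gcs_hosmer_lemeshow: stats.CalibrationResult
    coefficients: ScoreCoefficients = field(default=None)

    def to_dict(self) -> dict:
        def orr(r):
            return {"or": r.odds_ratio, "ci": [r.ci_low, r.ci_high], "p": r.p}

        def model(m):
            return {
                "intercept": m.intercept,
                "coefficients": m.coefficients,
                "standard_errors": m.standard_errors,
                "converged": m.converged,
                "log_likelihood": m.log_likelihood,
                "n_obs": m.n_obs,
            }

        return {
            "univariate": {k: orr(v) for k, v in self.univariate.items()},
            "gcs_code_univariate": {str(k): orr(v) for k, v in self.gcs_code_univariate.items()},
            "multivariate_rr": {k: orr(v) for k, v in self.multivariate_rr.items()},
            "multivariate_spo2": {k: orr(v) for k, v in self.multivariate_spo2.items()},
            "final_model": model(self.final_model),
            "coded_gcs_model": model(self.coded_gcs_model),
            "auc": self.auc,
            "hosmer_lemeshow": {
                "chi2": self.hosmer_lemeshow.chi2,
                "df": self.hosmer_lemeshow.df,
                "p": self.hosmer_lemeshow.p,
            },
            "coded_gcs_hosmer_lemeshow": {
                "chi2": self.coded_gcs_hosmer_lemeshow.chi2,
                "df": self.coded_gcs_hosmer_lemeshow.df,
                "p": self.coded_gcs_hosmer_lemeshow.p,
            },
            "coefficients": {
                "nts_b0": self.coefficients.nts_b0,
                "nts_b_gcs": self.coefficients.nts_b_gcs,
                "nts_b_sbp": self.coefficients.nts_b_sbp,
                "nts_b_spo2": self.coefficients.nts_b_spo2,
            },
        }


def _multivariate_ors(model: stats.LogisticModel) -> dict:
    return {
        name: stats._wald_or(model.coefficients[name], model.standard_errors[name])
        for name in model.names
    }


def derive_nts(registry: Registry) -> DerivationReport:
    """Run the full derivation ladder; requires complete vitals."""
    df = VitalsCoder().transform(registry.df)
    needed = ["gcs", "sbp", "rr", "spo2_code_nts", "sbp_code_nts", "gcs_code_rts"]
    if df[needed].isna().any().any():
        bad = [c for c in needed if df[c].isna().any()]
        raise ValueError(f"derivation needs complete data; missing cells in {bad} (impute first)")
    survived = (~df["died"].astype(bool)).astype(float).to_numpy()

    spo2_cont = df["spo2"].to_numpy(dtype=float).copy()
    spo2_cont[df["spo2_nm"].astype(bool).to_numpy()] = 0.0

    univariate = {
        "gcs": stats.univariate_or(df["gcs"], survived),
        "sbp": stats.univariate_or(df["sbp"], survived),
        "rr": stats.univariate_or(df["rr"], survived),
        "spo2": stats.univariate_or(spo2_cont, survived),
    }
    gcs_code_univariate = stats.univariate_or(
        df["gcs_code_rts"].astype(int), survived, categorical=True, reference=4
    )

    mv_rr = stats.fit_logistic(df[["gcs", "sbp", "rr"]], survived)
    mv_spo2 = stats.fit_logistic(
        pd.DataFrame({"gcs": df["gcs"], "sbp": df["sbp"], "spo2": spo2_cont}), survived
    )

    final = stats.fit_logistic(df[_FINAL_COVARIATES], survived)
    coded = stats.fit_logistic(
        df[["gcs_code_rts", "sbp_code_nts", "spo2_code_nts"]], survived
    )

    ps_hat = final.predict_proba(df)
    auc_value = stats.auc(ps_hat, survived)
    hl = stats.hosmer_lemeshow(ps_hat, survived)
    hl_coded = stats.hosmer_lemeshow(coded.predict_proba(df), survived)

    return DerivationReport(
        univariate=univariate,
        gcs_code_univariate=gcs_code_univariate,
        multivariate_rr=_multivariate_ors(mv_rr),
        multivariate_spo2=_multivariate_ors(mv_spo2),
        final_model=final,
        coded_gcs_model=coded,
        auc=auc_value,
        hosmer_lemeshow=hl,
        coded_gcs_hosmer_lemeshow=hl_coded,
        coefficients=ScoreCoefficients.from_logistic_model(final),
    )


class NTSDeriver(BaseEstimator):
    """Estimator face of the final-model fit.

    ``fit(X, y)`` takes raw vitals (``gcs``, ``sbp``, ``spo2`` columns,
    optionally ``spo2_nm``) and a binary survival outcome, codes them and
    fits the survival logistic model.  ``predict_proba`` returns Ps.
    """

    def __init__(self, nm_spo2_zero: bool = True):
        self.nm_spo2_zero = nm_spo2_zero

    def fit(self, X: pd.DataFrame, y):
        df = self._coded(X)
        self.model_ = stats.fit_logistic(df[_FINAL_COVARIATES], np.asarray(y, dtype=float))
        self.coefficients_ = ScoreCoefficients.from_logistic_model(self.model_)
        return self

    def _coded(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        for col in ("rr",):  # the coder wants the full vital set
            if col not in df.columns:
                df[col] = np.nan
        return VitalsCoder(nm_spo2_zero=self.nm_spo2_zero).transform(df)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("NTSDeriver is not fitted")
        return self.model_.predict_proba(self._coded(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)
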