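"""Multiple imputation by chained equations with predictive mean matching.

Registry vitals (SBP, RR, GCS, SpO2) and the ISS are imputed conditional
on age, sex, the outcome (in-hospital death) and each other, following the
standard MICE-PMM recipe: per variable, a perturbed linear model predicts
the missing cells and each is filled with an observed donor value drawn
from the ``donor_k`` nearest predicted means.  Donors guarantee imputed
values stay inside the observed range and preserve integer variables.

The m completed datasets come from m independent seeded chains.  Pooling
of per-imputation regression fits follows Rubin's rules: pooled beta is
the mean, total variance the within-imputation mean plus (1 + 1/m) times
the between-imputation variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.imputation.mice import MICEData

from .registry import Registry

__all__ = [
    "ImputationSet",
    "PooledModel",
    "mice_pmm",
    "pool_coefficients",
    "MicePmmImputer",
    "DEFAULT_IMPUTE_VARIABLES",
]

DEFAULT_IMPUTE_VARIABLES = ("sbp", "rr", "gcs", "spo2", "iss")
_MODEL_COLUMNS = ("age", "sex_male", "gcs", "sbp", "rr", "spo2", "iss", "died")


@dataclass
class ImputationSet:
    """m completed registries plus the chain settings that produced them."""

    m: int
    datasets: list
    seed: int
    iterations: int
    donor_k: int

    def __iter__(self):
        return iter(self.datasets)


@dataclass
class PooledModel:
    """Rubin-pooled coefficients across per-imputation logistic fits."""

    estimates: dict
    standard_errors: dict
    within_variance: dict
    between_variance: dict
    m: int


def _model_frame(registry: Registry) -> pd.DataFrame:
    df = registry.df
    frame = pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "sex_male": (df["sex"] == "male").astype(float),
            "gcs": df["gcs"].astype(float),
            "sbp": df["sbp"].astype(float),
            "rr": df["rr"].astype(float),
            "spo2": df["spo2"].astype(float),
            "iss": df["iss"].astype(float),
            "died": df["died"].astype(float),
        }
    )
    # Non-measurable SpO2 is known (coded 0 downstream), not missing at
    # random: hold it at 0 in the imputation model and restore afterwards.
    frame.loc[df["spo2_nm"].astype(bool).to_numpy(), "spo2"] = 0.0
    return frame


def mice_pmm(
    registry: Registry,
    variables=DEFAULT_IMPUTE_VARIABLES,
    m: int = 10,
    iterations: int = 10,
    donor_k: int = 5,
    seed: int = 0,
) -> ImputationSet:
    """Run m independent MICE-PMM chains and return the completed registries.

    Only the named ``variables`` may be imputed; any other column with
    missing cells raises.  Reproducible: the same seed yields bit-identical
    output, and per-chain seeds are derived so chains are independent.
    """
    df = registry.df
    for var in variables:
        col = df[var]
        observed = col.notna() | (df["spo2_nm"].astype(bool) if var == "spo2" else False)
        if not observed.any():
            raise ValueError(f"variable {var!r} has zero observed values; cannot impute")
    other_missing = [
        c for c in ("age", "sex", "mechanism", "died") if df[c].isna().any()
    ]
    if other_missing:
        raise ValueError(f"columns {other_missing} have missing cells but are never imputed")

    frame = _model_frame(registry)
    to_impute = [v for v in variables if frame[v].isna().any()]
    if not to_impute:
        return ImputationSet(m, [registry.copy() for _ in range(m)], seed, iterations, donor_k)

    # keep chains reproducible and mutually independent; MICEData draws
    # from the numpy global state, so seed it per chain
    chain_seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
    datasets = []
    for i in range(m):
        np.random.seed(int(chain_seeds[i]))
        md = MICEData(frame.copy(), k_pmm=donor_k)
        md.update_all(iterations)
        completed = registry.df.copy()
        for var in to_impute:
            completed[var] = md.data[var].to_numpy(dtype=float)
        # restore the NM convention: value stays absent, flag stays set
        completed.loc[completed["spo2_nm"].astype(bool).to_numpy(), "spo2"] = np.nan
        datasets.append(Registry(completed, registry.label, list(registry.rejected)))
    return ImputationSet(m, datasets, seed, iterations, donor_k)


def pool_coefficients(models) -> PooledModel:
    """Combine per-imputation logistic fits by Rubin's rules."""
    models = list(models)
    if not models:
        raise ValueError("no models to pool")
    names = ["const"] + models[0].names
    for mod in models:
        if ["const"] + mod.names != names:
            raise ValueError("models have mismatched covariates")
    m = len(models)
    est, se, within, between = {}, {}, {}, {}
    for name in names:
        betas = np.array(
            [mod.intercept if name == "const" else mod.coefficients[name] for mod in models]
        )
        ses = np.array([mod.standard_errors[name] for mod in models])
        qbar = betas.mean()
        w = (ses**2).mean()
        b = betas.var(ddof=1) if m > 1 else 0.0
        total = w + (1 + 1 / m) * b
        est[name] = float(qbar)
        within[name] = float(w)
        between[name] = float(b)
        se[name] = float(np.sqrt(total))
    return PooledModel(est, se, within, between, m)


class MicePmmImputer(BaseEstimator):
    """Estimator face of :func:`mice_pmm`.

    ``fit`` runs the chains and exposes ``imputation_set_`` /
    ``datasets_``; ``transform`` returns the completed frame of the first
    chain (a convenient single completion for pipeline use — pooled
    analyses should iterate over ``datasets_``).
    """

    def __init__(
        self,
        variables=DEFAULT_IMPUTE_VARIABLES,
        m: int = 10,
        iterations: int = 10,
        donor_k: int = 5,
        seed: int = 0,
    ):
        self.variables = variables
        self.m = m
        self.iterations = iterations
        self.donor_k = donor_k
        self.seed = seed

    def fit(self, X, y=None):
        registry = X if isinstance(X, Registry) else Registry(X.copy())
        self.imputation_set_ = mice_pmm(
            registry,
            variables=self.variables,
            m=self.m,
            iterations=self.iterations,
            donor_k=self.donor_k,
            seed=self.seed,
        )
        self.datasets_ = self.imputation_set_.datasets
        return self

    def transform(self, X=None):
        if not hasattr(self, "imputation_set_"):
            raise RuntimeError("MicePmmImputer is not fitted")
        return self.datasets_[0].df.copy()

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
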