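"""Code-value maps for the Revised Trauma Score and the New Trauma Score.

The RTS converts GCS, systolic blood pressure (SBP) and respiratory rate
(RR) into coded values 0-4.  The NTS keeps the *actual* GCS (3-15) and
replaces the RR with peripheral oxygen saturation (SpO2); its SBP bands are
re-centred so that the normotensive range 110-149 mmHg scores 4 while
hypertension (>= 150 mmHg) scores 3, reflecting the bimodal relation
between admission SBP and trauma mortality.

The published tables bin integer readings.  Real-valued inputs are handled
with intervals closed at each printed lower endpoint and open at the next
one (e.g. RTS SBP code 3 is [76, 90), so 89.5 -> 3), which closes the gaps
the integer table leaves open while agreeing with it on every integer.

Non-measurable SpO2 (typically profound shock or arrest) is coded 0 by
default — the lowest category — rather than treated as missing at random.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CodedVitals",
    "code_gcs_rts",
    "code_sbp_rts",
    "code_rr_rts",
    "code_sbp_nts",
    "code_spo2_nts",
    "code_record",
    "VitalsCoder",
    "CODING_TABLES",
    "export_coding_tables",
]

#: Machine-readable rendering of the code-value tables.  Each band is
#: (lower, upper, code) on a half-open interval [lower, upper).
CODING_TABLES = {
    "gcs_rts": [(13, 16, 4), (9, 13, 3), (6, 9, 2), (4, 6, 1), (3, 4, 0)],
    "sbp_rts": [(90, math.inf, 4), (76, 90, 3), (50, 76, 2), (0, 50, 1), (0, 0, 0)],
    "rr_rts": [(10, 30, 4), (30, math.inf, 3), (6, 10, 2), (0, 6, 1), (0, 0, 0)],
    "sbp_nts": [(110, 150, 4), (150, math.inf, 3), (90, 110, 2), (70, 90, 1), (0, 70, 0)],
    "spo2_nts": [(94, 101, 4), (80, 94, 3), (60, 80, 2), (40, 60, 1), (0, 40, 0)],
}


@dataclass(frozen=True)
class CodedVitals:
    """The five code values derived from one patient's vitals.

    A code is ``None`` exactly when the underlying vital is missing.  The
    NTS uses the actual GCS, so there is no NTS GCS code.
    """

    gcs_code_rts: int | None
    sbp_code_rts: int | None
    rr_code_rts: int | None
    sbp_code_nts: int | None
    spo2_code_nts: int | None


def code_gcs_rts(gcs: int) -> int:
    """RTS code for a Glasgow Coma Scale total: 13-15→4, 9-12→3, 6-8→2, 4-5→1, 3→0."""
    if not float(gcs).is_integer() or not 3 <= gcs <= 15:
        raise ValueError(f"GCS must be an integer in [3, 15], got {gcs!r}")
    gcs = int(gcs)
    if gcs >= 13:
        return 4
    if gcs >= 9:
        return 3
    if gcs >= 6:
        return 2
    if gcs >= 4:
        return 1
    return 0


def code_sbp_rts(sbp: float) -> int:
    """RTS code for systolic blood pressure (mmHg): >89→4, 76-89→3, 50-75→2, 1-49→1, 0→0."""
    if sbp < 0:
        raise ValueError(f"SBP must be non-negative, got {sbp!r}")
    if sbp >= 90:
        return 4
    if sbp >= 76:
        return 3
    if sbp >= 50:
        return 2
    if sbp > 0:
        return 1
    return 0


def code_rr_rts(rr: float) -> int:
    """RTS code for respiratory rate (breaths/min): 10-29→4, >29→3, 6-9→2, 1-5→1, 0→0."""
    if rr < 0:
        raise ValueError(f"RR must be non-negative, got {rr!r}")
    if 10 <= rr < 30:
        return 4
    if rr >= 30:
        return 3
    if rr >= 6:
        return 2
    if rr > 0:
        return 1
    return 0


def code_sbp_nts(sbp: float) -> int:
    """NTS code for systolic blood pressure: 110-149→4, ≥150→3, 90-109→2, 70-89→1, <70→0."""
    if sbp < 0:
        raise ValueError(f"SBP must be non-negative, got {sbp!r}")
    if 110 <= sbp < 150:
        return 4
    if sbp >= 150:
        return 3
    if sbp >= 90:
        return 2
    if sbp >= 70:
        return 1
    return 0


def code_spo2_nts(spo2: float | None, *, non_measurable: bool = False) -> int:
    """NTS code for SpO2 (%): ≥94→4, 80-93→3, 60-79→2, 40-59→1, <40→0.

    ``non_measurable=True`` yields 0: an unobtainable saturation almost
    always reflects extreme hypoxia or absent peripheral circulation.
    """
    if non_measurable:
        return 0
    if spo2 is None or not 0 <= spo2 <= 100:
        raise ValueError(f"SpO2 must lie in [0, 100] or be non-measurable, got {spo2!r}")
    if spo2 >= 94:
        return 4
    if spo2 >= 80:
        return 3
    if spo2 >= 60:
        return 2
    if spo2 >= 40:
        return 1
    return 0


def code_record(record, *, nm_spo2_zero: bool = True) -> CodedVitals:
    """Apply all five code maps to a :class:`~traumascore.registry.PatientRecord`.

    Missing vitals yield missing codes, field-wise.  With
    ``nm_spo2_zero=False`` a non-measurable SpO2 is left missing instead of
    coded 0.
    """
    gcs_code = None if record.gcs is None else code_gcs_rts(record.gcs)
    sbp_rts = None if record.sbp is None else code_sbp_rts(record.sbp)
    rr_rts = None if record.rr is None else code_rr_rts(record.rr)
    sbp_nts = None if record.sbp is None else code_sbp_nts(record.sbp)
    if record.spo2_non_measurable:
        spo2_nts = 0 if nm_spo2_zero else None
    elif record.spo2 is None:
        spo2_nts = None
    else:
        spo2_nts = code_spo2_nts(record.spo2)
    return CodedVitals(gcs_code, sbp_rts, rr_rts, sbp_nts, spo2_nts)


def _banded(values: np.ndarray, bands) -> np.ndarray:
    """Vectorised band lookup; NaN propagates."""
    out = np.full(values.shape, np.nan)
    for lo, hi, code in bands:
        if lo == hi:  # the exact-zero band
            mask = values == lo
        else:
            mask = (values >= lo) & (values < hi)
        out[mask] = code
    return out


class VitalsCoder(TransformerMixin, BaseEstimator):
    """Stateless transformer appending the five code columns to a registry frame.

    Parameters
    ----------
    nm_spo2_zero : bool, default True
        Code non-measurable SpO2 (``spo2_nm`` column) as 0 rather than
        leaving it missing.
    """

    def __init__(self, nm_spo2_zero: bool = True):
        self.nm_spo2_zero = nm_spo2_zero

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        gcs = df["gcs"].to_numpy(dtype=float)
        bad = ~np.isnan(gcs) & ((gcs < 3) | (gcs > 15) | (gcs != np.round(gcs)))
        if bad.any():
            raise ValueError(f"GCS out of [3, 15] or non-integer at rows {list(np.flatnonzero(bad))}")
        for col in ("sbp", "rr"):
            v = df[col].to_numpy(dtype=float)
            if (v[~np.isnan(v)] < 0).any():
                raise ValueError(f"negative {col} values")
        spo2 = df["spo2"].to_numpy(dtype=float)
        if ((spo2[~np.isnan(spo2)] < 0) | (spo2[~np.isnan(spo2)] > 100)).any():
            raise ValueError("SpO2 outside [0, 100]")

        df["gcs_code_rts"] = _banded(gcs, CODING_TABLES["gcs_rts"])
        df["sbp_code_rts"] = _banded(df["sbp"].to_numpy(dtype=float), CODING_TABLES["sbp_rts"])
        df["rr_code_rts"] = _banded(df["rr"].to_numpy(dtype=float), CODING_TABLES["rr_rts"])
        df["sbp_code_nts"] = _banded(df["sbp"].to_numpy(dtype=float), CODING_TABLES["sbp_nts"])
        spo2_code = _banded(spo2, CODING_TABLES["spo2_nts"])
        if self.nm_spo2_zero and "spo2_nm" in df.columns:
            spo2_code[df["spo2_nm"].to_numpy(dtype=bool)] = 0.0
        df["spo2_code_nts"] = spo2_code
        return df


def export_coding_tables() -> str:
    """The coding tables as JSON (for documentation and cross-language tests)."""
    tables = {
        name: [{"lower": lo, "upper": ("inf" if math.isinf(hi) else hi), "code": code} for lo, hi, code in bands]
        for name, bands in CODING_TABLES.items()
    }
    return json.dumps(tables, indent=2)
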