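"""MIPI prognostic indices and the PET "metabolic risk" signature.

The Mantle cell lymphoma International Prognostic Index (MIPI) is a linear
score on age, ECOG performance status, LDH (relative to its upper limit of
normal) and white blood cell count; the biological variant (MIPI-b) adds
the Ki-67 proliferation index.  Both map to three risk categories (1 low,
2 intermediate, 3 high) via published cutpoints.  Constants live in
:class:`MIPIConstants` so they are auditable and overridable rather than
buried in code.

The metabolic risk signature dichotomizes SUVmean and Entropy at their
cut-offs and combines them by majority vote: both above -> high, both at or
below -> low, one of each -> intermediate (the two-category variant folds
intermediate into low).  MIPI-m / MIPI-bm shift the MIPI category by +-1
according to metabolic risk, capped at the 1..3 range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MIPIConstants",
    "SignatureConfig",
    "mipi_score",
    "mipi_b_score",
    "metabolic_risk",
    "modify_mipi",
    "build_risk_profiles",
    "derive_pfs2y_event",
]

RISK_LOW, RISK_INTERMEDIATE, RISK_HIGH = "low", "intermediate", "high"
_METABOLIC_STEP = {RISK_LOW: -1, RISK_INTERMEDIATE: 0, RISK_HIGH: +1}


@dataclass
class MIPIConstants:
    """Published MIPI / MIPI-b coefficients and category cutpoints.

    score = c_age*age + c_ecog*[ECOG >= 2] + c_ldh*log10(LDH/ULN)
            + c_wbc*log10(WBC in 1e6/L)  (+ c_ki67*Ki-67% for MIPI-b)

    WBC is supplied in 1e9/L clinically and converted (x1000) to the
    1e6/L scale the published formula uses.  Categories: score < t1 -> low,
    t1 <= score < t2 -> intermediate, score >= t2 -> high.
    """

    c_age: float = 0.03535
    c_ecog: float = 0.6978
    c_ldh: float = 1.367
    c_wbc: float = 0.9393
    c_ki67: float = 0.02142
    mipi_cutpoints: tuple[float, float] = (5.7, 6.2)
    mipi_b_cutpoints: tuple[float, float] = (5.7, 6.5)


@dataclass
class SignatureConfig:
    """Dichotomization cut-offs for the radiomic signature."""

    suvmean_cutoff: float = 3.55
    entropy_cutoff: float = 3.5
    n_categories: int = 3

    def __post_init__(self) -> None:
        if not (math.isfinite(self.suvmean_cutoff) and math.isfinite(self.entropy_cutoff)):
            raise ValueError("signature cut-offs must be finite")
        if self.n_categories not in (2, 3):
            raise ValueError("n_categories must be 2 or 3")


def _categorize(score: float, cutpoints: tuple[float, float]) -> int:
    t1, t2 = cutpoints
    if score < t1:
        return 1
    if score < t2:
        return 2
    return 3


def _linear_predictor(age, ecog, wbc, ldh, ldh_uln, constants: MIPIConstants) -> float:
    if wbc <= 0:
        raise ValueError(f"WBC must be positive, got {wbc}")
    if ldh <= 0 or ldh_uln <= 0:
        raise ValueError(f"LDH and its ULN must be positive, got {ldh}/{ldh_uln}")
    return (
        constants.c_age * float(age)
        + constants.c_ecog * (1.0 if int(ecog) >= 2 else 0.0)
        + constants.c_ldh * math.log10(float(ldh) / float(ldh_uln))
        + constants.c_wbc * math.log10(float(wbc) * 1000.0)  # 1e9/L -> 1e6/L
    )


def mipi_score(
    age, ecog, wbc, ldh, ldh_uln, constants: MIPIConstants | None = None
) -> tuple[float, int]:
    """Classic MIPI score and its three-level risk category."""
    constants = constants or MIPIConstants()
    score = _linear_predictor(age, ecog, wbc, ldh, ldh_uln, constants)
    return score, _categorize(score, constants.mipi_cutpoints)


def mipi_b_score(
    age, ecog, wbc, ldh, ldh_uln, ki67, constants: MIPIConstants | None = None
) -> tuple[float, int]:
    """Biological MIPI (adds the Ki-67 index, in percent) and its category."""
    constants = constants or MIPIConstants()
    if not 0 <= float(ki67) <= 100:
        raise ValueError(f"Ki-67 must be a percentage in [0, 100], got {ki67}")
    score = _linear_predictor(age, ecog, wbc, ldh, ldh_uln, constants)
    score += constants.c_ki67 * float(ki67)
    return score, _categorize(score, constants.mipi_b_cutpoints)


def metabolic_risk(suv_mean, entropy, cfg: SignatureConfig | None = None) -> str:
    """Majority-vote metabolic risk from dichotomized SUVmean and Entropy.

    Three categories: high when both features exceed their cut-offs, low
    when both are at or below, intermediate otherwise.  Two categories:
    high when both exceed, low otherwise (intermediate folded into low).
    Values exactly at a cut-off count as below it.
    """
    cfg = cfg or SignatureConfig()
    if not (math.isfinite(float(suv_mean)) and math.isfinite(float(entropy))):
        raise ValueError("suv_mean and entropy must be finite")
    suv_high = float(suv_mean) > cfg.suvmean_cutoff
    ent_high = float(entropy) > cfg.entropy_cutoff
    if suv_high and ent_high:
        return RISK_HIGH
    if not suv_high and not ent_high:
        return RISK_LOW
    return RISK_INTERMEDIATE if cfg.n_categories == 3 else RISK_LOW


def modify_mipi(mipi_cat: int, metabolic: str) -> int:
    """Shift a MIPI category by metabolic risk, capped at the 1..3 range.

    High metabolic risk adds one category step unless already 3; low
    subtracts one unless already 1; intermediate leaves it unchanged.
    """
    if mipi_cat not in (1, 2, 3):
        raise ValueError(f"MIPI category must be 1, 2 or 3, got {mipi_cat}")
    if metabolic not in _METABOLIC_STEP:
        raise ValueError(f"unknown metabolic risk category: {metabolic!r}")
    return int(np.clip(mipi_cat + _METABOLIC_STEP[metabolic], 1, 3))


def derive_pfs2y_event(pfs_months, progressed) -> bool:
    """Two-year endpoint: progression or death within 24 months."""
    return bool(progressed) and float(pfs_months) <= 24.0


@dataclass
class RiskProfile:
    patient_id: str
    mipi_score: float
    mipi_cat: int
    mipi_b_score: float
    mipi_b_cat: int
    metabolic_risk: str
    metabolic_risk_2cat: str
    mipi_m_cat: int
    mipi_bm_cat: int


def build_risk_profiles(
    features: pd.DataFrame,
    patients: pd.DataFrame,
    cfg: SignatureConfig | None = None,
    constants: MIPIConstants | None = None,
) -> pd.DataFrame:
    """Join features with clinical records and score every patient.

    ``features`` needs ``patient_id, suv_mean, entropy``; ``patients`` needs
    ``patient_id, age, ecog, wbc, ldh, ldh_uln, ki67``.  The tables must
    match 1:1 on ``patient_id``.
    """
    cfg = cfg or SignatureConfig()
    constants = constants or MIPIConstants()
    f_ids = set(features["patient_id"])
    p_ids = set(patients["patient_id"])
    unmatched = sorted(f_ids.symmetric_difference(p_ids))
    if unmatched or not f_ids:
        raise ValueError(
            "feature and patient tables must match 1:1 on patient_id; "
            f"unmatched ids: {unmatched}" if unmatched else "empty join"
        )
    merged = features.merge(patients, on="patient_id", validate="1:1")
    cfg3 = SignatureConfig(cfg.suvmean_cutoff, cfg.entropy_cutoff, 3)
    cfg2 = SignatureConfig(cfg.suvmean_cutoff, cfg.entropy_cutoff, 2)
    rows = []
    for rec in merged.itertuples(index=False):
        score, cat = mipi_score(rec.age, rec.ecog, rec.wbc, rec.ldh, rec.ldh_uln, constants)
        score_b, cat_b = mipi_b_score(
            rec.age, rec.ecog, rec.wbc, rec.ldh, rec.ldh_uln, rec.ki67, constants
        )
        met3 = metabolic_risk(rec.suv_mean, rec.entropy, cfg3)
        met2 = metabolic_risk(rec.suv_mean, rec.entropy, cfg2)
        rows.append(
            RiskProfile(
                patient_id=rec.patient_id,
                mipi_score=score,
                mipi_cat=cat,
                mipi_b_score=score_b,
                mipi_b_cat=cat_b,
                metabolic_risk=met3,
                metabolic_risk_2cat=met2,
                mipi_m_cat=modify_mipi(cat, met3),
                mipi_bm_cat=modify_mipi(cat_b, met3),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
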