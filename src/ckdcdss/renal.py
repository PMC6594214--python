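"""Renal calculators: eGFR from creatinine and cystatin-C, and kidney-failure risk.

Implements the CKD-EPI 2009 creatinine equation, the CKD-EPI 2012
cystatin-C equation, and the 4-variable, 5-year kidney failure risk
equation (KFRE, North-American calibration).  All three are deterministic
pure functions of their clinical inputs; units follow US clinical
convention (creatinine mg/dL, cystatin-C mg/L, ACR mg/g, eGFR
mL/min/1.73m²).

The creatinine equation's Black-race coefficient is behind an explicit
flag, default off: contemporary practice omits it, and the source lab
convention for the study population is not knowable from the data model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

__all__ = [
    "egfr_creatinine",
    "egfr_cystatin",
    "kfre_5yr",
    "TripleMarkerPanel",
    "KidneyFailureRisk",
]

# --- CKD-EPI 2009 (creatinine) constants ---
_CR_KAPPA = {"female": 0.7, "male": 0.9}
_CR_ALPHA = {"female": -0.329, "male": -0.411}
_CR_FEMALE_FACTOR = 1.018
_CR_RACE_FACTOR = 1.159

# --- CKD-EPI 2012 (cystatin-C) constants ---
_CYS_KAPPA = 0.8
_CYS_ALPHA = -0.499
_CYS_BETA = -1.328
_CYS_FEMALE_FACTOR = 0.932

# --- KFRE 4-variable, 5-year, North-American calibration ---
# Linear predictor is centred at the derivation-cohort means; baseline
# 5-year survival 0.9365.
_KFRE_BASELINE_SURVIVAL_5YR = 0.9365
_KFRE_COEF_AGE = -0.2201  # per decade, centred at 7.036
_KFRE_COEF_MALE = 0.2467  # centred at 0.5642
_KFRE_COEF_EGFR = -0.5567  # per 5 mL/min, centred at 7.222
_KFRE_COEF_LOGACR = 0.4510  # per ln(mg/g), centred at 5.137


def _check_sex(sex: str) -> str:
    s = str(sex).lower()
    if s not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    return s


def egfr_creatinine(
    scr: float,
    age: float,
    sex: str,
    race_coefficient_enabled: bool = False,
    black: bool = False,
) -> float:
    """Estimated GFR from serum creatinine (CKD-EPI 2009).

    Parameters
    ----------
    scr : serum creatinine, mg/dL; must be > 0.
    age : age in years (adults).
    sex : ``'female'`` or ``'male'``.
    race_coefficient_enabled : apply the historical Black-race
        coefficient when ``black`` is True.  Default off.
    black : patient's race flag, only consulted when the coefficient
        is enabled.

    Returns
    -------
    float
        eGFR in mL/min/1.73m².
    """
    sex = _check_sex(sex)
    if not scr > 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    kappa = _CR_KAPPA[sex]
    alpha = _CR_ALPHA[sex]
    ratio = scr / kappa
    value = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993 ** age
    if sex == "female":
        value *= _CR_FEMALE_FACTOR
    if race_coefficient_enabled and black:
        value *= _CR_RACE_FACTOR
    return value


def egfr_cystatin(scys: float, age: float, sex: str) -> float:
    """Estimated GFR from serum cystatin-C (CKD-EPI 2012, cystatin alone).

    ``scys`` in mg/L; returns eGFR in mL/min/1.73m².
    """
    sex = _check_sex(sex)
    if not scys > 0:
        raise ValueError(f"cystatin-C must be positive, got {scys}")
    ratio = scys / _CYS_KAPPA
    value = (
        133.0
        * min(ratio, 1.0) ** _CYS_ALPHA
        * max(ratio, 1.0) ** _CYS_BETA
        * 0.996 ** age
    )
    if sex == "female":
        value *= _CYS_FEMALE_FACTOR
    return value


def kfre_5yr(age: float, sex: str, egfr: float, acr: float) -> float:
    """Five-year kidney-failure risk, 4-variable KFRE (North America).

    Parameters
    ----------
    age : years.
    sex : ``'female'`` or ``'male'``.
    egfr : mL/min/1.73m²; must be > 0.
    acr : urine albumin-creatinine ratio, mg/g; must be > 0.

    Returns
    -------
    float
        Probability of kidney failure within 5 years, in (0, 1).
    """
    sex = _check_sex(sex)
    if not egfr > 0:
        raise ValueError(f"eGFR must be positive, got {egfr}")
    if not acr > 0:
        raise ValueError(f"ACR must be positive, got {acr}")
    male = 1.0 if sex == "male" else 0.0
    lp = (
        _KFRE_COEF_AGE * (age / 10.0 - 7.036)
        + _KFRE_COEF_MALE * (male - 0.5642)
        + _KFRE_COEF_EGFR * (egfr / 5.0 - 7.222)
        + _KFRE_COEF_LOGACR * (math.log(acr) - 5.137)
    )
    return 1.0 - _KFRE_BASELINE_SURVIVAL_5YR ** math.exp(lp)


@dataclass(frozen=True)
class TripleMarkerPanel:
    """The creatinine / cystatin-C / ACR triple with derived eGFRs.

    ``completed_at`` is the latest of the three collection timestamps —
    the moment the panel becomes actionable for decision support.
    """

    scr: float
    scys: float
    acr: float
    age: float
    sex: str
    completed_at: datetime | None = None
    egfr_cr: float = field(init=False)
    egfr_cys: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "egfr_cr", egfr_creatinine(self.scr, self.age, self.sex))
        object.__setattr__(self, "egfr_cys", egfr_cystatin(self.scys, self.age, self.sex))

    @classmethod
    def from_results(cls, scr, scys, acr, age, sex, timestamps) -> "TripleMarkerPanel":
        """Build a panel from three results; completion = max timestamp."""
        return cls(scr=scr, scys=scys, acr=acr, age=age, sex=sex,
                   completed_at=max(timestamps))


@dataclass(frozen=True)
class KidneyFailureRisk:
    """A computed 5-year KFRE value with its inputs, for provenance."""

    risk_5yr: float
    age: float
    sex: str
    egfr: float
    acr: float

    @classmethod
    def compute(cls, age, sex, egfr, acr) -> "KidneyFailureRisk":
        return cls(kfre_5yr(age, sex, egfr, acr), age, sex, egfr, acr)
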