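"""Synthetic primary-care EHR generator.

Emulates the panel structure of an academic general-internal-medicine
practice: ~80 providers (attendings, residents, nurse practitioners),
each with a patient panel; per-patient creatinine histories engineered
so that a configurable fraction satisfies the trial's eligibility
pattern (two outpatient eGFR 30–59 at least 90 days apart, one recent)
while every other patient violates exactly one criterion, giving full
coverage of the exclusion cascade; ambulatory blood-pressure series with
a configurable between-provider intraclass correlation; and medication,
comorbidity and diagnosis tables drawn at the prevalences observed in
the study population.

A ground-truth sidecar table records each patient's true eligibility
label, the single criterion violated, and latent triple-marker
physiology (cystatin-C, ACR) with the implied risk tier.  The sidecar
exists for test oracles and for the trial simulator's lab
materialisation; the cohort selector and the decision-support engine
never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .renal import egfr_creatinine, egfr_cystatin

__all__ = ["GeneratorConfig", "EHRDataset", "generate_population", "generate_bp_series"]

DAYS_PER_YEAR = 365.25

ROLES = ("attending", "resident", "nurse_practitioner")

ANTIHYPERTENSIVE_CLASSES = frozenset(
    {"acei_arb", "thiazide_diuretic", "loop_diuretic", "beta_blocker", "calcium_channel_blocker"}
)
DIURETIC_CLASSES = frozenset({"thiazide_diuretic", "loop_diuretic"})

# one violated criterion per ineligible patient; the cycle gives every
# exclusion path coverage in any moderately sized dataset
VIOLATIONS = (
    "age_high",
    "age_low",
    "language",
    "egfr_out_of_range",
    "egfr_too_close",
    "egfr_stale",
    "egfr_single",
    "no_recent_pcp_visit",
    "deceased",
    "esrd",
    "nephrology_engaged",
    "transplant",
    "dementia",
)


def age_at(birth_date: date, when: date) -> float:
    """Age in years at a reference date (day granularity)."""
    return (when - birth_date).days / DAYS_PER_YEAR


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic practice.

    BP variance follows the two-component cluster model used in the
    trial's power calculation: systolic BP = grand mean + provider
    random effect (variance ``bp_icc * bp_sd**2``) + patient residual
    (variance ``(1 - bp_icc) * bp_sd**2``), with optional visit-level
    jitter ``visit_sd`` (default 0: a patient's measurements repeat
    their latent value, which keeps the intraclass correlation exactly
    interpretable).
    """

    n_providers: int = 81
    role_weights: tuple[int, int, int] = (47, 31, 3)  # attending, resident, NP
    mean_panel_size: float = 12.0
    frac_eligible: float = 0.65
    index_date: date = date(2017, 8, 14)

    # demographics
    age_mean: float = 70.3
    age_sd: float = 8.9
    p_female: float = 0.45
    race_probs: dict = field(default_factory=lambda: {
        "White": 0.53, "Asian": 0.23, "Black": 0.13, "Hispanic": 0.07, "Other": 0.04})
    language_probs: dict = field(default_factory=lambda: {
        "English": 0.90, "Chinese": 0.07, "Spanish": 0.03})
    insurance_probs: dict = field(default_factory=lambda: {
        "Medicare": 0.41, "Medicaid": 0.31, "Private": 0.28})
    comorbidity_prevalence: dict = field(default_factory=lambda: {
        "hypertension": 0.72, "hyperlipidemia": 0.58, "diabetes": 0.38,
        "cad": 0.18, "chf": 0.08, "cerebrovascular": 0.07})
    med_prevalence: dict = field(default_factory=lambda: {
        "statin": 0.67, "acei_arb": 0.61, "thiazide_diuretic": 0.25,
        "loop_diuretic": 0.13, "beta_blocker": 0.30,
        "calcium_channel_blocker": 0.25, "nsaid": 0.12})
    p_ckd_problem_list: float = 0.12
    p_ckd_visit_dx_extra: float = 0.35  # on top of problem list -> ~47% recognized

    # CKD lab trajectory
    egfr_mean: float = 56.0
    egfr_sd: float = 11.8
    scr_jitter_cv: float = 0.0  # lognormal jitter on creatinine beyond the target eGFR
    # latent triple-marker physiology
    egfr_cys_shift_sd: float = 8.0  # cystatin eGFR scatters around creatinine eGFR
    log_acr_mean: float = 3.2      # lognormal ACR, median ~25 mg/g
    log_acr_sd: float = 1.2
    potassium_mean: float = 4.4
    potassium_sd: float = 0.45

    # blood pressure
    bp_mean: float = 128.0
    bp_sd: float = 5.0
    bp_icc: float = 0.025
    dbp_mean: float = 68.0
    dbp_sd: float = 6.0
    visit_sd: float = 0.0

    # visits
    visits_per_18mo: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_providers <= 0:
            raise ValueError(f"n_providers must be positive, got {self.n_providers}")
        if not 0 <= self.bp_icc < 1:
            raise ValueError(f"bp_icc must be in [0, 1), got {self.bp_icc}")
        if not self.bp_sd > 0:
            raise ValueError(f"bp_sd must be positive, got {self.bp_sd}")
        if self.mean_panel_size < 0:
            raise ValueError(f"mean_panel_size must be >= 0, got {self.mean_panel_size}")
        if not 0 <= self.frac_eligible <= 1:
            raise ValueError(f"frac_eligible must be in [0, 1], got {self.frac_eligible}")
        for name, probs in (("race_probs", self.race_probs),
                            ("language_probs", self.language_probs),
                            ("insurance_probs", self.insurance_probs)):
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has a negative probability")
        for name, prevs in (("comorbidity_prevalence", self.comorbidity_prevalence),
                            ("med_prevalence", self.med_prevalence)):
            for k, p in prevs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{k!r}] must be in [0, 1], got {p}")


_TABLES = ("patients", "providers", "labs", "encounters", "medications",
           "problem_list", "ground_truth")
_DATE_COLS = {
    "patients": ["birth_date"],
    "labs": ["collected_at"],
    "encounters": ["occurred_at"],
    "medications": ["active_from", "active_to"],
    "problem_list": ["noted_at"],
}


@dataclass
class EHRDataset:
    """Linked EHR tables; the substrate every downstream stage consumes."""

    patients: pd.DataFrame
    providers: pd.DataFrame
    labs: pd.DataFrame
    encounters: pd.DataFrame
    medications: pd.DataFrame
    problem_list: pd.DataFrame
    ground_truth: pd.DataFrame

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "EHRDataset":
        path = Path(path)
        frames = {}
        for name in _TABLES:
            f = path / f"{name}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing EHR table: {f}")
            df = pd.read_csv(f)
            for col in _DATE_COLS.get(name, []):
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col]).dt.date
            frames[name] = df
        return cls(**frames)


def _allocate_roles(n: int, weights: tuple[int, int, int]) -> list[str]:
    """Largest-remainder allocation of provider roles: deterministic and
    exact at the observed counts when n equals the weight total."""
    total = sum(weights)
    quotas = [n * w / total for w in weights]
    counts = [int(q) for q in quotas]
    remainders = sorted(range(3), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    roles: list[str] = []
    for role, c in zip(ROLES, counts):
        roles.extend([role] * c)
    return roles


def _scr_for_egfr(target: float, age: float, sex: str) -> float:
    """Invert the CKD-EPI 2009 equation: creatinine giving exactly
    ``target`` eGFR at this age/sex (race coefficient off)."""
    kappa = 0.7 if sex == "female" else 0.9
    at_knot = egfr_creatinine(kappa, age, sex)
    if target <= at_knot:  # scr above the knot
        exponent = -1.209
    else:
        exponent = -0.329 if sex == "female" else -0.411
    return kappa * (target / at_knot) ** (1.0 / exponent)


def generate_bp_series(
    n_visits: int,
    provider_effect: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Systolic/diastolic series for one patient over ``n_visits``
    ambulatory visits under the two-component cluster variance model."""
    resid_sd = config.bp_sd * np.sqrt(1.0 - config.bp_icc)
    patient_resid = rng.normal(0.0, resid_sd) if resid_sd > 0 else 0.0
    sbp = (config.bp_mean + provider_effect + patient_resid
           + (rng.normal(0.0, config.visit_sd, n_visits) if config.visit_sd > 0
              else np.zeros(n_visits)))
    dbp = config.dbp_mean + 0.4 * patient_resid + rng.normal(0.0, config.dbp_sd, n_visits)
    dbp = np.minimum(dbp, sbp - 10.0)  # keep systolic > diastolic
    return sbp, dbp


def provider_effects(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian provider random effects with variance icc * sd**2."""
    sd = config.bp_sd * np.sqrt(config.bp_icc)
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def _draw_cat(rng: np.random.Generator, probs: dict) -> str:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def generate_population(config: GeneratorConfig) -> EHRDataset:
    """Generate a full linked synthetic practice.

    Deterministic for a fixed ``config.seed``.  Eligible-stratum
    patients carry an engineered qualifying eGFR pair; each ineligible
    patient violates exactly one criterion, cycling through the full
    violation list.
    """
    rng = np.random.default_rng(config.seed)
    index = config.index_date

    roles = _allocate_roles(config.n_providers, config.role_weights)
    provider_ids = [f"P{i:03d}" for i in range(config.n_providers)]
    providers = pd.DataFrame({"provider_id": provider_ids, "role": roles})
    peff = provider_effects(config, config.n_providers, rng)

    pat_rows, lab_rows, enc_rows, med_rows, prob_rows, gt_rows = [], [], [], [], [], []
    enc_counter = 0
    violation_cycle = 0
    pid_counter = 0

    panel_sizes = rng.poisson(config.mean_panel_size, config.n_providers)

    for p_idx, prov_id in enumerate(provider_ids):
        for _ in range(panel_sizes[p_idx]):
            pid = f"PT{pid_counter:05d}"
            pid_counter += 1
            eligible = bool(rng.random() < config.frac_eligible)
            violation = ""
            if not eligible:
                violation = VIOLATIONS[violation_cycle % len(VIOLATIONS)]
                violation_cycle += 1

            # --- demographics ---
            if violation == "age_high":
                age = rng.uniform(81.5, 92.0)
            elif violation == "age_low":
                age = rng.uniform(14.0, 17.5)
            else:
                age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.5, 79.5))
            birth_date = index - timedelta(days=int(round(age * DAYS_PER_YEAR)))
            sex = "female" if rng.random() < config.p_female else "male"
            if violation == "language":
                language = "Russian"
            else:
                language = _draw_cat(rng, config.language_probs)
            comorbid = {k: int(rng.random() < p)
                        for k, p in config.comorbidity_prevalence.items()}
            deceased = int(violation == "deceased")
            pat_rows.append({
                "patient_id": pid, "provider_id": prov_id,
                "birth_date": birth_date, "sex": sex,
                "race_ethnicity": _draw_cat(rng, config.race_probs),
                "preferred_language": language,
                "insurance": _draw_cat(rng, config.insurance_probs),
                **comorbid,
                "deceased": deceased,
            })

            # --- creatinine history (drives eligibility) ---
            age_now = age_at(birth_date, index)

            def scr_lab(target_egfr: float, when: date, setting: str = "outpatient"):
                a = age_at(birth_date, when)
                scr = _scr_for_egfr(target_egfr, a, sex)
                if config.scr_jitter_cv > 0:
                    scr *= float(rng.lognormal(0.0, config.scr_jitter_cv))
                lab_rows.append({"patient_id": pid, "analyte": "serum_creatinine",
                                 "value": round(scr, 4), "collected_at": when,
                                 "setting": setting})

            base_egfr = float(np.clip(rng.normal(config.egfr_mean, config.egfr_sd), 30.5, 58.5))
            second_egfr = float(np.clip(base_egfr + rng.normal(0.0, 3.0), 30.5, 58.5))
            d_recent = index - timedelta(days=int(rng.integers(10, 300)))
            d_old = d_recent - timedelta(days=int(rng.integers(95, 400)))

            if violation == "egfr_out_of_range":
                scr_lab(float(rng.uniform(62.0, 85.0)), d_old)
                scr_lab(float(rng.uniform(62.0, 85.0)), d_recent)
            elif violation == "egfr_too_close":
                scr_lab(base_egfr, d_recent - timedelta(days=int(rng.integers(10, 85))))
                scr_lab(second_egfr, d_recent)
            elif violation == "egfr_stale":
                stale_recent = index - timedelta(days=int(rng.integers(400, 700)))
                scr_lab(base_egfr, stale_recent - timedelta(days=int(rng.integers(95, 300))))
                scr_lab(second_egfr, stale_recent)
            elif violation == "egfr_single":
                scr_lab(base_egfr, d_recent)
            else:
                # qualifying pair (also given to patients excluded downstream,
                # so the exclusion cascade is what removes them)
                scr_lab(base_egfr, d_old)
                scr_lab(second_egfr, d_recent)
                # inpatient distractor in range: must not count
                if rng.random() < 0.2:
                    scr_lab(float(rng.uniform(35.0, 55.0)),
                            d_recent - timedelta(days=5), setting="inpatient")

            # potassium history
            if rng.random() < 0.8:
                k_val = float(rng.normal(config.potassium_mean, config.potassium_sd))
                lab_rows.append({"patient_id": pid, "analyte": "potassium",
                                 "value": round(max(k_val, 2.8), 2),
                                 "collected_at": d_recent, "setting": "outpatient"})

            # --- encounters ---
            n_visits = max(1, int(rng.poisson(config.visits_per_18mo)))
            if violation == "no_recent_pcp_visit":
                visit_days = [int(rng.integers(560, 900)) for _ in range(n_visits)]
            else:
                visit_days = sorted(int(rng.integers(1, 540)) for _ in range(n_visits))
            sbp, dbp = generate_bp_series(len(visit_days), peff[p_idx], config, rng)
            for j, dback in enumerate(visit_days):
                enc_rows.append({
                    "encounter_id": f"E{enc_counter:06d}", "patient_id": pid,
                    "provider_id": prov_id, "occurred_at": index - timedelta(days=dback),
                    "type": "pcp_visit",
                    "systolic_bp": round(float(sbp[j]), 1),
                    "diastolic_bp": round(float(dbp[j]), 1),
                })
                enc_counter += 1
            if violation == "nephrology_engaged":
                for dback in (30, 150):
                    enc_rows.append({
                        "encounter_id": f"E{enc_counter:06d}", "patient_id": pid,
                        "provider_id": "NEPH00",
                        "occurred_at": index - timedelta(days=dback),
                        "type": "nephrology_visit",
                        "systolic_bp": np.nan, "diastolic_bp": np.nan,
                    })
                    enc_counter += 1

            # --- medications ---
            for med, prev in config.med_prevalence.items():
                if rng.random() < prev:
                    med_rows.append({
                        "patient_id": pid, "med_class": med,
                        "active_from": index - timedelta(days=int(rng.integers(200, 2000))),
                        "active_to": pd.NaT,
                    })

            # --- problem list ---
            if violation in ("esrd", "transplant", "dementia"):
                prob_rows.append({"patient_id": pid, "code": violation,
                                  "noted_at": index - timedelta(days=int(rng.integers(100, 1500)))})
            has_ckd_pl = rng.random() < config.p_ckd_problem_list
            if has_ckd_pl:
                prob_rows.append({"patient_id": pid, "code": "ckd_problem_list",
                                  "noted_at": index - timedelta(days=int(rng.integers(30, 1000)))})
            if rng.random() < config.p_ckd_visit_dx_extra:
                prob_rows.append({"patient_id": pid, "code": "ckd_visit_dx",
                                  "noted_at": index - timedelta(days=int(rng.integers(30, 1000)))})

            # --- latent triple-marker physiology (ground truth only) ---
            true_egfr_cys = max(8.0, base_egfr + rng.normal(0.0, config.egfr_cys_shift_sd))
            scys = _scys_for_egfr(true_egfr_cys, age_now, sex)
            acr = float(rng.lognormal(config.log_acr_mean, config.log_acr_sd))
            tier = "high" if (true_egfr_cys < 60.0 or acr > 30.0) else "low"
            gt_rows.append({
                "patient_id": pid, "eligible_true": int(eligible),
                "violation": violation,
                "true_scr": round(_scr_for_egfr(second_egfr, age_now, sex), 4),
                "true_scys": round(scys, 4), "true_acr": round(acr, 2),
                "true_egfr_cys": round(true_egfr_cys, 2),
                "true_risk_tier": tier,
            })

    patients = pd.DataFrame(pat_rows)
    labs = pd.DataFrame(lab_rows)
    encounters = pd.DataFrame(enc_rows)
    medications = pd.DataFrame(med_rows)
    problem_list = pd.DataFrame(prob_rows, columns=["patient_id", "code", "noted_at"])
    ground_truth = pd.DataFrame(gt_rows)
    return EHRDataset(patients, providers, labs, encounters, medications,
                      problem_list, ground_truth)


def _scys_for_egfr(target: float, age: float, sex: str) -> float:
    """Invert the CKD-EPI 2012 cystatin equation at this age/sex."""
    at_knot = egfr_cystatin(0.8, age, sex)
    exponent = -0.499 if target > at_knot else -1.328
    return 0.8 * (target / at_knot) ** (1.0 / exponent)
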