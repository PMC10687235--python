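"""Synthetic EMR cohorts with a known logistic outcome model.

Each patient gets a scan date, demographics, pre-scan encounters,
repeated dated vitals/labs with configurable missingness, coded
diagnoses/procedures/medications drawn from the bundled toy ontologies,
and at least a year of post-scan encounters — so every generated record
passes the cohort inclusion filters by construction.  Outcome labels are
drawn from a logistic model on the *latent* (noise-free) patient
features, whose coefficients are retained for recovery tests; positive
patients receive an I20-I25 diagnosis code inside the follow-up horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from ..emr.records import Code, Observation, PatientRecord
from .phantom import SyntheticCohortSpec, _solve_intercept

#: Latent feature names an EMR outcome model may reference.
EMR_FEATURES = ("age", "sex_male", "sbp", "glucose", "bmi", "ldl", "hdl", "charlson")

#: Default planted model: conventional cardiovascular risk-factor signs.
DEFAULT_EMR_COEFFICIENTS = {
    "age": 0.9,
    "sex_male": 0.5,
    "sbp": 0.6,
    "glucose": 0.8,
    "charlson": 0.5,
}

# Measurement noise (sd) around each latent value when recorded in the chart.
_MEAS_SD = {
    "sbp": 4.0,
    "dbp": 3.0,
    "bmi": 0.4,
    "total_chol": 6.0,
    "ldl": 5.0,
    "hdl": 2.5,
    "triglycerides": 10.0,
    "glucose": 5.0,
    "hba1c": 0.15,
}


@dataclass
class EmrCohort:
    records: list[PatientRecord]
    labels: np.ndarray
    latent: pd.DataFrame
    true_linear_predictor: np.ndarray
    coefficients: dict[str, float]


def make_emr_cohort(
    spec: SyntheticCohortSpec,
    missing_rate: float = 0.10,
    horizon_years: int = 1,
    scan_date: date = date(2016, 6, 1),
) -> EmrCohort:
    """Generate records plus labels from the cohort's planted logistic model.

    Coefficients act on z-scored latent features; an intercept is solved so
    expected prevalence matches the target.  ``missing_rate`` is the chance
    an entire lab series is absent from a chart (0 means no missing labs).
    The label RNG stream is separate from the chart-noise stream.
    """
    coeffs = spec.outcome_coefficients or dict(DEFAULT_EMR_COEFFICIENTS)
    unknown = set(coeffs) - set(EMR_FEATURES)
    if unknown:
        raise ValueError(f"outcome coefficients reference unknown features: {sorted(unknown)}")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")

    chart_rng = np.random.default_rng([spec.seed, 10])
    label_rng = np.random.default_rng([spec.seed, 11])
    n = spec.n_patients

    # latent physiology
    age = chart_rng.uniform(25.0, 85.0, n)
    sex_male = (chart_rng.uniform(size=n) < 0.45).astype(float)
    diabetes = (chart_rng.uniform(size=n) < 0.15).astype(float)
    renal = (chart_rng.uniform(size=n) < 0.07).astype(float)
    hypertensive = (chart_rng.uniform(size=n) < 0.2 + 0.004 * (age - 40)).astype(float)
    latent = pd.DataFrame(
        {
            "age": age,
            "sex_male": sex_male,
            "sbp": 118 + 0.25 * (age - 50) + 12 * hypertensive + chart_rng.normal(0, 9, n),
            "dbp": 76 + 5 * hypertensive + chart_rng.normal(0, 6, n),
            "bmi": np.clip(27 + chart_rng.normal(0, 4, n), 16, 55),
            "total_chol": 195 + chart_rng.normal(0, 28, n),
            "ldl": 115 + chart_rng.normal(0, 24, n),
            "hdl": np.clip(52 - 4 * sex_male + chart_rng.normal(0, 11, n), 20, 110),
            "triglycerides": np.clip(130 + chart_rng.normal(0, 45, n), 40, 500),
            "glucose": 96 + 32 * diabetes + chart_rng.normal(0, 11, n),
            "hba1c": 5.4 + 1.5 * diabetes + chart_rng.normal(0, 0.3, n),
            "charlson": diabetes * 1 + renal * 2,
        }
    )

    z = (latent - latent.mean()) / latent.std(ddof=0).replace(0.0, 1.0)
    lp = np.zeros(n)
    for name, beta in coeffs.items():
        lp += beta * z[name].to_numpy()
    # noise perturbs the label draw only; the retained oracle predictor is β·z
    noisy = lp + label_rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else lp
    intercept = _solve_intercept(noisy, spec.prevalence_target)
    prob = 1.0 / (1.0 + np.exp(-(noisy + intercept)))
    labels = (label_rng.uniform(size=n) < prob).astype(int)

    records = []
    horizon_days = round(horizon_years * 365.25)
    for i in range(n):
        pid = f"P{i:05d}"
        birth = scan_date - timedelta(days=round(age[i] * 365.25))
        encounters = sorted(
            scan_date - timedelta(days=int(d))
            for d in chart_rng.integers(1, 360, size=int(chart_rng.integers(2, 7)))
        )
        # guaranteed follow-up beyond the horizon
        encounters += sorted(
            scan_date + timedelta(days=int(d))
            for d in [int(chart_rng.integers(20, 300)), horizon_days + int(chart_rng.integers(5, 200))]
        )

        observations: list[Observation] = []
        vitals = ("sbp", "dbp", "bmi")
        for name in _MEAS_SD:
            if name not in vitals and chart_rng.uniform() < missing_rate:
                continue  # this lab never measured for this patient
            n_meas = 1 + int(chart_rng.poisson(1.5 if name in vitals else 0.8))
            days = chart_rng.integers(0, 360, size=n_meas)
            for d in days:
                value = float(latent.loc[i, name] + chart_rng.normal(0.0, _MEAS_SD[name]))
                observations.append(
                    Observation(scan_date - timedelta(days=int(d)), name, value)
                )

        codes: list[Code] = []

        def hist_day() -> date:
            return scan_date - timedelta(days=int(chart_rng.integers(5, 360)))

        if hypertensive[i]:
            codes.append(Code(hist_day(), "ICD10", "I10"))
            if chart_rng.uniform() < 0.6:
                codes.append(Code(hist_day(), "DRUG", "C03AA03"))  # a diuretic
        if diabetes[i]:
            codes.append(Code(hist_day(), "ICD10", "E11.9"))
            codes.append(Code(hist_day(), "DRUG", "A10BA02"))
        if renal[i]:
            codes.append(Code(hist_day(), "ICD10", "N18.3"))
        if chart_rng.uniform() < 0.3:
            codes.append(Code(hist_day(), "ICD10", "R07.9"))
        if chart_rng.uniform() < 0.4:
            codes.append(Code(hist_day(), "DRUG", "C10AA05"))  # a statin
        for _ in range(int(chart_rng.poisson(1.2))):
            codes.append(Code(hist_day(), "CPT", "99213"))
        if chart_rng.uniform() < 0.5:
            codes.append(Code(hist_day(), "CPT", "80061"))
        if labels[i]:
            onset = scan_date + timedelta(days=int(label_rng.integers(30, horizon_days)))
            codes.append(Code(onset, "ICD10", "I21.4"))

        records.append(
            PatientRecord(
                patient_id=pid,
                scan_date=scan_date,
                birthdate=birth,
                sex="M" if sex_male[i] else "F",
                encounters=encounters,
                observations=observations,
                codes=codes,
            )
        )
    return EmrCohort(records, labels, latent, lp, dict(coeffs))
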