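"""Longitudinal patient records, outcome labelling and cohort construction.

The outcome is a new ischemic-heart-disease (IHD) diagnosis, defined as
any ICD10 code in I20-I25 dated strictly after the scan and within the
follow-up horizon.  History windows are half-open: (scan - 365 d, scan]
for pre-scan features, (scan, scan + horizon] for the outcome.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

DAYS_PER_YEAR = 365.25
IHD_PREFIXES = ("I20", "I21", "I22", "I23", "I24", "I25")


@dataclass
class Observation:
    when: date
    name: str
    value: float


@dataclass
class Code:
    when: date
    system: str  # ICD10 | CPT | DRUG
    code: str


@dataclass
class PatientRecord:
    """One patient's scan anchor plus their longitudinal EMR streams."""

    patient_id: str
    scan_date: date
    birthdate: date
    sex: str  # "M" | "F"
    encounters: list[date] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    codes: list[Code] = field(default_factory=list)

    @property
    def age_at_scan(self) -> float:
        return (self.scan_date - self.birthdate).days / DAYS_PER_YEAR

    def observations_named(self, name: str) -> list[Observation]:
        return [o for o in self.observations if o.name == name]


def _is_ihd(code: str) -> bool:
    return code.replace(".", "").upper().startswith(IHD_PREFIXES)


def has_prior_ihd(record: PatientRecord) -> bool:
    """Any IHD diagnosis at or before the scan (an exclusion, not a label)."""
    return any(
        c.system == "ICD10" and _is_ihd(c.code) and c.when <= record.scan_date
        for c in record.codes
    )


def label_outcome(record: PatientRecord, horizon_years: int) -> bool:
    """True iff an I20-I25 code falls in (scan, scan + horizon]."""
    horizon_end = record.scan_date + timedelta(days=round(horizon_years * DAYS_PER_YEAR))
    return any(
        c.system == "ICD10"
        and _is_ihd(c.code)
        and record.scan_date < c.when <= horizon_end
        for c in record.codes
    )


@dataclass
class FilterAudit:
    """Per-rule removal counts; input = included + sum of drops."""

    n_input: int
    n_included: int
    dropped: Counter = field(default_factory=Counter)
    drop_reasons: dict[str, str] = field(default_factory=dict)  # "patient_id@scan_date" -> rule

    def conserved(self) -> bool:
        return self.n_input == self.n_included + sum(self.dropped.values())


def apply_inclusion_filters(
    records: list[PatientRecord],
    horizon_years: int = 1,
    min_age: float = 18.0,
    dedup_window_days: int = 183,
) -> tuple[list[PatientRecord], FilterAudit]:
    """Apply the cohort inclusion rules and account for every removal.

    Rules, applied in order per record: adult age at scan; at least one
    clinical encounter in the year before the scan; no IHD diagnosis prior
    to or at the scan; adequate follow-up (an outcome within the horizon, or
    an encounter at least ``horizon_years`` after the scan).  Finally, among
    multiple scans of the same patient, later scans falling within six
    months of an already included scan are dropped (chronological greedy).
    """
    audit = FilterAudit(n_input=len(records), n_included=0)
    survivors: list[PatientRecord] = []
    for rec in records:
        rule = None
        year_before = rec.scan_date - timedelta(days=365)
        horizon_end = rec.scan_date + timedelta(days=round(horizon_years * DAYS_PER_YEAR))
        if rec.age_at_scan < min_age:
            rule = "age_under_18"
        elif not any(year_before < e <= rec.scan_date for e in rec.encounters):
            rule = "no_prior_year_encounter"
        elif has_prior_ihd(rec):
            rule = "prior_ihd"
        elif not label_outcome(rec, horizon_years) and not any(
            e >= horizon_end for e in rec.encounters
        ):
            rule = "insufficient_follow_up"
        if rule is None:
            survivors.append(rec)
        else:
            audit.dropped[rule] += 1
            audit.drop_reasons[f"{rec.patient_id}@{rec.scan_date}"] = rule

    # 6-month dedup among survivors, chronological greedy per patient
    included: list[PatientRecord] = []
    last_kept: dict[str, date] = {}
    for rec in sorted(survivors, key=lambda r: (r.patient_id, r.scan_date)):
        prev = last_kept.get(rec.patient_id)
        if prev is not None and (rec.scan_date - prev).days < dedup_window_days:
            audit.dropped["within_6_months_of_included_scan"] += 1
            audit.drop_reasons[f"{rec.patient_id}@{rec.scan_date}"] = (
                "within_6_months_of_included_scan"
            )
            continue
        last_kept[rec.patient_id] = rec.scan_date
        included.append(rec)
    audit.n_included = len(included)
    return included, audit


def stratified_split(
    labels: np.ndarray, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-stratified train/test index split (80/20 by default).

    Prevalence is equal between splits up to integer rounding and the split
    is deterministic per seed.  A single-class cohort still splits, with a
    warning.
    """
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class cohort: split is unstratified", stacklevel=2)
    train_idx, test_idx = [], []
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        idx = rng.permutation(idx)
        n_test = round(len(idx) * test_fraction)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))
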