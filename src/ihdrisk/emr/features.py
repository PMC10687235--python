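"""EMR feature engineering: temporal aggregation, ontology rollups,
comorbidity indexing, correlation pruning and targeted imputation.

Every feature a record produces is named and tagged with a provenance
class (demographic, vital, lab, count, icd_block, cpt_group, atc_group,
charlson).  Missing values are NaN and flow through to learners that
handle missingness natively; only explicitly targeted features (the
lipid covariates needed by baseline risk scores) are median-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources

import numpy as np
import pandas as pd

from .records import PatientRecord

HISTORY_DAYS = 365


@dataclass(frozen=True)
class OntologyMap:
    """Longest-prefix code → group mapping for one coding system."""

    system: str
    prefixes: dict[str, str]  # code prefix -> group name

    def lookup(self, code: str) -> str | None:
        code = code.replace(".", "").upper()
        best = None
        for prefix, group in self.prefixes.items():
            if code.startswith(prefix) and (best is None or len(prefix) > len(best[0])):
                best = (prefix, group)
        return best[1] if best else None

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.prefixes.values()))


def load_ontology_tsv(path_or_name) -> OntologyMap:
    """Load a (system, prefix, group, description) TSV; bundled names allowed.

    Bundled maps: ``icd10_blocks.tsv``, ``cpt_h2.tsv``, ``atc_level2.tsv``.
    """
    df = _read_config_tsv(path_or_name)
    systems = df["system"].unique()
    if len(systems) != 1:
        raise ValueError(f"one system per ontology map, got {systems}")
    return OntologyMap(str(systems[0]), dict(zip(df["prefix"].astype(str), df["group"])))


def _read_config_tsv(path_or_name) -> pd.DataFrame:
    candidate = str(path_or_name)
    if "/" not in candidate and not candidate.startswith("."):
        ref = resources.files("ihdrisk.config") / candidate
        if ref.is_file():
            with resources.as_file(ref) as p:
                return pd.read_csv(p, sep="\t", dtype=str)
    return pd.read_csv(candidate, sep="\t", dtype=str)


def load_charlson_map(path_or_name="charlson_icd10.tsv") -> pd.DataFrame:
    """Charlson condition map: columns condition, weight, prefix."""
    df = _read_config_tsv(path_or_name)
    df["weight"] = df["weight"].astype(int)
    return df


def exp_weighted_value(
    values,
    times,
    scan_time: date,
    decay_per_day: float = np.log(2) / 30.0,
    scheme: str = "exponential",
) -> float:
    """Time-weighted average of repeated measurements before a scan.

    Weights decrease with the gap Δt (days) between measurement and scan:
    ``exponential`` uses u = exp(-λ·Δt) (default half-life 30 days), and
    ``inverse_time`` uses u = 1/(1 + Δt), the alternative reading of
    "inversely proportional to the difference in time".  An empty series
    yields NaN (a missing marker), not an error.
    """
    values = list(values)
    times = list(times)
    if len(values) != len(times):
        raise ValueError("values and times must pair up")
    if not values:
        return float("nan")
    if decay_per_day < 0:
        raise ValueError("decay must be >= 0")
    dt = np.array([(scan_time - t).days for t in times], dtype=float)
    if (dt < 0).any():
        raise ValueError("measurement after scan time")
    if scheme == "exponential":
        # shift by the smallest gap so extreme decay rates cannot underflow
        u = np.exp(-decay_per_day * (dt - dt.min()))
    elif scheme == "inverse_time":
        u = 1.0 / (1.0 + dt)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    v = np.asarray(values, dtype=float)
    return float((u * v).sum() / u.sum())


def measurement_count(times, scan_time: date, window_days: int = HISTORY_DAYS) -> int:
    """Number of dated observations in the (scan - window, scan] history."""
    start = scan_time - timedelta(days=window_days)
    return sum(1 for t in times if start < t <= scan_time)


def rollup_codes(
    codes, maps: list[OntologyMap], scan_time: date, window_days: int = HISTORY_DAYS
) -> tuple[dict[str, int], list[str]]:
    """Occurrence counts per ontology group over the pre-scan year.

    Returns (group counts over all maps' groups, list of unmapped codes).
    Unmapped codes are reported, never fatal.
    """
    start = scan_time - timedelta(days=window_days)
    counts = {g: 0 for m in maps for g in m.groups}
    by_system = {m.system: m for m in maps}
    unmapped: list[str] = []
    for c in codes:
        if not start < c.when <= scan_time:
            continue
        m = by_system.get(c.system)
        if m is None:
            continue
        group = m.lookup(c.code)
        if group is None:
            unmapped.append(c.code)
        else:
            counts[group] += 1
    return counts, unmapped


def charlson_index(codes, charlson_map: pd.DataFrame, scan_time: date | None = None) -> int:
    """Charlson Comorbidity Index: sum of weights over distinct conditions.

    A condition matched by several codes counts once.  When ``scan_time`` is
    given only codes at or before the scan qualify (comorbidity is history).
    """
    matched: dict[str, int] = {}
    rows = list(zip(charlson_map["condition"], charlson_map["weight"], charlson_map["prefix"]))
    for c in codes:
        if c.system != "ICD10":
            continue
        if scan_time is not None and c.when > scan_time:
            continue
        code = c.code.replace(".", "").upper()
        for condition, weight, prefix in rows:
            if code.startswith(prefix):
                matched[condition] = int(weight)
    return sum(matched.values())


def prune_correlated(
    table: pd.DataFrame, r_max: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop features until max pairwise |Pearson r| <= r_max.

    Missing values are pairwise-excluded from r.  Of an offending pair the
    later column (in the table's column order) is dropped — a deterministic
    rule.  Strictly-greater comparison: a pair at exactly r_max survives.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    cols = list(table.columns)
    dropped: list[str] = []
    while True:
        sub = table[cols]
        corr = sub.corr(method="pearson").abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        if corr.max() <= r_max:
            break
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        victim = cols[max(i, j)]
        dropped.append(victim)
        cols.remove(victim)
    return table[cols], dropped


def impute_targeted_median(
    features: pd.DataFrame,
    targets: list[str],
    training_medians: pd.Series | None = None,
    train_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Median-impute only the named features; all other NaNs pass through.

    Medians come from ``training_medians`` or are computed on the rows
    selected by ``train_mask`` (never on test rows).  An all-missing target
    with no explicit median is an error.
    """
    out = features.copy()
    for name in targets:
        if name not in out.columns:
            raise KeyError(f"target feature {name!r} not present")
        if training_medians is not None and name in training_medians.index:
            med = training_medians[name]
        else:
            col = out[name] if train_mask is None else out.loc[train_mask, name]
            med = col.median()
        if pd.isna(med):
            raise ValueError(
                f"feature {name!r} is all-missing in training; provide an explicit median"
            )
        out[name] = out[name].fillna(float(med))
    return out


DEFAULT_VITALS = ("sbp", "dbp", "bmi")
DEFAULT_LABS = ("total_chol", "ldl", "hdl", "triglycerides", "glucose", "hba1c")


@dataclass
class FeatureConfig:
    """Names and parameters fixing the feature vector of a pipeline."""

    vitals: tuple[str, ...] = DEFAULT_VITALS
    labs: tuple[str, ...] = DEFAULT_LABS
    decay_per_day: float = np.log(2) / 30.0
    weighting: str = "exponential"
    ontology_maps: list[OntologyMap] = field(default_factory=list)
    charlson_map: pd.DataFrame | None = None

    @classmethod
    def with_bundled_maps(cls, **kwargs) -> "FeatureConfig":
        maps = [
            load_ontology_tsv("icd10_blocks.tsv"),
            load_ontology_tsv("cpt_h2.tsv"),
            load_ontology_tsv("atc_level2.tsv"),
        ]
        return cls(ontology_maps=maps, charlson_map=load_charlson_map(), **kwargs)

    def feature_names(self) -> list[str]:
        names = ["age", "sex_male"]
        for v in (*self.vitals, *self.labs):
            names += [v, f"{v}_n_measurements"]
        for m in self.ontology_maps:
            names += m.groups
        if self.charlson_map is not None:
            names.append("charlson_index")
        return names

    def provenance(self) -> dict[str, str]:
        tag = {"age": "demographic", "sex_male": "demographic"}
        for v in self.vitals:
            tag[v] = "vital"
            tag[f"{v}_n_measurements"] = "count"
        for l in self.labs:
            tag[l] = "lab"
            tag[f"{l}_n_measurements"] = "count"
        kind = {"ICD10": "icd_block", "CPT": "cpt_group", "DRUG": "atc_group"}
        for m in self.ontology_maps:
            for g in m.groups:
                tag[g] = kind.get(m.system, "code_group")
        if self.charlson_map is not None:
            tag["charlson_index"] = "charlson"
        return tag


def build_feature_vector(record: PatientRecord, config: FeatureConfig) -> pd.Series:
    """Deterministic fixed-name feature vector for one record.

    Demographics (age at scan in years, male-sex indicator; race/ethnicity
    deliberately excluded), exponentially time-weighted vitals and labs with
    measurement counts, ontology-group occurrence counts, and the Charlson
    index.  Order of same-day events does not affect the result.
    """
    start = record.scan_date - timedelta(days=HISTORY_DAYS)
    values: dict[str, float] = {
        "age": record.age_at_scan,
        "sex_male": 1.0 if record.sex.upper().startswith("M") else 0.0,
    }
    for name in (*config.vitals, *config.labs):
        obs = [
            o
            for o in record.observations_named(name)
            if start < o.when <= record.scan_date
        ]
        obs.sort(key=lambda o: (o.when, o.value))  # stable under same-day reordering
        values[name] = exp_weighted_value(
            [o.value for o in obs],
            [o.when for o in obs],
            record.scan_date,
            decay_per_day=config.decay_per_day,
            scheme=config.weighting,
        )
        values[f"{name}_n_measurements"] = float(len(obs))
    counts, _ = rollup_codes(record.codes, config.ontology_maps, record.scan_date)
    values.update({k: float(v) for k, v in counts.items()})
    if config.charlson_map is not None:
        values["charlson_index"] = float(
            charlson_index(record.codes, config.charlson_map, record.scan_date)
        )
    return pd.Series(values, index=config.feature_names(), dtype=float)


def build_feature_table(records: list[PatientRecord], config: FeatureConfig) -> pd.DataFrame:
    """Stack per-record feature vectors into a patients × features table."""
    table = pd.DataFrame(
        [build_feature_vector(r, config) for r in records],
        index=[r.patient_id for r in records],
    )
    return table
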