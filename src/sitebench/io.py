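"""Delimited-file I/O, schema validation and cohort summary tables.

File dialect: UTF-8 CSV with a header row; sex coded F/M, diagnosis coded
MDD/HC; the missing-value token is the empty string.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (Dataset, FeatureMatrix, ROSTER_OPTIONAL,
                         ROSTER_REQUIRED, validate_roster)
from .errors import IntegrityError, SchemaError
from .schema import FEATURE_CLASSES, FeatureSchema, canonical_schema


def read_dataset(roster_path, features_path) -> Dataset:
    """Read roster and feature CSVs and join them on subject_id.

    Subjects present in only one of the two files are rejected; empty cells
    in the feature file become masked entries.
    """
    roster = pd.read_csv(roster_path, dtype={"subject_id": str})
    roster = validate_roster(roster)
    feats = pd.read_csv(features_path, dtype={"subject_id": str})
    fm = FeatureMatrix.from_dataframe(feats)

    roster_ids = set(roster["subject_id"])
    feat_ids = set(fm.subjects)
    if len(feat_ids) != len(fm.subjects):
        dupes = sorted({s for s in fm.subjects if fm.subjects.count(s) > 1})
        raise IntegrityError(f"duplicate subject_id in feature file: {dupes}")
    only_roster = sorted(roster_ids - feat_ids)
    only_feats = sorted(feat_ids - roster_ids)
    if only_roster or only_feats:
        raise IntegrityError(
            "subjects present in only one file: "
            f"roster-only={only_roster}, features-only={only_feats}")
    # align feature rows to roster order
    order = {s: i for i, s in enumerate(fm.subjects)}
    rows = [order[s] for s in roster["subject_id"]]
    return Dataset(roster, fm.take(rows))


def write_dataset(dataset: Dataset, roster_path, features_path,
                  float_format: str = "%.10g") -> None:
    cols = list(ROSTER_REQUIRED) + list(ROSTER_OPTIONAL)
    dataset.roster[cols].to_csv(roster_path, index=False,
                                float_format=float_format)
    dataset.features.to_dataframe().to_csv(features_path, index=False,
                                           float_format=float_format)


def summarize_by_cohort(roster: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort counts and demographics plus an all-sites total row.

    Columns: cohort, n_total, n_hc, n_mdd, age_mean, age_sd, n_female,
    pct_female. A single-subject cohort reports age_sd = 0.
    """
    if len(roster) == 0:
        raise SchemaError("roster is empty")

    def one(group: pd.DataFrame, label: str) -> dict:
        ages = group["age"].dropna()
        sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
        n_female = int((group["sex"] == "F").sum())
        return {
            "cohort": label,
            "n_total": int(len(group)),
            "n_hc": int((group["dx"] == "HC").sum()),
            "n_mdd": int((group["dx"] == "MDD").sum()),
            "age_mean": float(ages.mean()) if len(ages) else float("nan"),
            "age_sd": sd,
            "n_female": n_female,
            "pct_female": 100.0 * n_female / len(group),
        }

    rows = [one(g, site) for site, g in roster.groupby("site", sort=True)]
    rows.append(one(roster, "ALL"))
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Outcome of feature-schema validation."""

    passed: bool
    class_counts: dict
    n_features: int
    missing_features: list = field(default_factory=list)
    duplicate_features: list = field(default_factory=list)
    nonfinite_entries: list = field(default_factory=list)  # (subject, feature)
    messages: list = field(default_factory=list)


def validate_schema(fm: FeatureMatrix) -> ValidationReport:
    """Check the 68/68/16 feature layout and observed-value finiteness."""
    canon = canonical_schema()
    counts = fm.schema.class_counts()
    expected = canon.class_counts()
    messages = []
    missing = [n for n in canon.names if n not in fm.schema.names]
    passed = True
    if counts != expected:
        passed = False
        messages.append(f"class counts {counts} != expected {expected}")
    if missing:
        passed = False
        messages.append(f"missing features: {missing}")
    # duplicates are rejected at FeatureSchema construction; re-check raw names
    seen, dupes = set(), []
    for n in fm.schema.names:
        if n in seen:
            dupes.append(n)
        seen.add(n)
    nonfinite = []
    with np.errstate(invalid="ignore"):
        bad = fm.mask & ~np.isfinite(fm.values)
    for i, j in zip(*np.nonzero(bad)):
        nonfinite.append((fm.subjects[i], fm.schema.names[j]))
    if nonfinite:
        passed = False
        messages.append(f"non-finite observed values at {nonfinite}")
    return ValidationReport(passed=passed, class_counts=counts,
                            n_features=len(fm.schema),
                            missing_features=missing,
                            duplicate_features=dupes,
                            nonfinite_entries=nonfinite,
                            messages=messages)
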