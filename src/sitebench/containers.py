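"""In-memory containers: subject roster and masked feature matrix."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError
from .schema import FeatureSchema, canonical_schema

ROSTER_REQUIRED = ("subject_id", "site", "age", "sex", "dx", "icv")
ROSTER_OPTIONAL = ("onset_group", "antidepressant", "episodes")
SEX_LEVELS = ("F", "M")
DX_LEVELS = ("MDD", "HC")
OPTIONAL_LEVELS = {
    "onset_group": ("adolescent", "adult"),
    "antidepressant": ("yes", "no"),
    "episodes": ("first", "recurrent"),
}


def validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    """Validate mandatory columns, vocabularies and subject uniqueness.

    Returns a normalized copy: optional columns present (NaN where absent),
    subject_id as string index-free column.
    """
    for col in ROSTER_REQUIRED:
        if col not in roster.columns:
            raise SchemaError(f"roster is missing mandatory column {col!r}")
    roster = roster.copy()
    roster["subject_id"] = roster["subject_id"].astype(str)
    dup = roster["subject_id"][roster["subject_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate subject_id: {sorted(set(dup))}")
    bad_sex = set(roster["sex"]) - set(SEX_LEVELS)
    if bad_sex:
        raise SchemaError(f"sex must be one of {SEX_LEVELS}, got {sorted(bad_sex)}")
    bad_dx = set(roster["dx"]) - set(DX_LEVELS)
    if bad_dx:
        raise SchemaError(f"dx must be one of {DX_LEVELS}, got {sorted(bad_dx)}")
    if (roster["age"] <= 0).any():
        raise SchemaError("age must be positive")
    if (roster["icv"] <= 0).any():
        raise SchemaError("icv must be positive")
    for col, levels in OPTIONAL_LEVELS.items():
        if col not in roster.columns:
            roster[col] = pd.NA
        else:
            vals = roster[col].dropna()
            bad = set(vals) - set(levels)
            if bad:
                raise SchemaError(f"{col} must be one of {levels}, got {sorted(bad)}")
    return roster.reset_index(drop=True)


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with an observedness mask.

    ``values`` entries where ``mask`` is False carry no numeric meaning;
    they are stored as NaN by convention but never read.
    """

    subjects: list[str]
    schema: FeatureSchema
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, p = self.values.shape
        if len(self.subjects) != n:
            raise SchemaError("subject list does not match value rows")
        if p != len(self.schema):
            raise SchemaError(
                f"value columns ({p}) do not match schema ({len(self.schema)})")
        if self.mask.shape != self.values.shape:
            raise SchemaError("mask shape does not match values")
        # non-finite observed entries are representable but flagged by
        # io.validate_schema rather than rejected at construction

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(list(self.subjects), self.schema,
                             self.values.copy(), self.mask.copy())

    def take(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix([self.subjects[i] for i in rows], self.schema,
                             self.values[rows], self.mask[rows])

    def completeness(self) -> np.ndarray:
        """Fraction of observed features per subject."""
        return self.mask.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.names))
        df = df.mask(~self.mask)
        df.insert(0, "subject_id", self.subjects)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       schema: FeatureSchema | None = None) -> "FeatureMatrix":
        if "subject_id" not in df.columns:
            raise SchemaError("feature table is missing subject_id column")
        feat_cols = [c for c in df.columns if c != "subject_id"]
        if schema is None:
            canon = canonical_schema()
            unknown = [c for c in feat_cols if c not in canon.names]
            if unknown:
                raise SchemaError(f"unknown feature names: {unknown}")
            # canonical column order, independent of file order
            ordered = [n for n in canon.names if n in feat_cols]
            from .schema import schema_from_names
            schema = schema_from_names(ordered)
        else:
            missing = [n for n in schema.names if n not in feat_cols]
            if missing:
                raise SchemaError(f"feature table is missing columns: {missing}")
            ordered = list(schema.names)
        values = df[ordered].to_numpy(dtype=float)
        mask = ~np.isnan(values)
        return cls([str(s) for s in df["subject_id"]], schema, values, mask)


@dataclass
class Dataset:
    """A roster joined with its feature matrix, rows aligned."""

    roster: pd.DataFrame
    features: FeatureMatrix

    def __post_init__(self):
        if list(self.roster["subject_id"]) != list(self.features.subjects):
            raise IntegrityError("roster and feature matrix subject order differ")

    @property
    def n_subjects(self) -> int:
        return len(self.roster)

    def take(self, rows) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(self.roster.iloc[rows].reset_index(drop=True),
                       self.features.take(rows))

    def subset_features(self, subset: str) -> "Dataset":
        cols = self.features.schema.subset(subset)
        from .schema import schema_from_names
        names = [self.features.schema.names[i] for i in cols]
        sub_schema = schema_from_names(names)
        fm = FeatureMatrix(list(self.features.subjects), sub_schema,
                           self.features.values[:, cols],
                           self.features.mask[:, cols])
        return Dataset(self.roster, fm)
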