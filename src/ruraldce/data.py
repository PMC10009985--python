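"""Choice-data model: attribute schema, long-format paired-choice datasets,
design-matrix encoding and CSV input/output.

Everything downstream — design construction, simulation, estimation and
post-estimation — consumes the types defined here.  The encoding column
order is a single global contract: the coefficient vector of every
estimator is indexed by :meth:`AttributeSchema.encoded_columns`, in schema
order, with exactly one column per linear attribute and one column per
non-reference level of each categorical attribute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: A profile is one level assignment per attribute, in schema order.
Profile = tuple

#: Labels for the two alternatives of a paired choice task.
ALTERNATIVES = ("A", "B")

#: Conversion rate used when the salary attribute is reported in USD.
#: All computation is done in ETB; this is metadata only.
ETB_PER_USD = 41.0


class SchemaError(ValueError):
    """Raised for invalid attribute schemas or level labels."""


@dataclass(frozen=True)
class Attribute:
    """One choice attribute: its levels and how it enters the design matrix.

    Parameters
    ----------
    name
        Attribute identifier, used as the level column name in datasets.
    levels
        Ordered level labels.
    coding
        ``"linear"`` (one numeric column) or ``"categorical"``
        (dummy columns against ``reference``).
    reference
        Reference level for categorical coding; encodes to all-zero dummies.
    numeric_values
        Level label -> numeric value, required for linear coding
        (e.g. monthly salary in ETB).
    """

    name: str
    levels: tuple
    coding: str = "categorical"
    reference: str | None = None
    numeric_values: dict | None = None

    def __post_init__(self):
        if len(self.levels) < 2:
            raise SchemaError(f"attribute {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"attribute {self.name!r} has duplicate levels")
        if self.coding == "linear":
            if self.numeric_values is None or set(self.numeric_values) != set(self.levels):
                raise SchemaError(
                    f"linear attribute {self.name!r} needs a numeric value per level"
                )
        elif self.coding == "categorical":
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise SchemaError(
                    f"reference {ref!r} of attribute {self.name!r} not among its levels"
                )
            object.__setattr__(self, "reference", ref)
        else:
            raise SchemaError(f"unknown coding {self.coding!r}")

    @property
    def encoded_columns(self) -> tuple:
        if self.coding == "linear":
            return (self.name,)
        return tuple(
            f"{self.name}_{lv}" for lv in self.levels if lv != self.reference
        )

    def encode_level(self, level) -> tuple:
        """Numeric encoding of one level, aligned with ``encoded_columns``."""
        if level not in self.levels:
            raise SchemaError(f"unknown level {level!r} for attribute {self.name!r}")
        if self.coding == "linear":
            return (float(self.numeric_values[level]),)
        return tuple(
            1.0 if level == lv else 0.0 for lv in self.levels if lv != self.reference
        )

    def decode(self, values: tuple):
        """Inverse of :meth:`encode_level`."""
        if self.coding == "linear":
            for lv, num in self.numeric_values.items():
                if np.isclose(values[0], num):
                    return lv
            raise SchemaError(f"no level of {self.name!r} has value {values[0]}")
        nonref = [lv for lv in self.levels if lv != self.reference]
        hot = [lv for lv, v in zip(nonref, values) if round(v) == 1]
        if len(hot) > 1:
            raise SchemaError(f"multiple dummies set for attribute {self.name!r}")
        return hot[0] if hot else self.reference


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of attributes defining the choice experiment."""

    attributes: tuple

    def __post_init__(self):
        if not self.attributes:
            raise SchemaError("schema has no attributes")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names")

    @property
    def names(self) -> tuple:
        return tuple(a.name for a in self.attributes)

    @property
    def encoded_columns(self) -> tuple:
        """Design-matrix column order shared by all estimators."""
        return tuple(c for a in self.attributes for c in a.encoded_columns)

    @property
    def n_profiles(self) -> int:
        """Full factorial size (product of level counts)."""
        n = 1
        for a in self.attributes:
            n *= len(a.levels)
        return n

    def __getitem__(self, name) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def validate_profile(self, profile: Profile) -> None:
        if len(profile) != len(self.attributes):
            raise SchemaError(
                f"profile has {len(profile)} levels, schema has "
                f"{len(self.attributes)} attributes"
            )
        for attr, level in zip(self.attributes, profile):
            if level not in attr.levels:
                raise SchemaError(
                    f"unknown level {level!r} for attribute {attr.name!r}"
                )

    def encode_profile(self, profile: Profile) -> np.ndarray:
        self.validate_profile(profile)
        return np.concatenate(
            [attr.encode_level(lv) for attr, lv in zip(self.attributes, profile)]
        )

    def decode_profile(self, row: np.ndarray) -> Profile:
        out, i = [], 0
        for attr in self.attributes:
            k = len(attr.encoded_columns)
            out.append(attr.decode(tuple(row[i : i + k])))
            i += k
        return tuple(out)

    # -- serialisation --------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "attributes": [
                {
                    "name": a.name,
                    "levels": list(a.levels),
                    "coding": a.coding,
                    **({"reference": a.reference} if a.coding == "categorical" else {}),
                    **(
                        {"numeric_values": {k: float(v) for k, v in a.numeric_values.items()}}
                        if a.numeric_values
                        else {}
                    ),
                }
                for a in self.attributes
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AttributeSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        attrs = tuple(
            Attribute(
                name=a["name"],
                levels=tuple(a["levels"]),
                coding=a.get("coding", "categorical"),
                reference=a.get("reference"),
                numeric_values=a.get("numeric_values"),
            )
            for a in doc["attributes"]
        )
        return cls(attrs)


def default_schema() -> AttributeSchema:
    """The six-attribute rural-job schema.

    Monthly salary is linear with four levels — the 9,056 ETB base plus
    rural allowances of 25/50/75% (steps of 2,264 ETB); the five remaining
    attributes are binary with the less attractive level as reference:
    basic vs superior housing, inadequate vs adequate drug and medical
    supply, two vs one mandatory service years before study leave,
    unsupportive vs supportive management, heavy vs normal workload.
    """
    return AttributeSchema(
        (
            Attribute(
                "salary",
                ("base", "base+25%", "base+50%", "base+75%"),
                coding="linear",
                numeric_values={
                    "base": 9056.0,
                    "base+25%": 11320.0,
                    "base+50%": 13584.0,
                    "base+75%": 15848.0,
                },
            ),
            Attribute("housing", ("basic", "superior"), reference="basic"),
            Attribute("drug_supply", ("inadequate", "adequate"), reference="inadequate"),
            Attribute("service", ("twoyears", "oneyear"), reference="twoyears"),
            Attribute("management", ("unsupportive", "supportive"), reference="unsupportive"),
            Attribute("workload", ("heavy", "normal"), reference="heavy"),
        )
    )


def enumerate_full_factorial(schema: AttributeSchema):
    """Every distinct profile exactly once, in lexicographic level order."""
    return [
        tuple(combo)
        for combo in itertools.product(*(a.levels for a in schema.attributes))
    ]


# ---------------------------------------------------------------------------
# Choice dataset


#: Columns every long-format choice CSV must carry, before attribute columns.
ID_COLUMNS = ("respondent_id", "task_id", "alt", "chosen")
COVARIATE_COLUMNS = ("age", "sex")


@dataclass
class ChoiceDataset:
    """Long-format paired-choice panel.

    One row per (respondent, task, alternative); two alternatives "A"/"B"
    per task, exactly one with ``chosen == 1``.  Attribute columns hold
    level labels; respondent covariates (age in years, sex in
    {male, female}) repeat within a respondent.  "Observation" counts the
    respondent-tasks, i.e. half the number of rows.
    """

    df: pd.DataFrame
    schema: AttributeSchema

    @property
    def n_respondents(self) -> int:
        return self.df["respondent_id"].nunique()

    @property
    def n_observations(self) -> int:
        """Respondent-task pairs (choice sets), not rows."""
        return len(self.df.drop_duplicates(["respondent_id", "task_id"]))

    @property
    def n_tasks_per_respondent(self) -> int:
        counts = self.df.groupby("respondent_id")["task_id"].nunique()
        if counts.nunique() != 1:
            raise ValueError("unbalanced panel: tasks per respondent differ")
        return int(counts.iloc[0])

    def validate(self, age_range: tuple = (21, 28)) -> list:
        """Invariant checks; returns a list of violation strings (empty iff valid)."""
        report = []
        df = self.df
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            return [f"missing required columns: {missing}"]
        for name in self.schema.names:
            if name not in df.columns:
                report.append(f"missing attribute column {name!r}")
            else:
                bad = set(df[name]) - set(self.schema[name].levels)
                if bad:
                    report.append(f"unknown levels {sorted(bad)} in attribute {name!r}")
        for (rid, tid), grp in df.groupby(["respondent_id", "task_id"]):
            if len(grp) != 2:
                report.append(
                    f"respondent {rid} task {tid} has {len(grp)} alternative(s), expected 2"
                )
                continue
            n_chosen = int(grp["chosen"].sum())
            if n_chosen != 1:
                report.append(
                    f"respondent {rid} task {tid} has {n_chosen} chosen alternatives"
                )
            if set(grp["alt"]) != set(ALTERNATIVES):
                report.append(f"respondent {rid} task {tid} alternatives != {{A, B}}")
        if "age" in df.columns:
            ages = df.groupby("respondent_id")["age"].first()
            out = ages[(ages < age_range[0]) | (ages > age_range[1])]
            for rid, a in out.items():
                report.append(
                    f"respondent {rid} age {a} outside configured range {age_range} (warning)"
                )
        if "sex" in df.columns:
            bad = set(df["sex"].dropna()) - {"male", "female"}
            if bad:
                report.append(f"unknown sex labels {sorted(bad)}")
        return report

    # -- I/O ------------------------------------------------------------

    def to_csv(self, path) -> None:
        cols = [c for c in ID_COLUMNS] + list(self.schema.names)
        cols += [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: AttributeSchema) -> "ChoiceDataset":
        df = pd.read_csv(path)
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        ds = cls(df, schema)
        violations = [v for v in ds.validate() if "warning" not in v]
        if violations:
            raise ValueError(f"{path}: invalid choice data: " + "; ".join(violations[:5]))
        return ds


def read_choice_csv(path, schema: AttributeSchema) -> ChoiceDataset:
    return ChoiceDataset.from_csv(path, schema)


def write_choice_csv(dataset: ChoiceDataset, path) -> None:
    dataset.to_csv(path)


# ---------------------------------------------------------------------------
# Encoding


@dataclass
class EncodedMatrix:
    """Numeric design matrix row-aligned with a :class:`ChoiceDataset`."""

    X: np.ndarray
    columns: tuple
    index: pd.Index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.columns), index=self.index)


def encode(dataset: ChoiceDataset, schema: AttributeSchema) -> EncodedMatrix:
    """Encode level labels into the shared design-matrix layout.

    Linear attributes map to their numeric value (salary in ETB/month);
    each non-reference categorical level maps to a 0/1 dummy.  Raises on
    any level label absent from the schema, naming the offending record.
    """
    df = dataset.df
    blocks = []
    for attr in schema.attributes:
        col = df[attr.name]
        bad = ~col.isin(attr.levels)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            rec = df.iloc[i]
            raise SchemaError(
                f"record (respondent {rec['respondent_id']}, task {rec['task_id']}, "
                f"alt {rec['alt']}): unknown level {rec[attr.name]!r} "
                f"for attribute {attr.name!r}"
            )
        lut = {lv: attr.encode_level(lv) for lv in attr.levels}
        blocks.append(np.array([lut[v] for v in col], dtype=float))
    X = np.hstack(blocks)
    return EncodedMatrix(X, schema.encoded_columns, df.index)


def paired_differences(dataset: ChoiceDataset, schema: AttributeSchema):
    """Reduce each paired task to (x_A - x_B, chose_A).

    Returns ``(dx, y, respondent_ids)`` with one row per respondent-task:
    ``dx`` the encoded attribute difference between alternatives A and B,
    ``y`` 1 if A was chosen, and the respondent id of each task (for panel
    grouping).  For two-alternative tasks the conditional logit likelihood
    depends on the data only through these differences.
    """
    enc = encode(dataset, schema)
    df = dataset.df.reset_index(drop=True)
    X = enc.X
    order = np.lexsort(
        (df["alt"].to_numpy(), df["task_id"].to_numpy(), df["respondent_id"].to_numpy())
    )
    X = X[order]
    sub = df.iloc[order]
    alt = sub["alt"].to_numpy()
    if not (np.all(alt[0::2] == "A") and np.all(alt[1::2] == "B")):
        raise ValueError("each (respondent, task) must have exactly alternatives A and B")
    dx = X[0::2] - X[1::2]
    y = sub["chosen"].to_numpy()[0::2].astype(float)
    resp = sub["respondent_id"].to_numpy()[0::2]
    return dx, y, resp


def respondent_covariates(dataset: ChoiceDataset) -> pd.DataFrame:
    """Per-respondent covariate table (first row of each respondent)."""
    cols = [c for c in COVARIATE_COLUMNS if c in dataset.df.columns]
    return (
        dataset.df.groupby("respondent_id")[cols].first()
        if cols
        else pd.DataFrame(index=dataset.df["respondent_id"].unique())
    )
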