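"""Reading, writing and summarising sustained-phonation vocal feature tables.

The canonical input is a comma-separated table in the layout of the UCI
Machine Learning Repository "Parkinsons" dataset: one row per voice record,
a ``name`` column (``phon_R01_S<nn>_<k>``), 22 numeric vocal measures
(MDVP perturbation measures plus nonlinear dynamics measures), and a binary
``status`` column (1 = Parkinson's disease, 0 = healthy control).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Exact UCI header strings, in file order (status column excluded).
UCI_MEASURES: tuple[str, ...] = (
    "MDVP:Fo(Hz)",
    "MDVP:Fhi(Hz)",
    "MDVP:Flo(Hz)",
    "MDVP:Jitter(%)",
    "MDVP:Jitter(Abs)",
    "MDVP:RAP",
    "MDVP:PPQ",
    "Jitter:DDP",
    "MDVP:Shimmer",
    "MDVP:Shimmer(dB)",
    "Shimmer:APQ3",
    "Shimmer:APQ5",
    "MDVP:APQ",
    "Shimmer:DDA",
    "NHR",
    "HNR",
    "RPDE",
    "DFA",
    "spread1",
    "spread2",
    "D2",
    "PPE",
)

#: Alias map from spellings commonly used in the dysphonia literature to the
#: exact UCI header strings.
MEASURE_ALIASES: dict[str, str] = {
    "MDVP: F0": "MDVP:Fo(Hz)",
    "MDVP:F0": "MDVP:Fo(Hz)",
    "MDVP: F0 (Hz)": "MDVP:Fo(Hz)",
    "MDVP: Jitter (%)": "MDVP:Jitter(%)",
    "MDVP: Jitter (Abs)": "MDVP:Jitter(Abs)",
    "MDVP: RAP": "MDVP:RAP",
    "MDVP: PPQ": "MDVP:PPQ",
    "Jitter: DDP": "Jitter:DDP",
    "MDVP: Shimmer": "MDVP:Shimmer",
    "MDVP: Shimmer (dB)": "MDVP:Shimmer(dB)",
    "Shimmer: APQ3": "Shimmer:APQ3",
    "Shimmer: APQ5": "Shimmer:APQ5",
    "MDVP: APQ11": "MDVP:APQ",
    "Shimmer: DDA": "Shimmer:DDA",
    "Spread1": "spread1",
    "Spread2": "spread2",
}

LABEL_CO = "CO"
LABEL_PD = "PD"

_RECORD_ID_RE = re.compile(r"^phon_R\d+_(S\d+)_\d+$")


class FormatError(ValueError):
    """Input file does not follow the expected column layout."""


class ParseError(ValueError):
    """A cell could not be parsed as a numeric measure."""


def canonical_measure_name(name: str) -> str:
    """Map a literature spelling (e.g. ``"Spread2"``) to the UCI header string."""
    return MEASURE_ALIASES.get(name, name)


@dataclass
class VocalRecord:
    """One sustained-vowel voice record with its vocal measures and class label."""

    record_id: str
    subject_id: str
    measures: dict[str, float]
    label: str  # "CO" or "PD"

    def vector(self, measure_names: list[str] | tuple[str, ...]) -> np.ndarray:
        return np.array([self.measures[m] for m in measure_names], dtype=float)


@dataclass
class FeatureTable:
    """Records-by-measures table with binary class labels.

    Thin wrapper over a pandas DataFrame preserving measure order and
    record/subject identity.
    """

    records: list[VocalRecord]
    measure_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record_id in feature table")
        for r in self.records:
            missing = [m for m in self.measure_names if m not in r.measures]
            if missing:
                raise ValueError(f"record {r.record_id} missing measures {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def matrix(self, measures: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
        names = list(measures) if measures is not None else self.measure_names
        names = [canonical_measure_name(m) for m in names]
        unknown = [m for m in names if m not in self.measure_names]
        if unknown:
            raise KeyError(f"unknown measures: {unknown}")
        return np.array([[r.measures[m] for m in names] for r in self.records])

    def y(self) -> np.ndarray:
        """0/1 label vector (1 = PD)."""
        return (self.labels == LABEL_PD).astype(int)

    def class_counts(self) -> dict[str, int]:
        lab = self.labels
        return {LABEL_CO: int((lab == LABEL_CO).sum()), LABEL_PD: int((lab == LABEL_PD).sum())}

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable([self.records[i] for i in np.asarray(idx, dtype=int)],
                            list(self.measure_names))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.measures for r in self.records], columns=list(self.measure_names))
        df.insert(0, "name", self.record_ids)
        df["status"] = self.y()
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return _table_from_dataframe(df)


@dataclass
class SubjectInfo:
    """Per-subject metadata: demographics and Hoehn & Yahr disease stage."""

    subject_id: str
    gender: str = "unknown"  # "M", "F" or "unknown"
    age: int | None = None
    group: str | None = None  # "CO" or "PD"
    hy_stage: float | None = None

    def __post_init__(self) -> None:
        if self.group == LABEL_CO and self.hy_stage is not None:
            raise ValueError("healthy controls carry no H&Y stage")


# Published per-subject metadata for the subjects appearing in the study's
# misclassification listings (bundled fixture; metadata is optional and
# pipeline stages run with labels only).
SUBJECT_METADATA: dict[str, SubjectInfo] = {
    s.subject_id: s
    for s in [
        SubjectInfo("S02", "M", 60, "PD", 2.0),
        SubjectInfo("S04", "M", 70, "PD", 2.5),
        SubjectInfo("S08", "F", 48, "PD", 2.0),
        SubjectInfo("S19", "M", 73, "PD", 1.0),
        SubjectInfo("S20", "M", 70, "PD", 3.0),
        SubjectInfo("S25", "M", 74, "PD", 3.0),
        SubjectInfo("S26", "F", 53, "PD", 2.0),
        SubjectInfo("S27", "M", 72, "PD", 2.5),
        SubjectInfo("S32", "M", 50, "PD", 1.0),
        SubjectInfo("S42", "F", 66, "CO", None),
        SubjectInfo("S43", "M", 62, "CO", None),
        SubjectInfo("S49", "M", 69, "CO", None),
        SubjectInfo("S50", "F", 66, "CO", None),
    ]
}


def parse_subject_id(record_id: str) -> tuple[str, bool]:
    """Extract the subject token ``S<nn>`` from a ``phon_R01_S<nn>_<k>`` record id.

    Returns ``(subject_id, matched)``. On pattern mismatch the record id is
    returned unchanged with ``matched=False`` and a warning is emitted.
    """
    m = _RECORD_ID_RE.match(record_id)
    if m:
        return m.group(1), True
    warnings.warn(f"record id {record_id!r} does not follow the phon_R01_S<nn>_<k> pattern",
                  stacklevel=2)
    return record_id, False


def _table_from_dataframe(df: pd.DataFrame) -> FeatureTable:
    if "status" not in df.columns:
        raise FormatError("missing required column: status")
    if "name" not in df.columns:
        raise FormatError("missing required column: name")
    measure_names = [c for c in df.columns if c not in ("name", "status")]
    records = []
    for _, row in df.iterrows():
        rid = str(row["name"])
        measures = {}
        for m in measure_names:
            try:
                measures[m] = float(row[m])
            except (TypeError, ValueError) as exc:
                raise ParseError(f"non-numeric value {row[m]!r} for measure {m} "
                                 f"in record {rid}") from exc
        try:
            status = int(row["status"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric status {row['status']!r} in record {rid}") from exc
        label = LABEL_PD if status == 1 else LABEL_CO
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            subject, _ = parse_subject_id(rid)
        records.append(VocalRecord(rid, subject, measures, label))
    return FeatureTable(records, measure_names)


def load_feature_table(path, dialect: str = "uci") -> FeatureTable:
    """Load a UCI-layout vocal feature table from a CSV file.

    The ``status`` column is mapped to class labels (1 -> PD, 0 -> CO) and
    removed from the measures; measure order is preserved from the header.
    """
    if dialect != "uci":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    return _table_from_dataframe(df)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table back to the canonical CSV layout (inverse of load)."""
    table.to_dataframe().to_csv(path, index=False)


def summarize_groups(table: FeatureTable, measures: list[str]) -> pd.DataFrame:
    """Per-class mean and sample standard deviation (n-1 denominator) per measure.

    Returns a DataFrame indexed by measure with columns
    ``(CO, mean), (CO, sd), (PD, mean), (PD, sd)``.
    """
    names = [canonical_measure_name(m) for m in measures]
    unknown = [m for m in names if m not in table.measure_names]
    if unknown:
        raise KeyError(f"unknown measures: {unknown}")
    lab = table.labels
    out = {}
    for cls in (LABEL_CO, LABEL_PD):
        mask = lab == cls
        if not mask.any():
            raise ValueError(f"no records in class {cls}")
        X = table.matrix(names)[mask]
        out[(cls, "mean")] = X.mean(axis=0)
        # sample SD matches the published group statistics convention
        out[(cls, "sd")] = X.std(axis=0, ddof=1) if mask.sum() > 1 else np.zeros(len(names))
    df = pd.DataFrame(out, index=names)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


def summary_to_json(summary: pd.DataFrame) -> str:
    payload = {
        measure: {
            cls: {"mean": float(summary.loc[measure, (cls, "mean")]),
                  "sd": float(summary.loc[measure, (cls, "sd")])}
            for cls in (LABEL_CO, LABEL_PD)
        }
        for measure in summary.index
    }
    return json.dumps(payload, indent=2)
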