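"""Survey schema, ingestion, reverse scoring, dose encoding and cohort descriptives.

The survey instrument consists of Likert items grouped into named scales
(e.g. the four vaccination-attitude scales CoVaH, T-DiG, TRUST-Ph, TiPHA),
an ordinal vaccine-dose outcome (0-5 doses, "5 or more" capped at 5) and
categorical demographic variables. Only complete responses are retained:
rows with missing or out-of-range item values are rejected, not imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "EncodingError",
    "ScaleDefinition",
    "SurveySchema",
    "SurveyDataset",
    "CohortSummary",
    "DOSE_LABELS",
    "encode_dose",
    "reverse_score",
    "load_survey",
    "summarize_cohort",
    "dose_summary_from_counts",
]


class SchemaError(ValueError):
    """The schema and the data file disagree (e.g. a named column is absent)."""


class ValidationError(ValueError):
    """A respondent row violates the declared Likert ranges or invariants."""


class EncodingError(ValueError):
    """A dose label is not in the declared label set."""


#: Default mapping from dose-category labels to integer dose counts.
#: "5 or more" is capped at 5, following the usual top-coded questionnaire
#: category.
DOSE_LABELS: dict[str, int] = {
    "0": 0,
    "1": 1,
    "2": 2,
    "3": 3,
    "4": 4,
    "5": 5,
    "5 or more": 5,
}

MAX_DOSE = 5


@dataclass(frozen=True)
class ScaleDefinition:
    """One named scale: its items, Likert range and reverse-phrased items.

    Parameters
    ----------
    scale_id
        Scale label, e.g. ``"CoVaH"``.
    item_ids
        Ordered item identifiers (column names in the survey table).
    likert_min, likert_max
        Inclusive response range (1..5 for CoVaH/T-DiG/TRUST-Ph, 1..4 for
        TiPHA).
    reverse_items
        Items phrased opposite to the scale direction; their responses are
        reflected onto the common direction by :func:`reverse_score`.
    prefix
        Short letter used to build factor identifiers (``C-c1`` etc.).
        Defaults to the first character of ``scale_id``.
    """

    scale_id: str
    item_ids: tuple[str, ...]
    likert_min: int = 1
    likert_max: int = 5
    reverse_items: frozenset[str] = field(default_factory=frozenset)
    prefix: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "reverse_items", frozenset(self.reverse_items))
        if not self.item_ids:
            raise SchemaError(f"scale {self.scale_id!r} has no items")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise SchemaError(f"scale {self.scale_id!r} has duplicate item ids")
        if not self.reverse_items <= set(self.item_ids):
            extra = sorted(self.reverse_items - set(self.item_ids))
            raise SchemaError(
                f"reverse items {extra} not declared in scale {self.scale_id!r}"
            )
        if self.likert_min >= self.likert_max:
            raise SchemaError(
                f"scale {self.scale_id!r}: likert_min must be < likert_max"
            )
        if not self.prefix:
            object.__setattr__(self, "prefix", self.scale_id[0].upper())

    def reflect(self, value):
        """Reflect a response onto the common direction: v -> min + max - v."""
        return self.likert_min + self.likert_max - value


@dataclass(frozen=True)
class SurveySchema:
    """Column map tying a delimited file to scales, dose and demographics."""

    scales: tuple[ScaleDefinition, ...]
    dose_column: str
    demographic_columns: tuple[str, ...] = ()
    id_column: str | None = None
    dose_labels: Mapping[str, int] = field(default_factory=lambda: dict(DOSE_LABELS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(self.scales))
        object.__setattr__(
            self, "demographic_columns", tuple(self.demographic_columns)
        )
        all_items = [i for s in self.scales for i in s.item_ids]
        if len(set(all_items)) != len(all_items):
            raise SchemaError("item ids are not unique across scales")

    @property
    def item_ids(self) -> list[str]:
        return [i for s in self.scales for i in s.item_ids]

    def scale_of(self, item_id: str) -> ScaleDefinition:
        for s in self.scales:
            if item_id in s.item_ids:
                return s
        raise SchemaError(f"item {item_id!r} not declared in any scale")

    def to_yaml(self, path) -> None:
        raw = {
            "scales": [
                {
                    "scale_id": s.scale_id,
                    "items": list(s.item_ids),
                    "likert_min": s.likert_min,
                    "likert_max": s.likert_max,
                    "reverse_items": sorted(s.reverse_items),
                    "prefix": s.prefix,
                }
                for s in self.scales
            ],
            "dose_column": self.dose_column,
            "demographic_columns": list(self.demographic_columns),
            "id_column": self.id_column,
            "dose_labels": dict(self.dose_labels),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)

    @classmethod
    def from_yaml(cls, path) -> "SurveySchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scales = tuple(
            ScaleDefinition(
                scale_id=s["scale_id"],
                item_ids=tuple(s["items"]),
                likert_min=int(s.get("likert_min", 1)),
                likert_max=int(s.get("likert_max", 5)),
                reverse_items=frozenset(s.get("reverse_items", [])),
                prefix=s.get("prefix", ""),
            )
            for s in raw["scales"]
        )
        return cls(
            scales=scales,
            dose_column=raw["dose_column"],
            demographic_columns=tuple(raw.get("demographic_columns", [])),
            id_column=raw.get("id_column"),
            dose_labels=raw.get("dose_labels", dict(DOSE_LABELS)),
        )


@dataclass
class SurveyDataset:
    """Validated respondent-level survey table.

    ``responses`` is a respondents x items integer frame, ``dose`` an
    integer series in 0..5 and ``demographics`` a respondents x variables
    frame of category labels, all sharing one index of respondent ids.
    """

    responses: pd.DataFrame
    dose: pd.Series
    demographics: pd.DataFrame
    scales: tuple[ScaleDefinition, ...]
    reverse_applied: bool = False

    def __post_init__(self) -> None:
        self.scales = tuple(self.scales)
        self.validate()

    @property
    def respondent_ids(self) -> pd.Index:
        return self.responses.index

    @property
    def n(self) -> int:
        return len(self.responses)

    def scale(self, scale_id: str) -> ScaleDefinition:
        for s in self.scales:
            if s.scale_id == scale_id:
                return s
        raise SchemaError(f"unknown scale {scale_id!r}")

    def validate(self) -> None:
        if self.responses.index.has_duplicates:
            dupes = self.responses.index[self.responses.index.duplicated()]
            raise ValidationError(f"duplicate respondent ids: {list(dupes[:5])}")
        if not self.responses.index.equals(self.dose.index):
            raise ValidationError("responses and dose indexes differ")
        if len(self.demographics) and not self.responses.index.equals(
            self.demographics.index
        ):
            raise ValidationError("responses and demographics indexes differ")
        if self.responses.isna().any().any():
            raise ValidationError("missing item responses after ingestion")
        for s in self.scales:
            block = self.responses[list(s.item_ids)]
            bad = (block < s.likert_min) | (block > s.likert_max)
            if bad.any().any():
                col = bad.any(axis=0).idxmax()
                row = bad[col].idxmax()
                raise ValidationError(
                    f"response out of range [{s.likert_min}, {s.likert_max}] "
                    f"at respondent {row!r}, item {col!r}"
                )
        dose = self.dose.to_numpy()
        if ((dose < 0) | (dose > MAX_DOSE)).any():
            raise ValidationError("dose outside 0..5")

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            responses=self.responses.copy(),
            dose=self.dose.copy(),
            demographics=self.demographics.copy(),
            scales=self.scales,
            reverse_applied=self.reverse_applied,
        )


def encode_dose(raw_label, labels: Mapping[str, int] | None = None) -> int:
    """Encode a dose-category label as an integer dose count (0..5).

    The top category "5 or more" is coded 5. Unknown labels raise
    :class:`EncodingError`.
    """
    labels = dict(DOSE_LABELS) if labels is None else labels
    key = str(raw_label).strip()
    if key in labels:
        return int(labels[key])
    raise EncodingError(f"unrecognized dose label {raw_label!r}")


def reverse_score(dataset: SurveyDataset) -> SurveyDataset:
    """Reflect reverse-phrased items onto the common scale direction.

    Each declared reverse item value v becomes likert_min + likert_max - v;
    the operation is an involution (applying twice restores the input).
    """
    responses = dataset.responses.copy()
    for s in dataset.scales:
        for item in s.reverse_items:
            responses[item] = s.reflect(responses[item])
    return SurveyDataset(
        responses=responses,
        dose=dataset.dose.copy(),
        demographics=dataset.demographics.copy(),
        scales=dataset.scales,
        reverse_applied=not dataset.reverse_applied,
    )


def load_survey(
    path,
    schema: SurveySchema,
    *,
    on_invalid: str = "raise",
    sep: str | None = None,
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Read a delimited survey file and return a validated dataset.

    Parameters
    ----------
    path
        CSV/TSV file with a header row, one row per respondent.
    schema
        Column map (scales, dose column, demographics, optional id column).
    on_invalid
        ``"raise"`` (default) raises :class:`ValidationError` on the first
        offending row; ``"drop"`` rejects offending rows and reports them.
    sep
        Field separator; inferred from the extension when omitted.

    Returns
    -------
    (dataset, rejected)
        The dataset of complete, in-range rows and a frame describing any
        rejected rows (empty under ``on_invalid="raise"``).
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)

    needed = list(schema.item_ids) + [schema.dose_column] + list(
        schema.demographic_columns
    )
    if schema.id_column:
        needed.append(schema.id_column)
    for col in needed:
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    if schema.id_column:
        frame = frame.set_index(schema.id_column)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()]
        raise ValidationError(f"duplicate respondent ids: {list(dupes[:5])}")

    reasons: dict = {}

    def _flag(idx, reason):
        reasons.setdefault(idx, reason)

    items = frame[schema.item_ids]
    numeric = items.apply(pd.to_numeric, errors="coerce")
    for rid in numeric.index[numeric.isna().any(axis=1)]:
        col = numeric.columns[numeric.loc[rid].isna()][0]
        _flag(rid, f"missing or non-numeric item {col!r}")
    for s in schema.scales:
        block = numeric[list(s.item_ids)]
        bad = (block < s.likert_min) | (block > s.likert_max)
        for rid in bad.index[bad.any(axis=1)]:
            col = bad.columns[bad.loc[rid]][0]
            _flag(
                rid,
                f"item {col!r} outside [{s.likert_min}, {s.likert_max}]",
            )

    dose = pd.Series(index=frame.index, dtype=float)
    for rid, raw in frame[schema.dose_column].items():
        try:
            dose.loc[rid] = encode_dose(raw, schema.dose_labels)
        except EncodingError:
            _flag(rid, f"unrecognized dose label {raw!r}")

    demo = frame[list(schema.demographic_columns)]
    for rid in demo.index[demo.isna().any(axis=1)]:
        col = demo.columns[demo.loc[rid].isna()][0]
        _flag(rid, f"missing demographic {col!r}")

    if reasons and on_invalid == "raise":
        rid, why = next(iter(reasons.items()))
        raise ValidationError(f"respondent {rid!r}: {why}")

    keep = frame.index.difference(pd.Index(reasons.keys()), sort=False)
    keep.name = frame.index.name
    rejected = pd.DataFrame(
        {"respondent_id": list(reasons), "reason": list(reasons.values())}
    )
    dataset = SurveyDataset(
        responses=numeric.loc[keep].astype(int),
        dose=dose.loc[keep].astype(int).rename("dose"),
        demographics=demo.loc[keep].astype(str),
        scales=schema.scales,
    )
    return dataset, rejected


@dataclass
class CohortSummary:
    """Table-1 style cohort descriptives."""

    n: int
    dose_counts: dict[int, int]
    dose_mean: float
    ever_vaccinated_pct: float
    demographic_frequencies: dict[str, dict[str, tuple[int, float]]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "dose_counts": {str(k): v for k, v in self.dose_counts.items()},
                "dose_mean": round(self.dose_mean, 4),
                "ever_vaccinated_pct": round(self.ever_vaccinated_pct, 1),
                "demographic_frequencies": {
                    var: {cat: [cnt, round(pct, 1)] for cat, (cnt, pct) in cats.items()}
                    for var, cats in self.demographic_frequencies.items()
                },
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"Cohort summary (n = {self.n})", ""]
        lines.append("Total number of vaccine doses received")
        for d in sorted(self.dose_counts):
            cnt = self.dose_counts[d]
            label = f"{d} or more" if d == MAX_DOSE else str(d)
            lines.append(f"  {label}\t{cnt} ({100.0 * cnt / self.n:.1f})")
        lines.append(f"Mean doses: {self.dose_mean:.1f}")
        lines.append(f"Ever vaccinated: {self.ever_vaccinated_pct:.1f}%")
        for var, cats in self.demographic_frequencies.items():
            lines.append("")
            lines.append(var)
            for cat, (cnt, pct) in cats.items():
                lines.append(f"  {cat}\t{cnt} ({pct:.1f})")
        return "\n".join(lines)


def summarize_cohort(dataset: SurveyDataset) -> CohortSummary:
    """Compute dose descriptives and per-variable frequency tables."""
    if dataset.n == 0:
        raise ValidationError("cannot summarize an empty dataset")
    dose = dataset.dose.to_numpy()
    counts = {int(d): int((dose == d).sum()) for d in range(MAX_DOSE + 1)}
    freqs: dict[str, dict[str, tuple[int, float]]] = {}
    for var in dataset.demographics.columns:
        vc = dataset.demographics[var].value_counts()
        freqs[var] = {
            str(cat): (int(cnt), 100.0 * cnt / dataset.n) for cat, cnt in vc.items()
        }
    return CohortSummary(
        n=dataset.n,
        dose_counts=counts,
        dose_mean=float(dose.mean()),
        ever_vaccinated_pct=100.0 * float((dose > 0).mean()),
        demographic_frequencies=freqs,
    )


def dose_summary_from_counts(dose_counts: Mapping[int, int]) -> tuple[float, float]:
    """Mean dose and ever-vaccinated percentage from a dose-count table.

    Useful for published frequency tables where only per-category counts are
    printed. Returns ``(dose_mean, ever_vaccinated_pct)``.
    """
    n = sum(dose_counts.values())
    if n == 0:
        raise ValidationError("empty dose-count table")
    mean = sum(d * c for d, c in dose_counts.items()) / n
    ever = 100.0 * (n - dose_counts.get(0, 0)) / n
    return float(mean), float(ever)
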