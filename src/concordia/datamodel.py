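"""Shared data containers for paired transcriptome/proteome cohort analysis.

The pipeline operates on three kinds of objects:

* :class:`ExpressionMatrix` — one ome's feature-by-sample table. Transcript
  matrices hold nonnegative integer read counts; protein matrices hold
  nonnegative intensities where ``NaN`` marks "not detected" (intensity-based
  mass spectrometry reports absence, not zero).
* :class:`CohortDesign` — the sample-to-group assignment (case vs control).
* :class:`GeneSetCollection` — named feature sets (GO-style terms or curated
  functional groups such as respiratory complexes).

All joins are keyed by feature-id strings; nothing relies on row position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSCRIPT = "transcript"
PROTEIN = "protein"
OMES = (TRANSCRIPT, PROTEIN)

CASE = "case"
CONTROL = "control"

CATEGORIES = ("cellular_component", "biological_process", "functional_group")

#: accepted spellings of group labels in design tables
_GROUP_SYNONYMS = {
    "case": CASE, "pd": CASE, "patient": CASE, "disease": CASE,
    "control": CONTROL, "hc": CONTROL, "healthy": CONTROL, "ctrl": CONTROL,
}


def normalize_group_label(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _GROUP_SYNONYMS:
        raise ValueError(
            f"unrecognized group label {label!r}; expected one of "
            f"{sorted(_GROUP_SYNONYMS)}"
        )
    return _GROUP_SYNONYMS[key]


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values for a single ome.

    Parameters
    ----------
    ome
        ``"transcript"`` or ``"protein"``.
    values
        DataFrame indexed by feature id, columns are sample ids. Transcript
        values must be nonnegative integers with no missing cells; protein
        values are nonnegative reals where ``NaN`` means "not detected".
    feature_length_bp
        Optional per-feature length in base pairs (transcripts only;
        required for FPKM).
    """

    ome: str
    values: pd.DataFrame
    feature_length_bp: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.ome not in OMES:
            raise ValueError(f"ome must be one of {OMES}, got {self.ome!r}")
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        try:
            arr = v.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression values: {exc}") from exc
        if self.ome == TRANSCRIPT:
            if np.isnan(arr).any():
                raise ValueError("missing values are not permitted in a "
                                 "transcript count matrix")
            if not np.array_equal(arr, np.rint(arr)):
                raise ValueError("transcript counts must be integers")
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("expression values must be nonnegative")
        self.values = v.astype(float)
        self.values.index.name = "feature_id"
        self.values.columns.name = None
        if self.feature_length_bp is not None:
            lengths = pd.Series(self.feature_length_bp, dtype=float)
            lengths = lengths.reindex(v.index)
            if lengths.isna().any() or (lengths <= 0).any():
                raise ValueError("feature_length_bp must be positive and "
                                 "cover every feature")
            self.feature_length_bp = lengths

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortDesign:
    """Mapping sample id -> group ("case" or "control")."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = {
            str(s): normalize_group_label(g) for s, g in self.assignments.items()
        }
        for group in (CASE, CONTROL):
            if len(self.samples(group)) < 2:
                raise ValueError(f"need at least 2 samples per group; "
                                 f"group {group!r} has {len(self.samples(group))}")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @property
    def case_samples(self) -> list[str]:
        return self.samples(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples(CONTROL)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.sets:
            key = (s.category, s.name)
            if key in seen:
                raise ValueError(f"duplicate gene set name {s.name!r} in "
                                 f"category {s.category!r}")
            seen.add(key)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def by_category(self, category: str) -> list[GeneSet]:
        return [s for s in self.sets if s.category == category]
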