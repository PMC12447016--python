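"""Domain types and tabular I/O for lung-sound annotation studies.

A study is a long-format table of ratings: one row per (patient, chest
position, rater). Chest positions are the six standard anatomic
auscultation sites, carried here only as integer codes 1-6. Each rating is
first a judgement of interpretability (at least one audible breath cycle);
interpretable recordings are classified normal or abnormal, and abnormal
ones may carry a subtype (wheeze, crackle, or both).

Missing recordings are represented by absence of rows, never by a sentinel
label. Column values are case-insensitive on read and canonical lower-case
on write.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

__all__ = [
    "Status",
    "Subtype",
    "Role",
    "Provenance",
    "PositionLabel",
    "Rating",
    "FinalLabel",
    "StudyDataset",
    "read_ratings",
    "write_ratings",
    "read_final_labels",
    "write_final_labels",
    "RATINGS_COLUMNS",
    "FINAL_LABEL_COLUMNS",
]


class Status(str, enum.Enum):
    NORMAL = "normal"
    ABNORMAL = "abnormal"


class Subtype(str, enum.Enum):
    WHEEZE = "wheeze"
    CRACKLE = "crackle"
    BOTH = "both"


class Role(str, enum.Enum):
    PRIMARY = "primary"
    ARBITRATOR1 = "arbitrator1"
    ARBITRATOR2 = "arbitrator2"
    AI_ITERATION = "ai_iteration"
    CLINICIAN = "clinician"


class Provenance(str, enum.Enum):
    PRIMARY_CONSENSUS = "primary_consensus"
    ARBITRATOR1 = "arbitrator1"
    ARBITRATOR2 = "arbitrator2"
    SINGLE_SOURCE = "single_source"


@dataclass(frozen=True)
class PositionLabel:
    """One classification of one chest-position recording.

    Invariants: ``status`` is present iff ``interpretable``; ``subtype``
    may be present only when ``status`` is abnormal (and may be absent
    even then — subtyping is optional).
    """

    interpretable: bool
    status: Optional[Status] = None
    subtype: Optional[Subtype] = None

    def __post_init__(self) -> None:
        if self.interpretable and self.status is None:
            raise ValidationError("interpretable label must carry a status")
        if not self.interpretable and self.status is not None:
            raise ValidationError("uninterpretable label cannot carry a status")
        if self.subtype is not None and self.status is not Status.ABNORMAL:
            raise ValidationError("subtype is only defined for abnormal labels")

    # -- constructors -------------------------------------------------
    @classmethod
    def uninterpretable(cls) -> "PositionLabel":
        return cls(interpretable=False)

    @classmethod
    def normal(cls) -> "PositionLabel":
        return cls(interpretable=True, status=Status.NORMAL)

    @classmethod
    def abnormal(cls, subtype: Optional[Subtype] = None) -> "PositionLabel":
        return cls(interpretable=True, status=Status.ABNORMAL, subtype=subtype)

    # -- comparison keys ----------------------------------------------
    def key(self, granularity: str = "trilevel") -> tuple:
        """Hashable identity of the label at a given comparison granularity.

        ``trilevel`` distinguishes uninterpretable / normal / abnormal;
        ``full`` additionally distinguishes the abnormal subtype.
        """
        if granularity == "trilevel":
            return (self.interpretable, self.status)
        if granularity == "full":
            return (self.interpretable, self.status, self.subtype)
        raise ValueError(f"unknown granularity {granularity!r}")


@dataclass(frozen=True)
class Rating:
    """One rater's label for one chest-position recording."""

    patient_id: str
    position: int
    rater_id: str
    role: Role
    label: PositionLabel

    def __post_init__(self) -> None:
        if self.position not in range(1, 7):
            raise ValidationError(
                f"position must be 1-6, got {self.position!r} "
                f"(patient {self.patient_id})"
            )


@dataclass(frozen=True)
class FinalLabel:
    """Adjudicated (or single-source) label for one recording."""

    patient_id: str
    position: int
    label: PositionLabel
    provenance: Provenance


@dataclass
class StudyDataset:
    """A validated collection of ratings for one study."""

    ratings: list[Rating] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        positions: dict[str, set[int]] = {}
        for r in self.ratings:
            k = (r.patient_id, r.position, r.rater_id)
            if k in seen:
                raise IntegrityError(
                    f"duplicate rating for patient {r.patient_id}, "
                    f"position {r.position}, rater {r.rater_id}"
                )
            seen.add(k)
            positions.setdefault(r.patient_id, set()).add(r.position)
        for pid, pos in positions.items():
            if not 1 <= len(pos) <= 6:
                raise IntegrityError(f"patient {pid} has {len(pos)} positions")

    @property
    def patients(self) -> list[str]:
        return sorted({r.patient_id for r in self.ratings})

    def __len__(self) -> int:
        return len(self.ratings)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return sorted(self.ratings, key=_rating_sort_key) == sorted(
            other.ratings, key=_rating_sort_key
        )

    def by_recording(
        self, roles: Optional[Iterable[Role]] = None
    ) -> dict[tuple[str, int], list[Rating]]:
        """Group ratings by (patient_id, position), optionally by role."""
        wanted = set(roles) if roles is not None else None
        out: dict[tuple[str, int], list[Rating]] = {}
        for r in self.ratings:
            if wanted is not None and r.role not in wanted:
                continue
            out.setdefault((r.patient_id, r.position), []).append(r)
        return out


def _rating_sort_key(r: Rating):
    return (r.patient_id, r.position, r.role.value, r.rater_id)


RATINGS_COLUMNS = [
    "patient_id",
    "position",
    "rater_id",
    "role",
    "interpretable",
    "status",
    "subtype",
]

FINAL_LABEL_COLUMNS = [
    "patient_id",
    "position",
    "interpretable",
    "status",
    "subtype",
    "provenance",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}
_NA = {"", "na", "nan", "none", "null"}


def _norm(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip().lower()


def _parse_label(interpretable_raw, status_raw, subtype_raw) -> PositionLabel:
    iv = _norm(interpretable_raw)
    if iv in _TRUE:
        interpretable = True
    elif iv in _FALSE:
        interpretable = False
    else:
        raise ValidationError(f"cannot parse interpretable value {interpretable_raw!r}")
    sv = _norm(status_raw)
    status = None if sv in _NA else Status(sv)
    tv = _norm(subtype_raw)
    subtype = None if tv in _NA else Subtype(tv)
    return PositionLabel(interpretable=interpretable, status=status, subtype=subtype)


def read_ratings(
    path: Union[str, Path],
    schema: Optional[Mapping[str, str]] = None,
) -> StudyDataset:
    """Read a long-format ratings CSV into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical column names (``patient_id``,
        ``position``, ``rater_id``, ``role``, ``interpretable``,
        ``status``, ``subtype``) to the names used in the file.

    Raises
    ------
    SchemaError
        A canonical column cannot be resolved.
    ValidationError
        A row violates a label invariant; the message lists the offending
        row numbers (1-based, counting the header as line 1).
    IntegrityError
        Duplicate (patient, position, rater) rows.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c.lower(): c for c in df.columns}
    resolved = {}
    for canon in RATINGS_COLUMNS:
        name = schema.get(canon, canon).lower()
        if name not in colmap:
            raise SchemaError(f"column {canon!r} (looked for {name!r}) not in {path}")
        resolved[canon] = colmap[name]

    ratings: list[Rating] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            pos_raw = _norm(rec[resolved["position"]])
            try:
                position = int(pos_raw)
            except ValueError:
                raise ValidationError(f"position {pos_raw!r} is not an integer")
            label = _parse_label(
                rec[resolved["interpretable"]],
                rec[resolved["status"]],
                rec[resolved["subtype"]],
            )
            ratings.append(
                Rating(
                    patient_id=str(rec[resolved["patient_id"]]).strip(),
                    position=position,
                    rater_id=str(rec[resolved["rater_id"]]).strip(),
                    role=Role(_norm(rec[resolved["role"]])),
                    label=label,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s) in {path}: " + "; ".join(problems)
        )
    return StudyDataset(ratings=ratings)


def _label_fields(label: PositionLabel) -> dict:
    return {
        "interpretable": "true" if label.interpretable else "false",
        "status": label.status.value if label.status else "NA",
        "subtype": label.subtype.value if label.subtype else "NA",
    }


def write_ratings(dataset: StudyDataset, path: Union[str, Path]) -> Path:
    """Write a :class:`StudyDataset` to long-format CSV (canonical columns)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "position": r.position,
            "rater_id": r.rater_id,
            "role": r.role.value,
            **_label_fields(r.label),
        }
        for r in dataset.ratings
    ]
    df = pd.DataFrame(rows, columns=RATINGS_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_final_labels(labels: Iterable[FinalLabel], path: Union[str, Path]) -> Path:
    rows = [
        {
            "patient_id": fl.patient_id,
            "position": fl.position,
            **_label_fields(fl.label),
            "provenance": fl.provenance.value,
        }
        for fl in labels
    ]
    df = pd.DataFrame(rows, columns=FINAL_LABEL_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_final_labels(path: Union[str, Path]) -> list[FinalLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FINAL_LABEL_COLUMNS if c.lower() not in {x.lower() for x in df.columns}]
    if missing:
        raise SchemaError(f"columns {missing} not in {path}")
    colmap = {c.lower(): c for c in df.columns}
    out = []
    for _, rec in df.iterrows():
        label = _parse_label(
            rec[colmap["interpretable"]],
            rec[colmap["status"]],
            rec[colmap["subtype"]],
        )
        out.append(
            FinalLabel(
                patient_id=str(rec[colmap["patient_id"]]).strip(),
                position=int(_norm(rec[colmap["position"]])),
                label=label,
                provenance=Provenance(_norm(rec[colmap["provenance"]])),
            )
        )
    return out
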