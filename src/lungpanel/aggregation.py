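"""Patient-level roll-up, AI majority-vote ensembling, and pairing.

Patient rule: a patient whose positions are all uninterpretable is
uninterpretable; a patient with at least one interpretable abnormal
position is abnormal; otherwise (at least one interpretable position,
none abnormal) the patient is normal. A mixed uninterpretable +
interpretable-normal patient is therefore classified normal.

Interpretability gating for paired comparisons uses the reference (panel)
stream's interpretability only; the index stream (AI ensemble or
clinician) contributes status alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .annotations import (
    FinalLabel,
    PositionLabel,
    Provenance,
    Role,
    Status,
    StudyDataset,
)
from .errors import IntegrityError, TieError, ValidationError

__all__ = [
    "PatientLabel",
    "aggregate_patient",
    "aggregate_study",
    "majority_vote",
    "ensemble_ai",
    "clinician_stream",
    "build_comparison",
    "write_patient_labels",
]


@dataclass(frozen=True)
class PatientLabel:
    """Patient-level classification with supporting position counts."""

    patient_id: str
    status: str  # "uninterpretable" | "normal" | "abnormal"
    n_positions_total: int
    n_interpretable: int
    n_abnormal: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_abnormal <= self.n_interpretable <= self.n_positions_total <= 6:
            raise ValidationError(
                f"inconsistent counts for patient {self.patient_id}: "
                f"{self.n_abnormal}/{self.n_interpretable}/{self.n_positions_total}"
            )
        if (self.status == "uninterpretable") != (self.n_interpretable == 0):
            raise ValidationError("status uninterpretable iff no interpretable positions")
        if self.status != "uninterpretable" and (
            (self.status == "abnormal") != (self.n_abnormal >= 1)
        ):
            raise ValidationError("status abnormal iff >=1 abnormal position")


def aggregate_patient(
    patient_id: str, labels: Sequence[PositionLabel]
) -> PatientLabel:
    """Roll one patient's position labels up to a patient label."""
    if not labels:
        raise ValidationError(f"patient {patient_id}: no position labels")
    if len(labels) > 6:
        raise ValidationError(f"patient {patient_id}: more than 6 positions")
    n_total = len(labels)
    n_interp = sum(1 for l in labels if l.interpretable)
    n_abn = sum(1 for l in labels if l.status is Status.ABNORMAL)
    if n_interp == 0:
        status = "uninterpretable"
    elif n_abn >= 1:
        status = "abnormal"
    else:
        status = "normal"
    return PatientLabel(
        patient_id=patient_id,
        status=status,
        n_positions_total=n_total,
        n_interpretable=n_interp,
        n_abnormal=n_abn,
    )


def aggregate_study(finals: Iterable[FinalLabel]) -> list[PatientLabel]:
    """Aggregate a stream of per-position final labels by patient."""
    by_patient: dict[str, list[PositionLabel]] = {}
    for fl in finals:
        by_patient.setdefault(fl.patient_id, []).append(fl.label)
    return [aggregate_patient(pid, labs) for pid, labs in sorted(by_patient.items())]


def majority_vote(labels: Sequence[Status], tie: str = "error") -> Status:
    """Majority of k binary classifications from k algorithm iterations.

    An exact tie (possible only for even k) raises :class:`TieError`
    unless ``tie`` names a fallback status (``"abnormal"`` or
    ``"normal"``).
    """
    if not labels:
        raise ValidationError("majority_vote needs at least one label")
    n_abn = sum(1 for s in labels if s is Status.ABNORMAL)
    n_norm = len(labels) - n_abn
    if n_abn > n_norm:
        return Status.ABNORMAL
    if n_norm > n_abn:
        return Status.NORMAL
    if tie == "error":
        raise TieError(f"exact {n_abn}-{n_norm} tie among {len(labels)} iterations")
    if tie in ("abnormal", "normal"):
        return Status(tie)
    raise ValueError(f"unknown tie policy {tie!r}")


def ensemble_ai(
    dataset: StudyDataset, k: Optional[int] = None, tie: str = "error"
) -> list[FinalLabel]:
    """Combine AI iterations per recording by majority vote.

    ``k``, when given, asserts the expected number of iterations per
    recording. The ensemble output is a single-source final-label stream.
    """
    groups = dataset.by_recording(roles={Role.AI_ITERATION})
    finals: list[FinalLabel] = []
    for (pid, pos), ratings in sorted(groups.items()):
        if k is not None and len(ratings) != k:
            raise IntegrityError(
                f"patient {pid} position {pos}: expected {k} AI iterations, "
                f"found {len(ratings)}"
            )
        statuses = [r.label.status for r in ratings]
        if any(s is None for s in statuses):
            raise ValidationError(
                f"patient {pid} position {pos}: AI iteration with no status"
            )
        status = majority_vote(statuses, tie=tie)
        finals.append(
            FinalLabel(
                patient_id=pid,
                position=pos,
                label=PositionLabel(interpretable=True, status=status),
                provenance=Provenance.SINGLE_SOURCE,
            )
        )
    return finals


def clinician_stream(dataset: StudyDataset) -> list[FinalLabel]:
    """Extract the bedside clinician's labels as a single-source stream."""
    groups = dataset.by_recording(roles={Role.CLINICIAN})
    finals = []
    for (pid, pos), ratings in sorted(groups.items()):
        if len(ratings) != 1:
            raise IntegrityError(
                f"patient {pid} position {pos}: multiple clinician ratings"
            )
        finals.append(
            FinalLabel(
                patient_id=pid,
                position=pos,
                label=ratings[0].label,
                provenance=Provenance.SINGLE_SOURCE,
            )
        )
    return finals


def build_comparison(
    final_panel: Iterable[FinalLabel],
    other_stream: Iterable[FinalLabel],
    level: str = "position",
) -> list[tuple[Status, Status]]:
    """Pair the reference (panel) stream with an index stream.

    At ``position`` level, pairs are restricted to recordings the panel
    deemed interpretable; at ``patient`` level, to patients whose panel
    classification is not uninterpretable. A pair where the index stream
    has no defined binary status (absent or uninterpretable) is dropped.

    Returns a list of ``(reference_status, index_status)`` pairs.
    """
    panel = list(final_panel)
    other = list(other_stream)
    if level == "position":
        idx = {(fl.patient_id, fl.position): fl.label for fl in other}
        pairs = []
        for fl in panel:
            if not fl.label.interpretable:
                continue
            olabel = idx.get((fl.patient_id, fl.position))
            if olabel is None or olabel.status is None:
                continue
            pairs.append((fl.label.status, olabel.status))
    elif level == "patient":
        ref_patients = {p.patient_id: p for p in aggregate_study(panel)}
        idx_patients = {p.patient_id: p for p in aggregate_study(other)}
        pairs = []
        for pid, ref in sorted(ref_patients.items()):
            if ref.status == "uninterpretable":
                continue
            idxp = idx_patients.get(pid)
            if idxp is None or idxp.status == "uninterpretable":
                continue
            pairs.append((Status(ref.status), Status(idxp.status)))
    else:
        raise ValueError(f"unknown level {level!r}")
    if not pairs:
        raise ValidationError("streams share no comparable recordings")
    return pairs


def write_patient_labels(
    labels: Iterable[PatientLabel], path: Union[str, Path]
) -> Path:
    df = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "status": p.status,
                "n_positions_total": p.n_positions_total,
                "n_interpretable": p.n_interpretable,
                "n_abnormal": p.n_abnormal,
            }
            for p in labels
        ],
        columns=[
            "patient_id",
            "status",
            "n_positions_total",
            "n_interpretable",
            "n_abnormal",
        ],
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path
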