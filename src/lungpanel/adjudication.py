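"""Listening-panel adjudication of chest-position recordings.

Each recording is rated by two primary panelists. Agreement between the
primaries finalises the label. On disagreement a first arbitrator reviews
the recording: if the arbitrator matches either primary, that label is
final. If the arbitrator matches neither, a second arbitrator's label is
final unconditionally, even when it disagrees with all three earlier
raters.

Agreement is judged at a configurable granularity. The default,
``trilevel``, compares uninterpretable / normal / abnormal only, so a
wheeze-vs-crackle split between two abnormal calls does not trigger
arbitration; ``full`` granularity also compares the subtype. All the
downstream agreement statistics are binary normal-vs-abnormal, which is
why trilevel is the default; full mode exists for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .annotations import (
    FinalLabel,
    PositionLabel,
    Provenance,
    Role,
    Status,
    StudyDataset,
    Subtype,
)
from .errors import AdjudicationIncompleteError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = ["AdjudicationConfig", "adjudicate_position", "adjudicate_study"]


@dataclass(frozen=True)
class AdjudicationConfig:
    granularity: str = "trilevel"

    def __post_init__(self) -> None:
        if self.granularity not in ("trilevel", "full"):
            raise ValueError(f"unknown granularity {self.granularity!r}")


def _merge(x: PositionLabel, y: PositionLabel) -> PositionLabel:
    """Consensus of two labels that agree at trilevel granularity.

    If the status is abnormal and the two raters gave different subtypes,
    the consensus subtype is the conservative union ``both``; if only one
    gave a subtype it is kept.
    """
    if x.status is not Status.ABNORMAL:
        return x
    if x.subtype is None:
        subtype = y.subtype
    elif y.subtype is None or x.subtype == y.subtype:
        subtype = x.subtype
    else:
        subtype = Subtype.BOTH
    return PositionLabel.abnormal(subtype)


def adjudicate_position(
    primary_a: PositionLabel,
    primary_b: PositionLabel,
    arbitrator1: Optional[PositionLabel] = None,
    arbitrator2: Optional[PositionLabel] = None,
    config: AdjudicationConfig = AdjudicationConfig(),
    recording: str = "<recording>",
) -> tuple[PositionLabel, Provenance]:
    """Resolve one recording to its consensus label and provenance.

    Returns the final :class:`PositionLabel` and the stage that resolved
    it. Raises :class:`AdjudicationIncompleteError` when a required
    arbitrator rating is absent; superfluous arbitrator ratings are
    ignored with a logged notice.
    """
    g = config.granularity
    ka, kb = primary_a.key(g), primary_b.key(g)
    if ka == kb:
        if arbitrator1 is not None or arbitrator2 is not None:
            logger.info(
                "superfluous arbitrator rating(s) ignored for %s "
                "(primaries agree)", recording,
            )
        return _merge(primary_a, primary_b), Provenance.PRIMARY_CONSENSUS
    if arbitrator1 is None:
        raise AdjudicationIncompleteError(
            f"primaries disagree on {recording} but no arbitrator rating present"
        )
    k1 = arbitrator1.key(g)
    if k1 == ka:
        if arbitrator2 is not None:
            logger.info(
                "superfluous second-arbitrator rating ignored for %s", recording
            )
        return _merge(arbitrator1, primary_a), Provenance.ARBITRATOR1
    if k1 == kb:
        if arbitrator2 is not None:
            logger.info(
                "superfluous second-arbitrator rating ignored for %s", recording
            )
        return _merge(arbitrator1, primary_b), Provenance.ARBITRATOR1
    if arbitrator2 is None:
        raise AdjudicationIncompleteError(
            f"all three raters disagree on {recording} and no second "
            "arbitrator rating present"
        )
    return arbitrator2, Provenance.ARBITRATOR2


def adjudicate_study(
    dataset: StudyDataset,
    config: AdjudicationConfig = AdjudicationConfig(),
) -> list[FinalLabel]:
    """Adjudicate every panel-rated recording in a study.

    Produces one :class:`FinalLabel` per (patient, position) that has
    primary ratings. Recordings without any panel ratings are skipped and
    reported via the module logger. A recording with a number of primary
    ratings other than two is an integrity error.
    """
    panel_roles = {Role.PRIMARY, Role.ARBITRATOR1, Role.ARBITRATOR2}
    groups = dataset.by_recording(roles=panel_roles)
    all_recordings = dataset.by_recording()
    skipped = [k for k in all_recordings if k not in groups]
    if skipped:
        logger.info("%d recording(s) without panel ratings skipped", len(skipped))

    finals: list[FinalLabel] = []
    for (pid, pos), ratings in sorted(groups.items()):
        primaries = [r for r in ratings if r.role is Role.PRIMARY]
        if len(primaries) != 2:
            raise IntegrityError(
                f"patient {pid} position {pos}: expected exactly 2 primary "
                f"ratings, found {len(primaries)}"
            )
        arb1 = _at_most_one(ratings, Role.ARBITRATOR1, pid, pos)
        arb2 = _at_most_one(ratings, Role.ARBITRATOR2, pid, pos)
        label, provenance = adjudicate_position(
            primaries[0].label,
            primaries[1].label,
            arb1.label if arb1 else None,
            arb2.label if arb2 else None,
            config=config,
            recording=f"patient {pid} position {pos}",
        )
        finals.append(
            FinalLabel(patient_id=pid, position=pos, label=label, provenance=provenance)
        )
    return finals


def _at_most_one(ratings, role: Role, pid, pos):
    found = [r for r in ratings if r.role is role]
    if len(found) > 1:
        raise IntegrityError(
            f"patient {pid} position {pos}: multiple {role.value} ratings"
        )
    return found[0] if found else None
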