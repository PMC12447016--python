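"""Shared fixtures: programmatically built annotation studies.

``study_like_published`` builds a deterministic 95-patient study whose
panel-vs-AI pairs tabulate exactly to the published cell counts at both
comparison levels: position table (a,b,c,d) = (236, 26, 58, 177) over
497 interpretable positions (566 recorded, 69 uninterpretable, 4
missing), and patient table (77, 5, 3, 10) over 95 patients.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lungpanel.annotations import (
    PositionLabel,
    Rating,
    Role,
    Status,
    StudyDataset,
    Subtype,
)

# cell codes: 'a' ref abnormal/idx abnormal, 'b' ref normal/idx abnormal,
# 'c' ref abnormal/idx normal, 'd' ref normal/idx normal
_REF_ABNORMAL = {"a": True, "b": False, "c": True, "d": False}
_IDX_ABNORMAL = {"a": True, "b": True, "c": False, "d": False}


def _patient_plan() -> list[tuple[str, list[str], bool, bool]]:
    """Per patient: (patient_id, interpretable-cell list, has_missing,
    has_uninterpretable).

    Patients 1-4 miss position 6; patients 5-73 have position 6
    uninterpretable; patients 74-95 have six interpretable positions.
    Group sizes: 10 both-normal, 3 panel-abnormal/AI-normal, 5
    panel-normal/AI-abnormal, 77 both-abnormal.
    """
    plan = []
    # both-normal patients: all-d
    for i in range(1, 11):
        plan.append((f"p{i:03d}", ["d"] * 5, i <= 4, i > 4))
    # panel abnormal, AI normal: all-c
    for i in range(11, 14):
        plan.append((f"p{i:03d}", ["c"] * 5, False, True))
    # panel normal, AI abnormal: 2 b + 3 d
    for i in range(14, 19):
        plan.append((f"p{i:03d}", ["b", "b", "d", "d", "d"], False, True))
    # both-abnormal: one guaranteed 'a', remainder from the global pool
    pool = ["a"] * 159 + ["b"] * 16 + ["c"] * 43 + ["d"] * 112
    cursor = 0
    for i in range(19, 96):
        n_interp = 6 if i >= 74 else 5
        take = n_interp - 1
        cells = ["a"] + pool[cursor : cursor + take]
        cursor += take
        plan.append((f"p{i:03d}", cells, False, 19 <= i <= 73))
    assert cursor == len(pool)
    return plan


def build_study_like_published(include_arbitrators: bool = False) -> StudyDataset:
    """Deterministic study reproducing the published tables exactly.

    Both primaries agree everywhere (abnormal calls subtyped crackle),
    so adjudication is pure consensus; the five AI iterations are
    unanimous per recording.
    """
    abnormal = PositionLabel.abnormal(Subtype.CRACKLE)
    normal = PositionLabel.normal()
    uninterp = PositionLabel.uninterpretable()
    ratings: list[Rating] = []
    for pid, cells, has_missing, has_uninterp in _patient_plan():
        positions = list(range(1, 7))
        if has_missing:
            positions.remove(6)
        for pos in positions:
            if pos == 6 and has_uninterp:
                for rater in ("panelist1", "panelist2"):
                    ratings.append(Rating(pid, pos, rater, Role.PRIMARY, uninterp))
                continue
            cell = cells[pos - 1]
            ref = abnormal if _REF_ABNORMAL[cell] else normal
            idx_status = Status.ABNORMAL if _IDX_ABNORMAL[cell] else Status.NORMAL
            for rater in ("panelist1", "panelist2"):
                ratings.append(Rating(pid, pos, rater, Role.PRIMARY, ref))
            for j in range(1, 6):
                ratings.append(
                    Rating(pid, pos, f"ai_iter{j}", Role.AI_ITERATION,
                           PositionLabel(interpretable=True, status=idx_status))
                )
    return StudyDataset(ratings=ratings)


@pytest.fixture(scope="session")
def study_like_published() -> StudyDataset:
    return build_study_like_published()
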