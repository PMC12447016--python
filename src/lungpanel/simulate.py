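"""Synthetic annotation studies with latent true lung-sound status.

Generative model
----------------
Each patient i receives a random effect u_i ~ Normal(0, patient_sd); each
of their chest positions is truly abnormal with probability
logistic(base_abnormal_logit + u_i), which induces within-patient
correlation of abnormality. Uninterpretability and missingness are drawn
independently of true status. Every human rater and every AI iteration
emits the true status with its sensitivity (truly abnormal recordings)
or specificity (truly normal), conditionally independently given the
truth. Uninterpretable recordings are labelled uninterpretable by all
human raters and are not rated by the AI, which is trained on
interpretable sounds only. A fraction of patients is uncooperative
during auscultation; for them the AI's per-iteration error odds are
divided by ``uncooperative_agreement_or`` (an odds ratio < 1 raises the
error rate).

Two primary panelists are chosen per recording from the pool of three by
a seeded draw; both arbitrators rate every recording (superfluous
arbitrator ratings are ignored downstream). Truly abnormal positions
carry a latent subtype (wheeze / crackle / both); a rater that calls a
truly abnormal recording abnormal reports the true subtype, while a
false-positive abnormal call gets a random subtype.

The default configuration reproduces the magnitudes of a 95-patient
severe-pneumonia auscultation study: six positions per patient, ~0.7%
missing recordings, ~12% uninterpretable positions, and ~59.2% abnormal
prevalence among interpretable positions (base_abnormal_logit = 0.5256
with patient_sd = 1.5 is calibrated by quadrature to that marginal).

A single global seed expands into per-stream substreams (truth,
assignment, panel, AI, clinician) so adding a stream never perturbs
earlier draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .annotations import (
    PositionLabel,
    Rating,
    Role,
    Status,
    StudyDataset,
    Subtype,
)
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_study",
    "expected_table",
    "implied_kappa",
    "write_truth",
]

_SUBTYPES = np.array(["wheeze", "crackle", "both"])
# wheeze / crackle / both mix among truly abnormal positions; crackles
# predominate in pneumonia cohorts
_SUBTYPE_P = np.array([0.35, 0.45, 0.20])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study generator (see module docstring)."""

    n_patients: int = 95
    positions_per_patient: int = 6
    base_abnormal_logit: float = 0.5256
    patient_sd: float = 1.5
    p_uninterpretable: float = 0.12
    p_missing: float = 4 / 570
    panelist_sens: Tuple[float, ...] = (0.90, 0.90, 0.90, 0.93, 0.97)
    panelist_spec: Tuple[float, ...] = (0.90, 0.90, 0.90, 0.93, 0.97)
    ai_sens: float = 0.80
    ai_spec: float = 0.87
    ai_iterations: int = 5
    clinician_sens: float = 0.85
    clinician_spec: float = 0.85
    uncooperative_fraction: float = 0.20
    uncooperative_agreement_or: float = 0.51
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not 1 <= self.positions_per_patient <= 6:
            raise ValidationError("positions_per_patient must be 1-6")
        if self.patient_sd < 0:
            raise ValidationError("patient_sd must be >= 0")
        if self.ai_iterations < 1:
            raise ValidationError("ai_iterations must be >= 1")
        if len(self.panelist_sens) != 5 or len(self.panelist_spec) != 5:
            raise ValidationError(
                "panelist_sens/spec need 5 entries (3 primaries + 2 arbitrators)"
            )
        props = (
            self.p_uninterpretable,
            self.p_missing,
            *self.panelist_sens,
            *self.panelist_spec,
            self.ai_sens,
            self.ai_spec,
            self.clinician_sens,
            self.clinician_spec,
            self.uncooperative_fraction,
        )
        if any(not 0 <= p <= 1 for p in props):
            raise ValidationError("all proportions must lie in [0, 1]")
        if self.uncooperative_agreement_or <= 0:
            raise ValidationError("uncooperative_agreement_or must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panelist_sens"] = list(self.panelist_sens)
        d["panelist_spec"] = list(self.panelist_spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("panelist_sens", "panelist_spec"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Latent truth emitted alongside (never mingled with) the ratings."""

    positions: pd.DataFrame = field(repr=False)
    patients: pd.DataFrame = field(repr=False)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _emit(rng: np.random.Generator, truly_abnormal: np.ndarray,
          sens, spec) -> np.ndarray:
    """Emit an 'abnormal' call per recording given truth and error rates."""
    rolls = rng.random(truly_abnormal.shape)
    return np.where(truly_abnormal, rolls < sens, rolls < (1.0 - np.asarray(spec)))


def _adjusted_error(err: np.ndarray, odds_ratio: float) -> np.ndarray:
    """Divide error odds by ``odds_ratio`` (OR < 1 inflates the error)."""
    err = np.clip(err, 1e-12, 1 - 1e-12)
    odds = err / (1 - err) / odds_ratio
    return odds / (1 + odds)


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, SyntheticTruth]:
    """Draw one synthetic study: a ratings dataset plus its latent truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_assign, rng_panel, rng_ai, rng_clin = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    n, m = config.n_patients, config.positions_per_patient
    patient_ids = np.array([f"p{i + 1:05d}" for i in range(n)])

    # latent truth -----------------------------------------------------
    u = rng_truth.normal(0.0, config.patient_sd, n)
    cooperative = rng_truth.random(n) >= config.uncooperative_fraction
    p_abn = _expit(config.base_abnormal_logit + u)
    abnormal = rng_truth.random((n, m)) < p_abn[:, None]
    uninterpretable = rng_truth.random((n, m)) < config.p_uninterpretable
    missing = rng_truth.random((n, m)) < config.p_missing
    true_subtype = _SUBTYPES[rng_truth.choice(3, size=(n, m), p=_SUBTYPE_P)]

    # primary-panelist assignment: 2 of 3, per recording ---------------
    order = np.argsort(rng_assign.random((n, m, 3)), axis=-1)
    primary_idx = order[:, :, :2]  # rater indices 0..2

    sens_arr = np.asarray(config.panelist_sens)
    spec_arr = np.asarray(config.panelist_spec)
    primary_calls = np.empty((n, m, 2), dtype=bool)
    primary_fp_subtype = _SUBTYPES[rng_panel.choice(3, size=(n, m, 2))]
    for slot in range(2):
        ridx = primary_idx[:, :, slot]
        primary_calls[:, :, slot] = _emit(
            rng_panel, abnormal, sens_arr[ridx], spec_arr[ridx]
        )
    arb_calls = np.empty((n, m, 2), dtype=bool)
    arb_fp_subtype = _SUBTYPES[rng_panel.choice(3, size=(n, m, 2))]
    for j in range(2):
        arb_calls[:, :, j] = _emit(rng_panel, abnormal, sens_arr[3 + j], spec_arr[3 + j])

    # AI iterations, with uncooperative error inflation ----------------
    miss_rate = np.full(n, 1 - config.ai_sens)
    fp_rate = np.full(n, 1 - config.ai_spec)
    if config.uncooperative_agreement_or != 1.0:
        uncoop = ~cooperative
        miss_rate[uncoop] = _adjusted_error(
            miss_rate[uncoop], config.uncooperative_agreement_or
        )
        fp_rate[uncoop] = _adjusted_error(
            fp_rate[uncoop], config.uncooperative_agreement_or
        )
    ai_calls = np.empty((n, m, config.ai_iterations), dtype=bool)
    for j in range(config.ai_iterations):
        ai_calls[:, :, j] = _emit(
            rng_ai, abnormal, 1 - miss_rate[:, None], 1 - fp_rate[:, None]
        )

    clin_calls = _emit(rng_clin, abnormal, config.clinician_sens, config.clinician_spec)
    clin_fp_subtype = _SUBTYPES[rng_clin.choice(3, size=(n, m))]

    # assemble ratings -------------------------------------------------
    def label(call_abnormal: bool, truly_abn: bool, true_sub: str, fp_sub: str) -> PositionLabel:
        if not call_abnormal:
            return PositionLabel.normal()
        return PositionLabel.abnormal(Subtype(true_sub if truly_abn else fp_sub))

    uninterp_label = PositionLabel.uninterpretable()
    ratings: list[Rating] = []
    for i in range(n):
        pid = patient_ids[i]
        for p in range(m):
            if missing[i, p]:
                continue
            pos = p + 1
            truly_abn = bool(abnormal[i, p])
            true_sub = true_subtype[i, p]
            if uninterpretable[i, p]:
                for slot in range(2):
                    ratings.append(Rating(pid, pos, f"panelist{primary_idx[i, p, slot] + 1}",
                                          Role.PRIMARY, uninterp_label))
                ratings.append(Rating(pid, pos, "arbitrator1", Role.ARBITRATOR1, uninterp_label))
                ratings.append(Rating(pid, pos, "arbitrator2", Role.ARBITRATOR2, uninterp_label))
                ratings.append(Rating(pid, pos, "clinician", Role.CLINICIAN, uninterp_label))
                continue
            for slot in range(2):
                ratings.append(Rating(
                    pid, pos, f"panelist{primary_idx[i, p, slot] + 1}", Role.PRIMARY,
                    label(primary_calls[i, p, slot], truly_abn, true_sub, primary_fp_subtype[i, p, slot]),
                ))
            ratings.append(Rating(pid, pos, "arbitrator1", Role.ARBITRATOR1,
                                  label(arb_calls[i, p, 0], truly_abn, true_sub, arb_fp_subtype[i, p, 0])))
            ratings.append(Rating(pid, pos, "arbitrator2", Role.ARBITRATOR2,
                                  label(arb_calls[i, p, 1], truly_abn, true_sub, arb_fp_subtype[i, p, 1])))
            for j in range(config.ai_iterations):
                # AI emits status only; it does not subtype
                st = Status.ABNORMAL if ai_calls[i, p, j] else Status.NORMAL
                ratings.append(Rating(pid, pos, f"ai_iter{j + 1}", Role.AI_ITERATION,
                                      PositionLabel(interpretable=True, status=st)))
            ratings.append(Rating(pid, pos, "clinician", Role.CLINICIAN,
                                  label(clin_calls[i, p], truly_abn, true_sub, clin_fp_subtype[i, p])))

    positions_df = pd.DataFrame({
        "patient_id": np.repeat(patient_ids, m),
        "position": np.tile(np.arange(1, m + 1), n),
        "true_status": np.where(abnormal.ravel(), "abnormal", "normal"),
        "true_subtype": np.where(abnormal.ravel(), true_subtype.ravel(), "NA"),
        "interpretable": ~uninterpretable.ravel(),
        "missing": missing.ravel(),
    })
    patients_df = pd.DataFrame({
        "patient_id": patient_ids,
        "cooperative": cooperative,
        "random_effect": u,
    })
    truth = SyntheticTruth(positions=positions_df, patients=patients_df)
    return StudyDataset(ratings=ratings), truth


def write_truth(truth: SyntheticTruth, path: Union[str, Path]) -> Path:
    """Write the latent truth to one CSV (patient columns repeated)."""
    merged = truth.positions.merge(truth.patients, on="patient_id")
    path = Path(path)
    merged.to_csv(path, index=False)
    return path


def expected_table(
    prevalence: float,
    sens_ref: float,
    spec_ref: float,
    sens_idx: float,
    spec_idx: float,
) -> tuple[float, float, float, float]:
    """Closed-form cell probabilities (a, b, c, d) for two raters that
    err conditionally independently given a latent truth with the given
    prevalence. Serves as the analytic oracle for simulated agreement."""
    th = prevalence
    if not 0 <= th <= 1:
        raise ValidationError("prevalence must be in [0, 1]")
    a = th * sens_ref * sens_idx + (1 - th) * (1 - spec_ref) * (1 - spec_idx)
    b = th * (1 - sens_ref) * sens_idx + (1 - th) * spec_ref * (1 - spec_idx)
    c = th * sens_ref * (1 - sens_idx) + (1 - th) * (1 - spec_ref) * spec_idx
    d = th * (1 - sens_ref) * (1 - sens_idx) + (1 - th) * spec_ref * spec_idx
    return a, b, c, d


def implied_kappa(cells: tuple[float, float, float, float]) -> float:
    """Cohen's kappa implied by cell probabilities (a, b, c, d)."""
    a, b, c, d = cells
    po = a + d
    pe = (a + b) * (a + c) + (c + d) * (b + d)
    return (po - pe) / (1 - pe)
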