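"""Synthetic study generator: determinism, calibration, analytic oracle."""

from __future__ import annotations

import numpy as np
import pytest

from lungpanel.adjudication import adjudicate_study
from lungpanel.aggregation import build_comparison, ensemble_ai
from lungpanel.annotations import Role, Status
from lungpanel.concordance import ContingencyTable, agreement_statistics
from lungpanel.diagnostics import metrics_from_pairs
from lungpanel.errors import ValidationError
from lungpanel.simulate import (
    SimulationConfig,
    expected_table,
    implied_kappa,
    simulate_study,
    write_truth,
)
from lungpanel.annotations import write_ratings

PERFECT = dict(
    panelist_sens=(1.0,) * 5,
    panelist_spec=(1.0,) * 5,
    ai_sens=1.0,
    ai_spec=1.0,
    clinician_sens=1.0,
    clinician_spec=1.0,
    p_uninterpretable=0.0,
    p_missing=0.0,
)


def test_seed_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(n_patients=20, seed=42)
    ds1, t1 = simulate_study(cfg)
    ds2, t2 = simulate_study(SimulationConfig(n_patients=20, seed=42))
    p1 = write_ratings(ds1, tmp_path / "a.csv")
    p2 = write_ratings(ds2, tmp_path / "b.csv")
    assert p1.read_bytes() == p2.read_bytes()
    q1 = write_truth(t1, tmp_path / "ta.csv")
    q2 = write_truth(t2, tmp_path / "tb.csv")
    assert q1.read_bytes() == q2.read_bytes()
    ds3, _ = simulate_study(SimulationConfig(n_patients=20, seed=43))
    assert ds1 != ds3


def test_perfect_raters_give_perfect_statistics():
    """In the noise-free limit every downstream statistic is exactly 1."""
    cfg = SimulationConfig(n_patients=30, seed=5, **PERFECT)
    ds, truth = simulate_study(cfg)
    panel = adjudicate_study(ds)
    ai = ensemble_ai(ds, k=5)
    for level in ("position", "patient"):
        pairs = build_comparison(panel, ai, level=level)
        t = ContingencyTable.from_pairs(pairs)
        agr = agreement_statistics(t)
        assert agr.po == 1.0 and agr.kappa == 1.0 and agr.bp == 1.0
        d = metrics_from_pairs(pairs)
        assert d.sens.value == 1.0 and d.spec.value == 1.0


def test_perfect_panel_matches_truth():
    cfg = SimulationConfig(n_patients=25, seed=9, **PERFECT)
    ds, truth = simulate_study(cfg)
    panel = {(f.patient_id, f.position): f.label.status
             for f in adjudicate_study(ds)}
    for row in truth.positions.itertuples():
        key = (row.patient_id, row.position)
        assert panel[key] is Status(row.true_status)


@pytest.mark.parametrize(
    "args, want_cells, want_kappa",
    [
        ((0.5, 1, 1, 1, 1), (0.5, 0.0, 0.0, 0.5), 1.0),
        ((0.5, 0.8, 0.8, 0.8, 0.8), (0.34, 0.16, 0.16, 0.34), 0.36),
        ((0.5, 0.8, 0.8, 0.5, 0.5), None, 0.0),
    ],
)
def test_expected_table_closed_form(args, want_cells, want_kappa):
    cells = expected_table(*args)
    assert sum(cells) == pytest.approx(1.0)
    if want_cells is not None:
        assert cells == pytest.approx(want_cells)
    assert implied_kappa(cells) == pytest.approx(want_kappa, abs=1e-12)


def test_default_calibration_matches_study_magnitudes():
    """Across 200 seeds the mean interpretable / abnormal position
    counts match the generator's analytic expectation, which in turn
    lies within one study-level binomial SD of the published 497 / 294."""
    n_seeds = 200
    interp_counts = np.empty(n_seeds)
    abn_counts = np.empty(n_seeds)
    cfg0 = SimulationConfig()
    for s in range(n_seeds):
        _, truth = simulate_study(SimulationConfig(seed=s))
        pos = truth.positions
        ok = ~pos.missing & pos.interpretable
        interp_counts[s] = ok.sum()
        abn_counts[s] = (ok & (pos.true_status == "abnormal")).sum()
    n_slots = cfg0.n_patients * cfg0.positions_per_patient
    p_interp = (1 - cfg0.p_missing) * (1 - cfg0.p_uninterpretable)
    e_interp = n_slots * p_interp
    e_abn = e_interp * 0.592  # marginal calibration of the abnormal logit
    sd_interp = np.sqrt(n_slots * p_interp * (1 - p_interp))
    # study-to-study SD of the abnormal count (includes patient clustering)
    sd_abn = abn_counts.std(ddof=1)
    assert abs(interp_counts.mean() - e_interp) < 3 * sd_interp / np.sqrt(n_seeds)
    assert abs(abn_counts.mean() - e_abn) < 3 * sd_abn / np.sqrt(n_seeds)
    # the study conditions themselves: published counts within one
    # single-study binomial SD of the generator's expectation
    assert abs(e_interp - 497) < sd_interp
    assert abs(e_abn - 294) < sd_abn


def test_majority_vote_boosts_sensitivity():
    """With per-iteration sensitivity > 0.5, the 5-iteration majority is
    at least as sensitive against truth as a single iteration."""
    cfg = SimulationConfig(
        n_patients=800, seed=17, p_uninterpretable=0.0, p_missing=0.0,
        uncooperative_fraction=0.0,
    )
    ds, truth = simulate_study(cfg)
    truth_abn = {
        (r.patient_id, r.position)
        for r in truth.positions.itertuples()
        if r.true_status == "abnormal"
    }
    single_hits = total = 0
    for r in ds.ratings:
        if r.role is Role.AI_ITERATION and r.rater_id == "ai_iter1":
            if (r.patient_id, r.position) in truth_abn:
                total += 1
                single_hits += r.label.status is Status.ABNORMAL
    ens = ensemble_ai(ds, k=5)
    ens_hits = sum(
        1 for f in ens
        if (f.patient_id, f.position) in truth_abn
        and f.label.status is Status.ABNORMAL
    )
    assert ens_hits / total >= single_hits / total


def test_uncooperative_patients_raise_ai_error_rate():
    cfg = SimulationConfig(
        n_patients=2000, seed=23, p_uninterpretable=0.0, p_missing=0.0,
        uncooperative_fraction=0.5, uncooperative_agreement_or=0.3,
        ai_iterations=1,
    )
    ds, truth = simulate_study(cfg)
    coop = dict(zip(truth.patients.patient_id, truth.patients.cooperative))
    status = {
        (r.patient_id, r.position): r.true_status
        for r in truth.positions.itertuples()
    }
    err = {True: [0, 0], False: [0, 0]}  # cooperative -> [errors, total]
    for r in ds.ratings:
        if r.role is not Role.AI_ITERATION:
            continue
        truth_status = status[(r.patient_id, r.position)]
        wrong = r.label.status.value != truth_status
        bucket = err[bool(coop[r.patient_id])]
        bucket[0] += wrong
        bucket[1] += 1
    rate_coop = err[True][0] / err[True][1]
    rate_uncoop = err[False][0] / err[False][1]
    assert rate_uncoop > rate_coop


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(ai_sens=1.2)
    with pytest.raises(ValidationError):
        SimulationConfig(panelist_sens=(0.9, 0.9))
    with pytest.raises(ValidationError):
        SimulationConfig(uncooperative_agreement_or=0.0)


def test_config_round_trip_dict():
    cfg = SimulationConfig(n_patients=7, seed=2)
    assert SimulationConfig.from_dict(cfg.to_dict()) == cfg
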