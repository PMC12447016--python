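"""End-to-end evaluation pipeline and headline-result reproduction.

``run_pipeline`` chains every stage: read ratings, adjudicate the panel,
majority-vote the AI iterations, gate on panel interpretability, pair
the streams at position and patient level, and compute agreement and
diagnostic-accuracy statistics for each. ``reproduce_paper`` re-derives
the same statistic set from the published marginal counts alone, which
determine the underlying 2x2 tables uniquely.

Every number in a rendered report equals the corresponding module API
value after display rounding; the renderer never recomputes anything.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .adjudication import AdjudicationConfig, adjudicate_study
from .aggregation import build_comparison, clinician_stream, ensemble_ai
from .annotations import Role, StudyDataset, read_ratings
from .concordance import (
    AgreementResult,
    ContingencyTable,
    agreement_statistics,
    reconstruct_table,
)
from .design import DesignInputs, sample_size
from .diagnostics import DiagnosticResult, diagnostic_metrics
from .display import fmt, round_half_up

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_paper", "render_report"]

# Published marginal counts (N, reference-abnormal, index-abnormal,
# agreements) for the AI-vs-panel comparison, used by reproduce_paper.
POSITION_MARGINALS = (497, 294, 262, 413)
PATIENT_MARGINALS = (95, 80, 82, 87)
DESIGN_FIXTURE = DesignInputs(p=0.70, halfwidth=0.20, m=6, icc=0.70, conf=0.95)


@dataclass(frozen=True)
class PipelineConfig:
    granularity: str = "trilevel"
    tie: str = "error"
    ai_iterations: Optional[int] = None  # assert the per-recording count when set
    conf: float = 0.95


def _table_dict(t: ContingencyTable) -> dict:
    return {
        "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n,
        "reference_abnormal": t.reference_positive,
        "index_abnormal": t.index_positive,
        "agreements": t.agreement,
    }


def _agreement_dict(r: AgreementResult) -> dict:
    return {
        "po": r.po,
        "pe": r.pe,
        "kappa": r.kappa,
        "kappa_se": r.kappa_se,
        "kappa_ci": list(r.kappa_ci),
        "bp": r.bp,
        "bp_se": r.bp_se,
        "bp_ci": list(r.bp_ci),
        "strength_kappa": r.strength_kappa,
        "strength_bp": r.strength_bp,
    }


def _estimate_dict(e) -> dict:
    return {"value": e.value, "ci": list(e.ci) if e.ci else None}


def _diagnostic_dict(r: DiagnosticResult) -> dict:
    return {
        "sens": _estimate_dict(r.sens),
        "spec": _estimate_dict(r.spec),
        "ppv": _estimate_dict(r.ppv),
        "npv": _estimate_dict(r.npv),
        "lr_pos": _estimate_dict(r.lr_pos),
        "lr_neg": _estimate_dict(r.lr_neg),
        "dor": _estimate_dict(r.dor),
        "abnormal_fraction_index": r.abnormal_fraction_index,
        "n": r.n,
    }


def _comparison_block(pairs, conf: float) -> dict:
    t = ContingencyTable.from_pairs(pairs)
    return {
        "table": _table_dict(t),
        "agreement": _agreement_dict(agreement_statistics(t, conf=conf)),
        "diagnostics": _diagnostic_dict(diagnostic_metrics(t, conf=conf)),
    }


def run_pipeline(
    ratings: Union[str, Path, StudyDataset],
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run the full AI-vs-panel evaluation on a ratings table.

    Returns a JSON-serialisable report with, per comparison level
    (position, patient), the 2x2 table, agreement statistics, and
    diagnostic-accuracy metrics, plus patient-level clinician
    sensitivity comparisons when clinician ratings are present, and a
    provenance block sufficient to re-run the computation.
    """
    if isinstance(ratings, (str, Path)):
        source = str(ratings)
        digest = hashlib.sha256(Path(ratings).read_bytes()).hexdigest()
        dataset = read_ratings(ratings)
    else:
        source = "<in-memory dataset>"
        digest = None
        dataset = ratings

    panel = adjudicate_study(dataset, AdjudicationConfig(config.granularity))
    ai = ensemble_ai(dataset, k=config.ai_iterations, tie=config.tie)

    report: dict = {
        "comparisons": {
            level: _comparison_block(
                build_comparison(panel, ai, level=level), config.conf
            )
            for level in ("position", "patient")
        }
    }

    if any(r.role is Role.CLINICIAN for r in dataset.ratings):
        clin = clinician_stream(dataset)
        report["sensitivity_comparisons"] = {
            "clinician_vs_panel_patient": _comparison_block(
                build_comparison(panel, clin, level="patient"), config.conf
            ),
            "ai_vs_clinician_patient": _comparison_block(
                build_comparison(clin, ai, level="patient"), config.conf
            ),
        }

    report["provenance"] = {
        "input": source,
        "input_sha256": digest,
        "config": dataclasses.asdict(config),
        "version": __version__,
    }
    return report


def reproduce_paper(conf: float = 0.95) -> dict:
    """Recompute the headline statistics from the published marginals.

    The four printed counts per level (N, panel-abnormal, AI-abnormal,
    agreements) determine the 2x2 table uniquely; every statistic is then
    computed by the ordinary module APIs. Each displayed value carries a
    pass/fail flag against the published display-rounded figure.
    """
    out: dict = {"comparisons": {}}
    for level, marginals in (
        ("position", POSITION_MARGINALS),
        ("patient", PATIENT_MARGINALS),
    ):
        t = reconstruct_table(*marginals)
        out["comparisons"][level] = {
            "marginals": list(marginals),
            "table": _table_dict(t),
            "agreement": _agreement_dict(agreement_statistics(t, conf=conf)),
            "diagnostics": _diagnostic_dict(diagnostic_metrics(t, conf=conf)),
        }
    out["sample_size"] = {
        "inputs": dataclasses.asdict(DESIGN_FIXTURE),
        "participants": sample_size(DESIGN_FIXTURE),
    }

    published = {
        ("position", "kappa"): 0.659,
        ("position", "bp"): 0.662,
        ("patient", "kappa"): 0.665,
        ("patient", "bp"): 0.832,
    }
    checks = {}
    for (level, stat), expected in published.items():
        got = round_half_up(out["comparisons"][level]["agreement"][stat], 3)
        checks[f"{level}_{stat}"] = {
            "computed": got, "published": expected, "pass": got == expected,
        }
    got_n = out["sample_size"]["participants"]
    checks["sample_size"] = {"computed": got_n, "published": 91, "pass": got_n == 91}
    out["checks"] = checks
    return out


def _fmt_ci(ci, scale=1.0, nd=3):
    if ci is None:
        return "undefined"
    return f"({fmt(ci[0] * scale, nd)}, {fmt(ci[1] * scale, nd)})"


def _fmt_est(e: dict, scale=1.0, nd=1) -> str:
    if e["value"] is None:
        return "undefined"
    return f"{fmt(e['value'] * scale, nd)} {_fmt_ci(e['ci'], scale, nd)}"


def render_report(report: dict) -> str:
    """Render a report dict as human-readable tables (display rounding
    matches the module conventions: agreement to 3 decimals, percentages
    to 1, likelihood ratios to 2, odds ratios to 1)."""
    lines = []
    for level, block in report.get("comparisons", {}).items():
        t, agr, dia = block["table"], block["agreement"], block["diagnostics"]
        lines.append(f"=== {level} level (n = {t['n']}) ===")
        lines.append(
            f"  table a/b/c/d: {t['a']}/{t['b']}/{t['c']}/{t['d']}  "
            f"agreements {t['agreements']} "
            f"({fmt(100 * agr['po'], 1)}%)"
        )
        lines.append(
            f"  Cohen's kappa: {fmt(agr['kappa'], 3)} {_fmt_ci(agr['kappa_ci'])} "
            f"[{agr['strength_kappa']}]"
        )
        lines.append(
            f"  Brennan-Prediger: {fmt(agr['bp'], 3)} {_fmt_ci(agr['bp_ci'])} "
            f"[{agr['strength_bp']}]"
        )
        lines.append(
            f"  abnormal by index: {t['index_abnormal']}/{t['n']} "
            f"({fmt(100 * dia['abnormal_fraction_index'], 1)}%)"
        )
        lines.append(f"  sensitivity %: {_fmt_est(dia['sens'], 100, 1)}")
        lines.append(f"  specificity %: {_fmt_est(dia['spec'], 100, 1)}")
        lines.append(f"  PPV %: {_fmt_est(dia['ppv'], 100, 1)}")
        lines.append(f"  NPV %: {_fmt_est(dia['npv'], 100, 1)}")
        lines.append(f"  LR+: {_fmt_est(dia['lr_pos'], 1, 2)}")
        lines.append(f"  LR-: {_fmt_est(dia['lr_neg'], 1, 2)}")
        lines.append(f"  diagnostic OR: {_fmt_est(dia['dor'], 1, 1)}")
    if "sample_size" in report:
        ss = report["sample_size"]
        lines.append(
            f"=== sample size ===\n  participants: {ss['participants']} "
            f"(p={ss['inputs']['p']}, halfwidth={ss['inputs']['halfwidth']}, "
            f"m={ss['inputs']['m']}, icc={ss['inputs']['icc']})"
        )
    if "checks" in report:
        lines.append("=== checks against published values ===")
        for name, chk in report["checks"].items():
            flag = "PASS" if chk["pass"] else "FAIL"
            lines.append(
                f"  {name}: computed {chk['computed']} vs published "
                f"{chk['published']} [{flag}]"
            )
    return "\n".join(lines)


def save_report(report: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2) + "\n")
    return path
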