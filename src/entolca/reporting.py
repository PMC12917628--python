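"""Scenario-suite orchestration and machine-readable reports.

Ties the pipeline stages together: for each requested scenario and
system the suite evaluates totals, stage contributions and either
allocation fractions (attributional) or displacement credits
(expansion), and optionally appends the nutritional comparison
(score-based functional units and substitution factors).  Reports are
plain dicts of floats — JSON/CSV-ready and reproducible given the same
configuration and seed; no arithmetic happens report-side beyond
rounding at print time.
"""

from __future__ import annotations

from pathlib import Path

from .allocation import allocate
from .calibration_targets import AP_IMPACTS_PER_KG, QNRF_SCORES
from .consequential import credit_report, default_displacement_links, expand_system
from .core import CATEGORIES, SCENARIOS, validate_system
from .engine import contribution_by_stage
from .nutrition import nutritional_fu_convert, substitution_factor
from .synthetic import CalibratedFixtures, calibrated_tables

__all__ = ["run_scenario_suite", "nutritional_comparison"]


def nutritional_comparison(reference: str = "beef") -> dict:
    """Impacts per 1000 score units and substitution factors for the
    protein sources with published per-kg impacts."""
    out: dict[str, dict] = {}
    ref_score = QNRF_SCORES[reference]
    for food, impacts in AP_IMPACTS_PER_KG.items():
        score = QNRF_SCORES[food]
        per_fu = {
            cat: (val * 1000.0 / (10.0 * score) if val is not None else None)
            for cat, val in impacts.items()
        }
        out[food] = {
            "qnrf_score": score,
            "substitution_vs_" + reference: substitution_factor(ref_score, score),
            "impacts_per_kg": dict(impacts),
            "impacts_per_1000_score": per_fu,
        }
    return out


def run_scenario_suite(config: dict | None = None) -> dict:
    """Run the scenario suite described by ``config``.

    Recognised keys (all optional): ``scenarios`` (names, default all
    four), ``systems`` (subset of {"farm", "meal"}), ``seed`` (for the
    synthetic background), ``nutrition`` (bool), and ``files`` (paths
    that must exist, checked before any computation).
    """
    config = dict(config or {})
    for path in config.get("files", []):
        if not Path(path).exists():
            raise FileNotFoundError(f"configured input file missing: {path}")
    scenario_names = config.get("scenarios", list(SCENARIOS))
    systems = config.get("systems", ["farm", "meal"])
    seed = int(config.get("seed", 0))

    fx: CalibratedFixtures = calibrated_tables(seed)
    for name, system in (("farm", fx.farm), ("meal", fx.meal)):
        findings = validate_system(system)
        if findings:
            raise ValueError(f"{name} fixture invalid: {findings}")

    bundle: dict = {"seed": seed, "calibration_notes": list(fx.notes), "reports": {}}
    for sname in scenario_names:
        scenario = SCENARIOS[sname]
        for system_name in systems:
            system = fx.farm if system_name == "farm" else fx.meal
            key = f"{sname}/{system_name}"
            contrib = contribution_by_stage(system, 1.0, fx.average, fx.cfs)
            report: dict = {
                "scenario": sname,
                "system": system_name,
                "stage_totals": {
                    stage: dict(zip(CATEGORIES, contrib.absolute.loc[stage]))
                    for stage in contrib.absolute.index
                },
            }
            if scenario.strategy == "expansion":
                links = default_displacement_links(system)
                res = expand_system(system, links, fx.marginal, fx.cfs)
                report["totals"] = res.net.as_dict()
                report["gross"] = res.gross.as_dict()
                report["credits"] = {k: v.as_dict() for k, v in res.credits.items()}
                report["credit_shares"] = credit_report(res)
            else:
                res = allocate(system, scenario, fx.average, fx.cfs)
                report["totals"] = res.main.as_dict()
                report["gross"] = res.gross.as_dict()
                report["fractions"] = dict(res.fractions)
                report["coproducts"] = {k: v.as_dict() for k, v in res.per_product.items()}
            bundle["reports"][key] = report

    if config.get("nutrition", True):
        bundle["nutrition"] = nutritional_comparison()
        mealworm_ae = bundle["reports"].get("TM_AE/farm")
        if mealworm_ae is not None:
            from .core import ImpactVector

            per_kg = ImpactVector.from_dict(mealworm_ae["totals"])
            bundle["nutrition"]["mealworm"]["impacts_per_1000_score_computed"] = (
                nutritional_fu_convert(per_kg, QNRF_SCORES["mealworm"]).as_dict()
            )
    return bundle
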