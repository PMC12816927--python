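"""End-to-end orchestration: run the full desk-scale study from one config.

A run executes, in order: synthetic-data generation (or input loading), the
pharmacovigilance screen with control-drug validation, instrument selection
and two-sample MR, mediation MR, and SMR+HEIDI, then writes per-stage TSVs
plus one consolidated JSON report.  Identical config + seed gives identical
outputs; every stage seed is derived deterministically from the master seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigError
from .faers import ReportDatabase
from .hierarchy import TermHierarchy
from .instruments import harmonize, select_instruments, steiger_filter
from .mediation import run_mediation_pipeline
from .mr import MRAnalysis
from .signal import control_validation, describe, screen
from .simulate import (
    cis_region_scenario,
    generate_report_db,
    generate_summary_stats,
    headline_pv_scenario,
    independent_cis_scenario,
    glp1r_like_scenario,
    mediation_scenario,
    pv_null_scenario,
    pv_planted_smq_scenario,
)
from .smr import smr_analysis
from .sumstats import LDMatrix, SummaryStats

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("mrpv")

_PV_PRESETS = {
    "headline": headline_pv_scenario,
    "planted_smq": pv_planted_smq_scenario,
    "null": pv_null_scenario,
}
_GEN_PRESETS = {
    "independent": independent_cis_scenario,
    "glp1r": glp1r_like_scenario,
    "cis_region": cis_region_scenario,
}

#: Named analysis thresholds with their conventional defaults.
DEFAULT_THRESHOLDS = {
    "p_max": 5e-8,       # instrument genome-wide significance
    "eaf_min": 0.01,     # minor-allele-frequency floor
    "r2_max": 0.01,      # clumping LD ceiling
    "f_min": 10.0,       # weak-instrument F cut
    "steiger_alpha": 0.05,
    "gate_alpha": 0.05,  # two-step mediation significance gate
    "heidi_alpha": 0.01,
    "alpha": 0.05,       # ROR confidence level
    "min_cases": 3,      # ROR signal criterion on the a cell
    "presso_n_sim": 1000,
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mrpv_run"
    pv: dict = field(default_factory=dict)
    genetics: dict = field(default_factory=dict)
    mediation: dict = field(default_factory=dict)
    smr: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pv and not self.genetics:
            raise ConfigError("config must define at least one of: pv, genetics")
        for name, section in (("pv", self.pv), ("genetics", self.genetics)):
            if section and not ("scenario" in section or "paths" in section):
                raise ConfigError(f"{name}: need either a 'scenario' preset or 'paths'")
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")

    @property
    def cuts(self) -> dict:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        return merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {"seed", "outdir", "pv", "genetics", "mediation", "smr", "thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(master: int) -> dict[str, int]:
    names = ["pv", "genetics", "mediation", "smr", "presso"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _load_pv(section: dict, seed: int) -> tuple[ReportDatabase, TermHierarchy]:
    if "paths" in section:
        paths = section["paths"]
        db = ReportDatabase.read_csv(paths["db"])
        hierarchy = TermHierarchy.read_csv(paths.get("hierarchy", paths["db"]))
        return db, hierarchy
    preset = section["scenario"]
    if preset not in _PV_PRESETS:
        raise ConfigError(f"unknown pv scenario preset {preset!r}")
    kwargs = {k: v for k, v in section.items() if k in ("n_reports", "suicide_ror", "ror")}
    scenario = _PV_PRESETS[preset](seed=seed, **kwargs)
    log.info("generating report database: preset=%s n_reports=%d seed=%d",
             preset, scenario.n_reports, seed)
    return generate_report_db(scenario), scenario.hierarchy


def _load_genetics(section: dict, seed: int):
    if "paths" in section:
        paths = section["paths"]
        exposure = SummaryStats.read_tsv(paths["exposure"], trait_type="quantitative")
        outcome = SummaryStats.read_tsv(paths["outcome"], trait_type="binary")
        ld = LDMatrix.read_files(paths["ld"], paths.get("ld_snps"))
        return exposure, outcome, None, ld
    preset = section["scenario"]
    if preset not in _GEN_PRESETS:
        raise ConfigError(f"unknown genetics scenario preset {preset!r}")
    kwargs = {
        k: v
        for k, v in section.items()
        if k in ("theta", "n_snps", "mode", "outcome_name", "n_gwas", "n_eqtl")
    }
    scenario = _GEN_PRESETS[preset](seed=seed, **kwargs)
    log.info("generating summary statistics: preset=%s mode=%s theta=%.4f seed=%d",
             preset, scenario.mode, scenario.theta, seed)
    sset = generate_summary_stats(scenario)
    return sset.exposure, sset.outcome, sset.mediator, sset.ld


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; returns (and writes) the consolidated
    report.  Any stage error aborts with a stage-labelled message."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cuts = config.cuts
    seeds = _stage_seeds(config.seed)
    report: dict[str, Any] = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": cuts,
        "counts": {},
    }

    stage = "config"
    try:
        if config.pv:
            stage = "pv"
            db, hierarchy = _load_pv(config.pv, seeds["pv"])
            db_dedup = db.deduplicate()
            log.info("pv: %d records -> %d deduplicated cases", db.n_reports, db_dedup.n_reports)
            report["counts"]["pv_records"] = int(db.n_reports)
            report["counts"]["pv_cases"] = int(db_dedup.n_reports)

            targets = config.pv.get("targets", ["glp1_ra"])
            stratum = config.pv.get("stratum")
            res = screen(
                db,
                hierarchy,
                targets=targets,
                level=config.pv.get("level", "SMQ"),
                scope=config.pv.get("scope", "narrow"),
                event_sets=config.pv.get("event_sets"),
                stratum=stratum,
                alpha=cuts["alpha"],
                min_cases=cuts["min_cases"],
            )
            res.to_frame().to_csv(outdir / "pv_screen.tsv", sep="\t", index=False)
            report["pv"] = {
                "n_tests": res.n_tests,
                "signals": [
                    {"event_set": r.event_set, "stratum": r.stratum, "ror": r.ror,
                     "ci_low": r.ci_low, "ci_high": r.ci_high, "n_cases": r.n_cases}
                    for r in res.signals()
                ],
                "results": res.to_frame().to_dict(orient="records"),
            }
            controls = config.pv.get("controls")
            if controls:
                val = control_validation(db, hierarchy, controls)
                val.to_frame().to_csv(outdir / "pv_controls.tsv", sep="\t", index=False)
                report["pv"]["controls_passed"] = bool(val.passed)
            demo = describe(db)
            report["pv"]["describe"] = {
                k: v.to_dict(orient="index") for k, v in demo.items() if k != "n_reports"
            }

        if config.genetics:
            stage = "genetics"
            exposure, outcome, mediator, ld = _load_genetics(config.genetics, seeds["genetics"])
            ivs = select_instruments(
                exposure, ld, p_max=cuts["p_max"], eaf_min=cuts["eaf_min"],
                r2_max=cuts["r2_max"], f_min=cuts["f_min"],
            )
            log.info("genetics: %d candidate SNPs -> %d instruments", len(exposure), len(ivs))
            report["counts"]["candidate_snps"] = int(len(exposure))
            report["counts"]["instruments"] = int(len(ivs))
            hset = steiger_filter(harmonize(ivs, outcome), alpha=cuts["steiger_alpha"])
            fit = MRAnalysis(hset).fit(presso=True, n_sim=cuts["presso_n_sim"], seed=seeds["presso"])
            fit.to_frame().to_csv(outdir / "mr_results.tsv", sep="\t", index=False)
            sens = fit.sensitivity
            report["mr"] = {
                "estimates": fit.to_frame().to_dict(orient="records"),
                "cochran_q": sens.cochran_q,
                "q_p": sens.q_p,
                "egger_intercept_p": sens.intercept_p,
                "presso_global_p": sens.presso_global_p,
                "loo_influential": sens.loo_influential,
            }

            if config.mediation.get("enabled"):
                stage = "mediation"
                scenario = mediation_scenario(
                    seed=seeds["mediation"],
                    proportion=config.mediation.get("proportion", 0.18),
                    total=config.mediation.get("total", math.log(0.915)),
                )
                sset = generate_summary_stats(scenario)
                med = run_mediation_pipeline(
                    sset.exposure, sset.mediator, sset.outcome, sset.ld,
                    gate_alpha=cuts["gate_alpha"],
                )
                report["mediation"] = {
                    "gate_passed": med.gate_passed,
                    "indirect_beta": med.indirect_beta,
                    "proportion": med.proportion,
                    "proportion_ci": [med.proportion_ci_low, med.proportion_ci_high],
                    "proportion_p": med.proportion_p,
                }
                (outdir / "mediation.json").write_text(
                    json.dumps(report["mediation"], indent=2) + "\n"
                )

            if config.smr.get("enabled"):
                stage = "smr"
                scenario = cis_region_scenario(
                    mode=config.smr.get("mode", "causal"),
                    theta=config.smr.get("theta", math.log(0.79)),
                    seed=seeds["smr"],
                )
                sset = generate_summary_stats(scenario)
                smr_res = smr_analysis(
                    sset.exposure, sset.outcome, sset.ld,
                    seed=seeds["smr"], heidi_alpha=cuts["heidi_alpha"],
                    mc_draws=config.smr.get("mc_draws", 100_000),
                )
                lo, hi = smr_res.or_ci
                report["smr"] = {
                    "top_snp": smr_res.top_snp,
                    "or": smr_res.or_,
                    "or_ci": [lo, hi],
                    "p_smr": smr_res.p_smr,
                    "heidi_p": smr_res.heidi_p,
                    "n_heidi_snps": smr_res.n_heidi_snps,
                    "verdict": smr_res.verdict,
                }
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report["counts"]["tests_run"] = int(
        report.get("pv", {}).get("n_tests", 0)
        + len(report.get("mr", {}).get("estimates", []))
        + (1 if "mediation" in report else 0)
        + (1 if "smr" in report else 0)
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    log.info("report written to %s", outdir / "report.json")
    return report
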