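"""Validation studies: oracle checks and ground-truth recovery simulations.

Every function here re-runs the package's own estimators against planted
truth from the synthetic-data module (or against an independent generic
routine, for the closed-form oracles) and returns plain dictionaries of
measured quantities.  The studies double as the acceptance checks and as
material for the worked examples in the documentation.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy import stats

from .instruments import harmonize, select_instruments, steiger_filter
from .mediation import mediate, run_mediation_pipeline
from .mr import MRAnalysis, egger, ivw, mr_presso
from .signal import ContingencyTable, ror, screen
from .simulate import (
    cis_region_scenario,
    generate_report_db,
    generate_summary_stats,
    independent_cis_scenario,
    mediation_scenario,
    outlier_scenario,
    pv_null_scenario,
    pv_planted_smq_scenario,
    reverse_scenario,
)
from .smr import heidi_test, smr_test

__all__ = [
    "ror_oracle_check",
    "pv_planted_recovery",
    "pv_null_false_signal_rate",
    "dedup_exactness",
    "ivw_oracle_check",
    "ivw_recovery_study",
    "egger_calibration_study",
    "presso_outlier_study",
    "steiger_filter_study",
    "mediation_recovery_study",
    "smr_strong_instrument_check",
    "smr_recovery_study",
    "heidi_power_study",
]


# ---------------------------------------------------------------------------
# pharmacovigilance
# ---------------------------------------------------------------------------


def ror_oracle_check(n_tables: int = 100, seed: int = 0) -> dict:
    """Compare ROR point estimates and CIs against the generic 2x2
    odds-ratio routine in statsmodels on random tables."""
    from statsmodels.stats.contingency_tables import Table2x2

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = rng.integers(1, 500, size=4)
        ours = ror(ContingencyTable(int(a), int(b), int(c), int(d)))
        oracle = Table2x2(np.array([[a, b], [c, d]]))
        lo, hi = oracle.oddsratio_confint(0.05)
        worst = max(
            worst,
            abs(ours.ror - oracle.oddsratio),
            abs(ours.ci_low - lo),
            abs(ours.ci_high - hi),
        )
    return {"max_abs_diff": float(worst), "n_tables": n_tables}


def pv_planted_recovery(
    ror_true: float = 5.0, seed: int = 1, n_reports: int = 200_000
) -> dict:
    """Screen a database with one planted SMQ-level reporting OR."""
    scenario = pv_planted_smq_scenario(ror=ror_true, seed=seed, n_reports=n_reports)
    db = generate_report_db(scenario)
    res = screen(
        db, scenario.hierarchy, ["glp1_ra"], level="SMQ", scope="narrow",
        event_sets=["suicide_self_harm"],
    ).results[0]
    return {
        "ror": res.ror,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "n_cases": res.n_cases,
        "is_signal": bool(res.is_signal),
        "covers_truth": bool(res.ci_low <= ror_true <= res.ci_high),
        "n_reports": n_reports,
    }


def pv_null_false_signal_rate(
    n_seeds: int = 200, n_reports: int = 20_000, seed: int = 0
) -> dict:
    """Fraction of evaluable SOC-level tests flagged as signals when no
    disproportionality is planted (type-I behaviour of the screen)."""
    flagged = evaluable = 0
    for i in range(n_seeds):
        scenario = pv_null_scenario(seed=seed * 100_003 + i, n_reports=n_reports)
        db = generate_report_db(scenario)
        res = screen(db, scenario.hierarchy, ["glp1_ra"], level="SOC")
        for r in res.results:
            if r.evaluable:
                evaluable += 1
                flagged += r.is_signal
    return {
        "false_signal_rate": flagged / evaluable,
        "n_tests": evaluable,
        "n_seeds": n_seeds,
        "n_reports": n_reports,
    }


def dedup_exactness(
    n_reports: int = 1000, duplicate_rate: float = 0.2, seed: int = 0
) -> dict:
    """Survivor count after deduplication must equal the case count."""
    scenario = pv_null_scenario(seed=seed, n_reports=n_reports)
    scenario = replace(scenario, duplicate_rate=duplicate_rate)
    db = generate_report_db(scenario)
    survivors = db.deduplicate().n_reports
    expected = n_reports - math.floor(duplicate_rate * n_reports)
    return {
        "survivors": int(survivors),
        "expected": int(expected),
        "exact": bool(survivors == expected),
        "n_records": int(db.n_reports),
    }


def pv_ci_coverage_study(
    n_seeds: int = 1000,
    ror_true: float = 2.0,
    n_reports: int = 4000,
    seed: int = 0,
) -> dict:
    """Empirical coverage of the 95% Wald interval for a planted PT-level OR."""
    from .simulate import PlantedSignal

    covered = evaluated = 0
    for i in range(n_seeds):
        scenario = pv_null_scenario(seed=seed * 100_003 + i, n_reports=n_reports)
        pt = sorted(scenario.event_catalog)[0]
        scenario = replace(
            scenario, planted=[PlantedSignal("glp1_ra", pt, ror_true)]
        )
        db = generate_report_db(scenario)
        res = screen(
            db, scenario.hierarchy, ["glp1_ra"], level="PT", event_sets=[pt]
        ).results[0]
        if res.evaluable:
            evaluated += 1
            covered += res.ci_low <= ror_true <= res.ci_high
    return {"coverage": covered / evaluated, "n_seeds": evaluated}


# ---------------------------------------------------------------------------
# MR estimators
# ---------------------------------------------------------------------------


def ivw_oracle_check(n_sets: int = 50, seed: int = 0) -> dict:
    """IVW against generic weighted zero-intercept least squares, and the
    Egger fit with the intercept forced to zero against fixed-effect IVW."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    worst_ivw = worst_egger = 0.0
    for _ in range(n_sets):
        k = int(rng.integers(3, 25))
        b_exp = rng.normal(0.3, 0.1, k)
        se_exp = np.full(k, 0.02)
        b_out = rng.normal(0.0, 0.05, k)
        se_out = rng.uniform(0.002, 0.01, k)
        est = ivw((b_exp, se_exp, b_out, se_out), random_effects=False)
        wls = sm.WLS(b_out, b_exp[:, None], weights=1.0 / se_out**2).fit()
        worst_ivw = max(worst_ivw, abs(est.beta - wls.params[0]))
        constrained, _ = egger((b_exp, se_exp, b_out, se_out), fit_intercept=False)
        worst_egger = max(
            worst_egger, abs(constrained.beta - est.beta), abs(constrained.se - est.se)
        )
    return {"max_abs_diff_ivw": float(worst_ivw), "max_abs_diff_egger0": float(worst_egger)}


def _fit_pipeline(scenario, random_effects: bool = True, steiger: bool = True):
    """Generate -> select -> harmonize (-> Steiger) -> IVW for one scenario."""
    sset = generate_summary_stats(scenario)
    ivs = select_instruments(sset.exposure, sset.ld)
    hset = harmonize(ivs, sset.outcome)
    if steiger:
        hset = steiger_filter(hset)
    return hset, ivw(hset, random_effects=random_effects)


def ivw_recovery_study(
    n_reps: int = 500, theta: float = math.log(0.9), seed: int = 0
) -> dict:
    """Bias and CI coverage of the full selection+harmonization+IVW pipeline
    at the strong-instrument cis regime (22 instruments, n ~ 5e5)."""
    biases, covered, ors, ks = [], 0, [], []
    for i in range(n_reps):
        scenario = independent_cis_scenario(theta=theta, seed=seed * 100_003 + i)
        _, est = _fit_pipeline(scenario)
        biases.append(est.beta - theta)
        covered += est.ci_low <= theta <= est.ci_high
        ors.append(est.or_)
        ks.append(est.n_snps)
    return {
        "median_bias": float(np.median(biases)),
        "mean_bias": float(np.mean(biases)),
        "coverage": covered / n_reps,
        "mean_or": float(np.mean(ors)),
        "true_or": float(math.exp(theta)),
        "mean_n_snps": float(np.mean(ks)),
        "n_reps": n_reps,
    }


def egger_calibration_study(
    n_null: int = 1000,
    n_power: int = 400,
    seed: int = 0,
    pleio_mean: float = 0.02,
    pleio_sd: float = 0.005,
) -> dict:
    """Type-I error of the Egger intercept test under no pleiotropy and its
    power under directional pleiotropy of the planted magnitude."""
    def rejection_rate(build, n):
        rej = 0
        for i in range(n):
            sset = generate_summary_stats(build(seed * 100_003 + 7 + i))
            ivs = select_instruments(sset.exposure, sset.ld)
            hset = harmonize(ivs, sset.outcome)
            _, intercept = egger(hset)
            rej += intercept.p < 0.05
        return rej / n

    null_rate = rejection_rate(
        lambda s: independent_cis_scenario(theta=math.log(0.9), seed=s), n_null
    )
    power = rejection_rate(
        lambda s: independent_cis_scenario(
            theta=math.log(0.9), seed=s,
            pleio_frac=1.0, pleio_mean=pleio_mean, pleio_sd=pleio_sd,
        ),
        n_power,
    )
    return {
        "type1_rate": null_rate,
        "power": power,
        "n_null": n_null,
        "n_power": n_power,
        "mc_band": [0.05 - 2 * math.sqrt(0.05 * 0.95 / n_null),
                    0.05 + 2 * math.sqrt(0.05 * 0.95 / n_null)],
    }


def presso_outlier_study(
    n_seeds: int = 200, theta: float = math.log(0.9), outlier_z: float = 5.0, seed: int = 0
) -> dict:
    """Detection rate for one planted pleiotropic outlier (direct outcome
    effect = ``outlier_z`` outcome SEs) and how often the outlier-removed
    estimate beats the raw IVW."""
    flagged = corrected_closer = corrected_n = 0
    for i in range(n_seeds):
        scenario = outlier_scenario(theta=theta, seed=seed * 100_003 + i, outlier_z=outlier_z)
        sset = generate_summary_stats(scenario)
        ivs = select_instruments(sset.exposure, sset.ld)
        hset = harmonize(ivs, sset.outcome)
        raw = ivw(hset)
        res = mr_presso(hset, n_sim=1000, seed=seed * 7 + i)
        kept_snps = hset.snps
        outlier_hit = any(kept_snps[j] == "rs100001" for j in res.outlier_idx)
        flagged += outlier_hit
        if res.corrected is not None:
            corrected_n += 1
            corrected_closer += abs(res.corrected.beta - theta) < abs(raw.beta - theta)
    return {
        "outlier_detection_rate": flagged / n_seeds,
        "corrected_closer_rate": corrected_closer / corrected_n if corrected_n else float("nan"),
        "n_corrected": corrected_n,
        "n_seeds": n_seeds,
    }


def steiger_filter_study(n_seeds: int = 200, seed: int = 0) -> dict:
    """Removal rate for planted reverse-causal instruments and retention
    rate for valid ones, aggregated over selected SNPs."""
    n_cis = 22
    rev_removed = rev_selected = valid_kept = valid_selected = 0
    for i in range(n_seeds):
        scenario = reverse_scenario(seed=seed * 100_003 + i)
        sset = generate_summary_stats(scenario)
        ivs = select_instruments(sset.exposure, sset.ld)
        hset = steiger_filter(harmonize(ivs, sset.outcome))
        table = hset.table
        idx = table["snp"].str.removeprefix("rs").astype(int) - 100001
        is_rev = (idx >= n_cis).to_numpy()
        dropped = table["dropped_reason"].notna().to_numpy()
        steiger_dropped = (table["dropped_reason"] == "steiger").to_numpy()
        considered = ~dropped | steiger_dropped  # survived harmonization
        rev_selected += int((is_rev & considered).sum())
        rev_removed += int((is_rev & steiger_dropped).sum())
        valid_selected += int((~is_rev & considered).sum())
        valid_kept += int((~is_rev & ~dropped).sum())
    return {
        "reverse_removed_rate": rev_removed / rev_selected,
        "valid_retained_rate": valid_kept / valid_selected,
        "n_reverse": rev_selected,
        "n_valid": valid_selected,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def mediation_recovery_study(
    n_reps: int = 500,
    proportion: float = 0.18,
    seed: int = 0,
    n_bootstrap_reps: int = 50,
    bootstrap_draws: int = 2000,
) -> dict:
    """Recovery of a planted proportion mediated by the full two-step
    pipeline, delta-interval coverage, and agreement of the delta SE with a
    parametric-bootstrap SE on a subset of replicates."""
    props, covered, gate = [], 0, 0
    se_ratios = []
    rng = np.random.default_rng(seed + 17)
    for i in range(n_reps):
        scenario = mediation_scenario(proportion=proportion, seed=seed * 100_003 + i)
        sset = generate_summary_stats(scenario)
        res = run_mediation_pipeline(sset.exposure, sset.mediator, sset.outcome, sset.ld)
        if not res.gate_passed or res.proportion is None:
            continue
        gate += 1
        props.append(res.proportion)
        covered += res.proportion_ci_low <= proportion <= res.proportion_ci_high
        if len(se_ratios) < n_bootstrap_reps:
            b1, s1 = res.step1.beta, res.step1.se
            b2, s2 = res.step2.beta, res.step2.se
            bt, st = res.total.beta, res.total.se
            draws = (
                rng.normal(b1, s1, bootstrap_draws)
                * rng.normal(b2, s2, bootstrap_draws)
                / rng.normal(bt, st, bootstrap_draws)
            )
            se_ratios.append(res.proportion_se / draws.std())
    props = np.asarray(props)
    return {
        "mean_proportion": float(props.mean()),
        "mc_se": float(props.std(ddof=1) / math.sqrt(len(props))),
        "coverage": covered / gate,
        "gate_pass_rate": gate / n_reps,
        "delta_vs_bootstrap_se_ratio": float(np.mean(se_ratios)),
        "true_proportion": proportion,
        "n_reps": n_reps,
    }


def mediation_delta_oracle(seed: int = 0, draws: int = 200_000) -> dict:
    """Hand-checkable delta-method arithmetic against a big parametric
    simulation at a fixed parameter point."""
    from .mr import MREstimate

    step1 = MREstimate("ivw", 0.5, 0.1, 1e-6, 10)
    step2 = MREstimate("ivw", 0.4, 0.1, 1e-4, 10)
    total = MREstimate("ivw", 1.0, 0.2, 1e-8, 10)
    res = mediate(total, step1, step2)
    rng = np.random.default_rng(seed)
    sim = rng.normal(0.5, 0.1, draws) * rng.normal(0.4, 0.1, draws)
    return {
        "indirect": res.indirect_beta,
        "indirect_se": res.indirect_se,
        "sim_indirect_se": float(sim.std()),
        "proportion": res.proportion,
    }


# ---------------------------------------------------------------------------
# SMR / HEIDI
# ---------------------------------------------------------------------------


def smr_strong_instrument_check(z_eqtl_min: float = 10.0) -> dict:
    """In the strong-instrument regime the SMR chi-square p-value approaches
    the Wald-ratio normal p-value; report the worst relative error on a grid.

    The relative error in the tail probability is ~ z_g^4 / (2 z_e^2), so the
    grid covers the sub-threshold GWAS associations (|z_g| <= 2) for which a
    tail-probability comparison is meaningful; for very large |z_g| both
    p-values vanish and their ratio is no longer informative.
    """
    worst = 0.0
    for z_e in (z_eqtl_min, 15.0, 25.0, 40.0):
        for z_g in (0.5, 1.0, 1.5, 2.0):
            t_smr = z_g**2 * z_e**2 / (z_g**2 + z_e**2)
            p_smr = stats.chi2.sf(t_smr, 1)
            p_wald = 2 * stats.norm.sf(abs(z_g))
            worst = max(worst, abs(p_smr - p_wald) / p_wald)
    return {"max_rel_err": float(worst), "z_eqtl_min": z_eqtl_min}


def smr_recovery_study(
    n_reps: int = 500, theta: float = math.log(0.79), seed: int = 0
) -> dict:
    """Mean SMR odds ratio across replicates of the single-shared-causal-
    variant cis scenario, against the planted value."""
    ors = []
    for i in range(n_reps):
        scenario = cis_region_scenario(mode="causal", theta=theta, seed=seed * 100_003 + i)
        sset = generate_summary_stats(scenario)
        res = smr_test(sset.exposure, sset.outcome)
        ors.append(res.or_)
    ors = np.asarray(ors)
    return {
        "mean_or": float(ors.mean()),
        "mc_se": float(ors.std(ddof=1) / math.sqrt(n_reps)),
        "true_or": float(math.exp(theta)),
        "n_reps": n_reps,
    }


def heidi_power_study(
    mode: str = "linkage",
    n_seeds: int = 400,
    alpha: float = 0.01,
    mc_draws: int = 25_000,
    seed: int = 0,
) -> dict:
    """HEIDI rejection rate under the linkage scenario (power) or the
    single-shared-causal-variant scenario (type-I error)."""
    theta = 0.0 if mode == "linkage" else math.log(0.79)
    rejected = testable = 0
    for i in range(n_seeds):
        scenario = cis_region_scenario(mode=mode, theta=theta, seed=seed * 100_003 + i)
        sset = generate_summary_stats(scenario)
        res = smr_test(sset.exposure, sset.outcome)
        heidi = heidi_test(
            sset.exposure, sset.outcome, sset.ld, res.top_snp,
            mc_draws=mc_draws, seed=seed * 11 + i,
        )
        if heidi.p is not None:
            testable += 1
            rejected += heidi.p < alpha
    return {
        "rejection_rate": rejected / testable,
        "n_testable": testable,
        "n_seeds": n_seeds,
        "mode": mode,
        "mc_draws": mc_draws,
    }
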