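"""Ground-truth contracts of the synthetic-data generators."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mrpv.hierarchy import generate_term_hierarchy
from mrpv.instruments import harmonize, select_instruments
from mrpv.mr import ivw
from mrpv.signal import screen
from mrpv.simulate import (
    GeneticScenario,
    PlantedSignal,
    generate_report_db,
    generate_summary_stats,
    independent_cis_scenario,
    pv_null_scenario,
    pv_planted_smq_scenario,
)
from mrpv.simulate.sumstats import build_ld


class TestTermHierarchy:
    def test_tree_arithmetic_and_unique_ancestor_paths(self):
        h = generate_term_hierarchy(n_soc=2, fanout=(2, 2, 2), seed=0)
        assert len(h.pts()) == 16
        for pt in h.pts():
            chain = [h.rollup(pt, lvl) for lvl in ("HLT", "HLGT", "SOC")]
            assert len(chain) == 3
            # rollup is a function: repeated calls agree
            assert h.rollup(pt, "SOC") == h.rollup(pt, "SOC")
        assert len(h.terms("SOC")) == 2
        assert len(h.terms("HLGT")) == 4

    def test_smq_narrow_subset_of_broad(self):
        h = generate_term_hierarchy(n_soc=2, fanout=(2, 2, 2), seed=1, n_smq=3)
        for narrow, broad in h.smq.values():
            assert narrow <= broad
        pts = sorted(h.pts())
        h.add_smq("x", narrow=[pts[0]], broad=[pts[0], pts[1]])
        assert h.smq_members("x", "narrow") <= h.smq_members("x", "broad")

    def test_invalid_fanout_rejected(self):
        with pytest.raises(ValueError):
            generate_term_hierarchy(n_soc=0, fanout=(1, 1, 1))


class TestReportGenerator:
    def test_duplicate_counting_contract(self):
        scenario = replace(pv_null_scenario(seed=3, n_reports=1000), duplicate_rate=0.2)
        db = generate_report_db(scenario)
        assert db.n_reports == 1000
        versions = db.demo.groupby("caseid").size()
        assert int((versions >= 2).sum()) == math.floor(0.2 * 1000)
        assert db.n_cases == 1000 - math.floor(0.2 * 1000)

    def test_planted_event_must_exist(self):
        scenario = pv_null_scenario(seed=0, n_reports=100)
        bad = replace(scenario, planted=[PlantedSignal("glp1_ra", "no_such_pt", 2.0)])
        with pytest.raises(ValueError, match="neither a catalog PT nor a known SMQ"):
            generate_report_db(bad)
        bad_drug = replace(scenario, planted=[
            PlantedSignal("no_such_drug", sorted(scenario.event_catalog)[0], 2.0)
        ])
        with pytest.raises(ValueError, match="unknown drug"):
            generate_report_db(bad_drug)

    def test_null_scenario_shows_no_signal(self):
        scenario = pv_null_scenario(seed=0, n_reports=30_000)
        db = generate_report_db(scenario)
        res = screen(db, scenario.hierarchy, ["glp1_ra"], level="SOC")
        rors = [r.ror for r in res.results if r.evaluable]
        assert rors, "expected evaluable SOC tables"
        # no planted effect: log-RORs scatter around zero, and false signals
        # stay near the per-test alpha level (the rate itself is checked over
        # 200 seeds in the acceptance suite)
        assert abs(np.mean(np.log(rors))) < 0.1
        n_signals = sum(r.is_signal for r in res.results)
        assert n_signals <= 0.15 * len(rors)

    def test_planted_ror_recovered_within_its_ci(self):
        scenario = pv_planted_smq_scenario(ror=5.0, seed=1, n_reports=200_000)
        db = generate_report_db(scenario)
        res = screen(
            db, scenario.hierarchy, ["glp1_ra"], level="SMQ",
            event_sets=["suicide_self_harm"],
        ).results[0]
        assert res.ci_low <= 5.0 <= res.ci_high

    def test_every_report_has_an_event_and_valid_roles(self):
        scenario = pv_null_scenario(seed=2, n_reports=2000)
        db = generate_report_db(scenario)
        assert set(db.reac["primaryid"]) == set(db.demo["primaryid"])
        assert set(db.drug["role_cod"]) <= {"PS", "SS", "C"}
        # exactly one PS drug and one indication per report
        ps = db.drug[db.drug["role_cod"] == "PS"]
        assert ps["primaryid"].is_unique
        assert len(db.indi) == db.n_reports

    def test_bit_reproducible(self):
        scenario = pv_null_scenario(seed=42, n_reports=1500)
        a = generate_report_db(scenario)
        b = generate_report_db(scenario)
        for name in ("demo", "drug", "reac", "indi"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))


class TestSummaryStatsGenerator:
    def test_z_and_p_agree(self):
        sset = generate_summary_stats(independent_cis_scenario(theta=0.1, seed=5))
        for stats_ in (sset.exposure, sset.outcome):
            z = stats_.table["beta"] / stats_.table["se"]
            from scipy import stats as sps

            expected = 2 * sps.norm.sf(np.abs(z))
            assert np.allclose(stats_.table["p"], expected, atol=1e-10)

    def test_bit_reproducible(self):
        scenario = independent_cis_scenario(theta=math.log(0.9), seed=9)
        a = generate_summary_stats(scenario)
        b = generate_summary_stats(scenario)
        pd.testing.assert_frame_equal(a.exposure.table, b.exposure.table)
        pd.testing.assert_frame_equal(a.outcome.table, b.outcome.table)
        assert np.array_equal(a.ld.r, b.ld.r)

    def test_observed_covariance_matches_model(self):
        """Empirical covariance of the observed betas across replicates
        reproduces D R D entrywise within 3 Monte-Carlo SEs."""
        n_reps = 2500
        r = build_ld(("ar1", 0.6), 4)
        base = GeneticScenario(
            n_snps=4, ld=("ar1", 0.6), causal_idx=[0], b_expr=0.3,
            maf=0.3, eaf_noise=False, palindromic_fraction=0.0,
        )
        betas = np.empty((n_reps, 4))
        for i in range(n_reps):
            sset = generate_summary_stats(replace(base, seed=50_000 + i))
            betas[i] = sset.exposure.table["beta"].to_numpy()
        se = 1.0 / np.sqrt(2 * 0.3 * 0.7 * base.n_eqtl)
        sigma = r * se**2
        emp = np.cov(betas, rowvar=False)
        mc_se = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n_reps)
        assert np.all(np.abs(emp - sigma) < 3.2 * mc_se)

    def test_null_mode_ivw_centred_on_zero(self):
        betas = []
        for i in range(60):
            sset = generate_summary_stats(independent_cis_scenario(theta=0.0, seed=900 + i))
            ivs = select_instruments(sset.exposure, sset.ld)
            est = ivw(harmonize(ivs, sset.outcome))
            betas.append(est.beta)
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 3 * betas.std(ddof=1) / math.sqrt(len(betas))

    def test_gwas_scale_effect_recovered_within_ci(self):
        """A planted protective log-OR at biobank GWAS scale (~480k) is inside the
        IVW 95% CI for a fixed seed."""
        theta = math.log(0.784)
        scenario = independent_cis_scenario(theta=theta, seed=12, n_gwas=480_289)
        sset = generate_summary_stats(scenario)
        est = ivw(harmonize(select_instruments(sset.exposure, sset.ld), sset.outcome))
        assert est.ci_low <= theta <= est.ci_high

    def test_non_psd_ld_rejected(self):
        bad = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        scenario = GeneticScenario(n_snps=3, ld=bad, causal_idx=[0], b_expr=0.3)
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_summary_stats(scenario)

    def test_linkage_mode_structure(self):
        """Linkage mode has two distinct causal variants: one expression-only,
        one outcome-only (no causal expression->outcome path)."""
        from mrpv.simulate import cis_region_scenario

        scenario = cis_region_scenario(mode="linkage", seed=0)
        assert scenario.theta == 0.0
        sset = generate_summary_stats(scenario)
        # the outcome-only variant produces a genome-wide significant GWAS hit
        assert sset.outcome.table["p"].min() < 5e-8
        # while expression and outcome top hits sit at different positions
        e_top = sset.exposure.table.loc[sset.exposure.table["p"].idxmin(), "pos"]
        g_top = sset.outcome.table.loc[sset.outcome.table["p"].idxmin(), "pos"]
        assert e_top != g_top

    def test_mediator_panel_layout(self):
        from mrpv.simulate import mediation_scenario

        sset = generate_summary_stats(mediation_scenario(seed=4))
        assert sset.mediator is not None
        assert len(sset.mediator) == len(sset.exposure)
        # mediator instruments live off the cis chromosome
        extras = sset.mediator.table.iloc[22:]
        assert (extras["chr"] != "6").all()
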