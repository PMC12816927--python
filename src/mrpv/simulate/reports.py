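"""Synthetic spontaneous-report database with planted reporting odds ratios.

Reports are generated independently.  Each case gets one primary-suspect
drug drawn from the catalog, an indication drawn from that drug's profile,
demographics from fixed categorical distributions, and events drawn as
independent Bernoulli trials per catalog preferred term.  For a planted
(drug, event) odds ratio R the event's reporting odds are multiplied by a
factor rho for reports of that drug (in the configured stratum), chosen so
that the report-level 2x2 contingency table reproduces R exactly in
expectation: for a single PT, rho = R; for an SMQ the common per-member
odds multiplier is solved numerically so the odds ratio of "any member PT"
equals R.

A configured fraction of cases is emitted twice (same case id, version 2 and
a new primaryid, identical content) to exercise deduplication: with
duplicate_rate d and n_reports N, exactly floor(d*N) cases carry two
versions and N records are emitted in total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ..faers import ReportDatabase
from .scenarios import PVScenario, PlantedSignal

__all__ = ["generate_report_db"]

# Fixed categorical distributions for report covariates (loosely modelled on
# the demographics of a US-dominated spontaneous-report system).
_AGE_BANDS = (["<18", "18-64.9", "65-85", ">85", "unknown"], [0.04, 0.62, 0.27, 0.02, 0.05])
_WEIGHT_BANDS = (["<50kg", "50-100kg", ">100kg", "unknown"], [0.05, 0.55, 0.15, 0.25])
_COUNTRIES = (["US", "GB", "CA", "other"], [0.873, 0.038, 0.011, 0.078])
_REPORTERS = (["consumer", "physician", "pharmacist", "other"], [0.80, 0.085, 0.05, 0.065])
_QUARTERS = [f"{y}Q{q}" for y in range(2004, 2025) for q in range(1, 5)]


def _smq_odds_multiplier(base_probs: np.ndarray, target_or: float) -> float:
    """Common per-member odds multiplier rho such that the odds ratio of
    'any member PT occurs' equals ``target_or`` under independence."""
    base_probs = np.asarray(base_probs, dtype=float)
    p_any0 = 1.0 - np.prod(1.0 - base_probs)
    odds0 = p_any0 / (1.0 - p_any0)
    q = base_probs / (1.0 - base_probs)

    def gap(log_rho: float) -> float:
        rho = np.exp(log_rho)
        p = rho * q / (1.0 + rho * q)
        p_any = np.clip(1.0 - np.prod(1.0 - p), 1e-300, 1 - 1e-12)
        return np.log(p_any / (1.0 - p_any)) - np.log(odds0 * target_or)

    return float(np.exp(brentq(gap, -25.0, 25.0, xtol=1e-12)))


def _resolve_planted(scenario: PVScenario) -> list[tuple[PlantedSignal, list[str], float]]:
    """Map each planted signal to its member PTs and per-member odds multiplier."""
    resolved = []
    catalog_pts = set(scenario.event_catalog)
    known_drug_keys = set(scenario.drug_names) | set(scenario.classes.values())
    for sig in scenario.planted:
        if sig.drug not in known_drug_keys:
            raise ValueError(f"planted signal references unknown drug or class {sig.drug!r}")
        if sig.event in catalog_pts:
            members = [sig.event]
            rho = sig.ror
        elif scenario.hierarchy is not None and sig.event in scenario.hierarchy.smq:
            members = sorted(
                scenario.hierarchy.smq_members(sig.event, "narrow") & catalog_pts
            )
            if not members:
                raise ValueError(
                    f"planted SMQ {sig.event!r} has no member PT in the event catalog"
                )
            base = np.array([scenario.event_catalog[pt] for pt in members])
            rho = _smq_odds_multiplier(base, sig.ror)
        else:
            raise ValueError(
                f"planted event {sig.event!r} is neither a catalog PT nor a known SMQ"
            )
        resolved.append((sig, members, rho))
    return resolved


def generate_report_db(scenario: PVScenario) -> ReportDatabase:
    """Generate a :class:`ReportDatabase` realising ``scenario``.

    Reports that sample no catalog event receive the scenario's filler PT so
    that every report carries at least one coded event; because case/non-case
    status for any target event set is decided at the report level, the
    filler does not perturb any planted 2x2 table.
    """
    planted = _resolve_planted(scenario)
    n_dup = int(np.floor(scenario.duplicate_rate * scenario.n_reports))
    n_cases = scenario.n_reports - n_dup
    if n_dup > n_cases:
        raise ValueError("duplicate_rate too high for n_reports")

    ss = np.random.SeedSequence(scenario.seed)
    rng_struct, rng_events, rng_dup = [np.random.default_rng(s) for s in ss.spawn(3)]

    # -- per-case covariates --------------------------------------------
    drugs = scenario.drug_catalog
    weights = np.asarray(
        scenario.drug_weights if scenario.drug_weights is not None else np.ones(len(drugs))
    )
    weights = weights / weights.sum()
    drug_idx = rng_struct.choice(len(drugs), size=n_cases, p=weights)
    drug_name = np.array(scenario.drug_names, dtype=object)[drug_idx]
    drug_class = np.array([d.drug_class for d in drugs], dtype=object)[drug_idx]

    indication = np.empty(n_cases, dtype=object)
    for i, spec in enumerate(drugs):
        mask = drug_idx == i
        n_i = int(mask.sum())
        if n_i:
            inds = list(spec.indications)
            probs = np.array([spec.indications[k] for k in inds])
            indication[mask] = rng_struct.choice(inds, size=n_i, p=probs / probs.sum())

    u = rng_struct.random(n_cases)
    p_unknown = scenario.unknown_sex_rate
    p_female = (1.0 - p_unknown) * scenario.sex_mix
    sex = np.where(u < p_unknown, "unknown", np.where(u < p_unknown + p_female, "F", "M")).astype(object)

    age_band = rng_struct.choice(_AGE_BANDS[0], size=n_cases, p=_AGE_BANDS[1])
    weight_band = rng_struct.choice(_WEIGHT_BANDS[0], size=n_cases, p=_WEIGHT_BANDS[1])
    country = rng_struct.choice(_COUNTRIES[0], size=n_cases, p=_COUNTRIES[1])
    reporter = rng_struct.choice(_REPORTERS[0], size=n_cases, p=_REPORTERS[1])
    quarter = rng_struct.choice(_QUARTERS, size=n_cases)

    caseid = np.arange(1, n_cases + 1)
    primaryid = caseid * 10 + 1

    # -- events ----------------------------------------------------------
    pts = sorted(scenario.event_catalog)
    reac_pid, reac_pt = [], []
    any_event = np.zeros(n_cases, dtype=bool)
    for pt in pts:
        p_vec = np.full(n_cases, scenario.event_catalog[pt])
        for sig, members, rho in planted:
            if pt not in members:
                continue
            mask = (drug_name == sig.drug) | (drug_class == sig.drug)
            if sig.indication is not None:
                mask &= indication == sig.indication
            if sig.sex is not None:
                mask &= sex == sig.sex
            q = p_vec[mask] / (1.0 - p_vec[mask])
            p_vec[mask] = rho * q / (1.0 + rho * q)
        hit = rng_events.random(n_cases) < p_vec
        any_event |= hit
        idx = np.nonzero(hit)[0]
        reac_pid.append(primaryid[idx])
        reac_pt.append(np.full(idx.size, pt, dtype=object))
    empty = np.nonzero(~any_event)[0]
    if empty.size:
        reac_pid.append(primaryid[empty])
        reac_pt.append(np.full(empty.size, scenario.filler_pt, dtype=object))
    reac = pd.DataFrame({"primaryid": np.concatenate(reac_pid), "pt": np.concatenate(reac_pt)})

    # -- drug table (PS drug plus optional concomitant) -------------------
    drug_tables = [
        pd.DataFrame(
            {
                "primaryid": primaryid,
                "drugname": drug_name,
                "role_cod": "PS",
                "drug_class": drug_class,
            }
        )
    ]
    conc_mask = rng_struct.random(n_cases) < scenario.concomitant_rate
    n_conc = int(conc_mask.sum())
    if n_conc:
        conc_idx = rng_struct.choice(len(drugs), size=n_conc)
        drug_tables.append(
            pd.DataFrame(
                {
                    "primaryid": primaryid[conc_mask],
                    "drugname": np.array(scenario.drug_names, dtype=object)[conc_idx],
                    "role_cod": "C",
                    "drug_class": np.array([d.drug_class for d in drugs], dtype=object)[conc_idx],
                }
            )
        )
    drug = pd.concat(drug_tables, ignore_index=True)

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "caseversion": 1,
            "sex": sex,
            "age_band": age_band,
            "weight_band": weight_band,
            "reporter_type": reporter,
            "country": country,
            "quarter": quarter,
        }
    )
    indi = pd.DataFrame({"primaryid": primaryid, "indi_pt": indication})

    # -- duplicate case versions ------------------------------------------
    if n_dup:
        dup_cases = np.sort(rng_dup.choice(caseid, size=n_dup, replace=False))
        dup_pid_old = dup_cases * 10 + 1
        dup_pid_new = dup_cases * 10 + 2
        remap = dict(zip(dup_pid_old, dup_pid_new))

        demo_dup = demo[demo["caseid"].isin(set(dup_cases))].copy()
        demo_dup["caseversion"] = 2
        demo_dup["primaryid"] = demo_dup["primaryid"].map(remap)
        demo = pd.concat([demo, demo_dup], ignore_index=True)

        for name, table in (("drug", drug), ("reac", reac), ("indi", indi)):
            extra = table[table["primaryid"].isin(remap)].copy()
            extra["primaryid"] = extra["primaryid"].map(remap)
            if name == "drug":
                drug = pd.concat([drug, extra], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, extra], ignore_index=True)
            else:
                indi = pd.concat([indi, extra], ignore_index=True)

    demo = demo.sort_values("primaryid").reset_index(drop=True)
    drug = drug.sort_values("primaryid", kind="stable").reset_index(drop=True)
    reac = reac.sort_values("primaryid", kind="stable").reset_index(drop=True)
    indi = indi.sort_values("primaryid", kind="stable").reset_index(drop=True)
    return ReportDatabase(demo=demo, drug=drug, reac=reac, indi=indi)
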