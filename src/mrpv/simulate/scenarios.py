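"""Scenario definitions for the synthetic-data generators.

A :class:`PVScenario` specifies a toy spontaneous-report database with known
ground truth: a drug catalog with indication profiles, an event catalog with
baseline per-report probabilities, planted reporting odds ratios (per PT or
per SMQ, optionally restricted to an indication or sex stratum), the sex
mix, and the duplicate-version rate.

A :class:`GeneticScenario` specifies cis-region summary statistics with a
known causal structure: LD pattern, true eQTL effects, the causal effect of
expression on the outcome, pleiotropic direct effects, an optional mediator
chain, reverse-causal variants, and the allele/strand bookkeeping knobs used
to exercise harmonization.

The preset constructors at the bottom are the study conditions used by the
validation suite; their parameter choices are documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DrugSpec",
    "PlantedSignal",
    "PVScenario",
    "MediationSpec",
    "GeneticScenario",
    "independent_cis_scenario",
    "glp1r_like_scenario",
    "cis_region_scenario",
    "reverse_scenario",
    "outlier_scenario",
    "mediation_scenario",
    "pv_null_scenario",
    "pv_planted_smq_scenario",
    "headline_pv_scenario",
]

# eQTLGen-scale blood eQTL sample size and a FinnGen-scale GWAS size.
N_EQTL_DEFAULT = 31684
N_GWAS_DEFAULT = 500_000


@dataclass
class DrugSpec:
    """One catalog drug: name, therapeutic class, and indication profile."""

    name: str
    drug_class: str
    indications: dict[str, float]

    def __post_init__(self) -> None:
        if not self.indications:
            raise ValueError(f"drug {self.name!r} must have at least one indication")
        total = sum(self.indications.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"drug {self.name!r}: indication probabilities must sum to 1")


@dataclass
class PlantedSignal:
    """A true reporting odds ratio planted for (drug-or-class, PT-or-SMQ).

    ``event`` names either a catalog PT or an SMQ of the scenario hierarchy
    (narrow scope).  If ``indication`` or ``sex`` is set, the elevated odds
    apply only to reports in that stratum, so the within-stratum 2x2 table
    reproduces ``ror`` while the pooled table is diluted.
    """

    drug: str
    event: str
    ror: float
    indication: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.ror <= 0:
            raise ValueError("planted reporting odds ratios must be positive")


@dataclass
class PVScenario:
    n_reports: int
    drug_catalog: list[DrugSpec]
    event_catalog: dict[str, float]
    hierarchy: object | None = None  # TermHierarchy; needed for SMQ planting
    planted: list[PlantedSignal] = field(default_factory=list)
    sex_mix: float = 0.656  # proportion female among sex-known reports
    duplicate_rate: float = 0.1
    concomitant_rate: float = 0.2
    unknown_sex_rate: float = 0.02
    drug_weights: Sequence[float] | None = None
    filler_pt: str = "PT_unspecified"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        if not 0 <= self.sex_mix <= 1:
            raise ValueError("sex_mix must lie in [0, 1]")
        if not 0 <= self.duplicate_rate <= 0.5:
            raise ValueError(
                "duplicate_rate must lie in [0, 0.5]: every duplicated case has "
                "exactly two versions, so at most half of all records are duplicates"
            )
        for pt, p in self.event_catalog.items():
            if not 0 < p < 1:
                raise ValueError(f"baseline probability for {pt!r} must lie in (0, 1)")
        if isinstance(self.planted, Mapping):  # convenience: {(drug, event): ror}
            self.planted = [PlantedSignal(d, e, r) for (d, e), r in self.planted.items()]

    @property
    def drug_names(self) -> list[str]:
        return [d.name for d in self.drug_catalog]

    @property
    def classes(self) -> dict[str, str]:
        return {d.name: d.drug_class for d in self.drug_catalog}


@dataclass
class MediationSpec:
    """Exposure -> mediator -> outcome chain configuration.

    ``beta_xm`` is the effect of one SD of target-gene expression on the
    mediator (SD units), ``beta_my`` the mediator's effect on the outcome
    (log odds per SD) and ``theta_direct`` the residual direct effect, so the
    total effect is ``theta_direct + beta_xm * beta_my``.  The mediator also
    has ``n_mediator_snps`` genome-wide instruments of its own, independent
    of the cis region.
    """

    beta_xm: float
    beta_my: float
    theta_direct: float
    n_mediator_snps: int = 30
    b_med: float | Sequence[float] | None = None  # None -> drawn +/- U(0.025, 0.06)
    n_mediator: int = N_GWAS_DEFAULT

    @property
    def indirect(self) -> float:
        return self.beta_xm * self.beta_my

    @property
    def total(self) -> float:
        return self.theta_direct + self.indirect

    @property
    def proportion(self) -> float:
        return self.indirect / self.total


@dataclass
class GeneticScenario:
    n_snps: int = 22
    #: "identity", ("ar1", rho), ("blocks", block_size, rho), or an explicit matrix
    ld: object = "identity"
    causal_idx: Sequence[int] | None = None
    b_expr: float | Sequence[float] | None = None  # None -> drawn +/- U(0.15, 0.45)
    theta: float = 0.0  # causal effect of expression on outcome, log odds per SD
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    direct_effects: Mapping[int, float] | None = None  # explicit per-SNP outcome effects
    mediation: MediationSpec | None = None
    mode: str = "causal"  # causal | null | linkage | reverse
    n_reverse: int = 0
    reverse_b_exp: float = 0.085
    reverse_b_out: float = 0.15
    linkage_offset: int = 2  # AR-1 steps between the two linkage causal variants
    linkage_b_out: float = 0.1
    n_eqtl: int = N_EQTL_DEFAULT
    n_gwas: int = N_GWAS_DEFAULT
    maf: float | Sequence[float] | None = None  # None -> drawn U(0.1, 0.4)
    palindromic_fraction: float = 0.1
    swap_fraction: float = 0.25
    strand_flip_fraction: float = 0.1
    eaf_noise: bool = True
    anchor: tuple[str, int] = ("6", 39_016_574)  # cis-region chromosome and midpoint
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("causal", "null", "linkage", "reverse"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "null":
            self.theta = 0.0
        if self.mode == "reverse" and self.n_reverse < 1:
            self.n_reverse = 8
        if self.causal_idx is None:
            if self.ld == "identity":
                self.causal_idx = list(range(self.n_snps))
            elif isinstance(self.ld, tuple) and self.ld[0] == "blocks":
                self.causal_idx = list(range(0, self.n_snps, self.ld[1]))
            else:
                self.causal_idx = [self.n_snps // 2]
        self.causal_idx = list(self.causal_idx)
        if any(i < 0 or i >= self.n_snps for i in self.causal_idx):
            raise ValueError("causal_idx out of range")
        if self.mode == "linkage":
            if self.linkage_offset < 1:
                raise ValueError("linkage mode needs two distinct causal variants")
            # pure-linkage confound: expression has no causal effect on outcome
            self.theta = 0.0
        if not 0 <= self.pleio_frac <= 1:
            raise ValueError("pleio_frac must lie in [0, 1]")

    def with_seed(self, seed: int) -> "GeneticScenario":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# genetic presets
# ---------------------------------------------------------------------------


def independent_cis_scenario(theta: float = 0.0, n_snps: int = 22, seed: int = 0, **overrides):
    """22 strong, mutually independent cis instruments.

    This is the summary-level regime of a drug-target MR with a fully clumped
    instrument set: per-allele expression effects of 0.15-0.45 SD at an
    eQTL sample size of ~32k give instrument F statistics comfortably above
    the weak-instrument threshold, matching a study whose instruments all
    have F > 47.
    """
    base = dict(
        n_snps=n_snps,
        ld="identity",
        causal_idx=list(range(n_snps)),
        theta=theta,
        seed=seed,
    )
    base.update(overrides)
    return GeneticScenario(**base)


def glp1r_like_scenario(theta: float = 0.0, seed: int = 0, **overrides):
    """A cis region with 22 independent signals embedded in LD blocks.

    22 blocks of 5 variants (AR-1 correlation 0.6 within a block, independence
    across blocks); the first variant of each block is the true eQTL.  Greedy
    clumping at r^2 < 0.01 should recover exactly the 22 block leaders.
    Palindromic variants are excluded from this preset: it emulates an
    instrument set in which every selected SNP survived harmonization.
    """
    block = 5
    n = 22 * block
    base = dict(
        n_snps=n,
        ld=("blocks", block, 0.6),
        causal_idx=[i * block for i in range(22)],
        theta=theta,
        palindromic_fraction=0.0,
        seed=seed,
    )
    base.update(overrides)
    return GeneticScenario(**base)


def cis_region_scenario(
    mode: str = "causal",
    theta: float = math.log(0.79),
    seed: int = 0,
    **overrides,
):
    """A dense cis region for SMR/HEIDI: 61 variants, AR-1 LD (rho = 0.85).

    ``mode="causal"``: a single causal variant in the middle drives both
    expression and (through expression) the outcome -- the single-shared-
    causal-variant configuration HEIDI should not reject.
    ``mode="linkage"``: a second variant two AR-1 steps away (r^2 ~ 0.52)
    affects the outcome only, with a marginal effect large enough to reach
    genome-wide significance -- the configuration HEIDI should reject.
    ``mode="null"``: expression effects only.
    """
    n = 61
    centre = n // 2
    base = dict(
        n_snps=n,
        ld=("ar1", 0.85),
        causal_idx=[centre],
        b_expr=0.35,
        theta=theta,
        mode=mode,
        linkage_offset=2,
        linkage_b_out=0.1,
        n_gwas=480_289,  # anxiety-endpoint scale: 35,875 cases / 444,414 controls
        seed=seed,
    )
    base.update(overrides)
    return GeneticScenario(**base)


def reverse_scenario(theta: float = math.log(0.9), seed: int = 0, **overrides):
    """22 valid instruments plus 8 reverse-causal variants.

    The reverse variants are strong outcome loci (|log OR| = 0.15, z ~ 50-70
    at n = 5e5) that leak a weak association into the expression statistics
    (0.085 SD, z ~ 6-10) -- enough to pass the p < 5e-8 instrument screen but
    with more variance explained in the outcome than in the exposure, which
    is exactly what Steiger filtering must catch.
    """
    base = dict(mode="reverse", theta=theta, n_reverse=8, seed=seed)
    base.update(overrides)
    return independent_cis_scenario(**base)


def outlier_scenario(theta: float = math.log(0.9), seed: int = 0, outlier_z: float = 5.0, **overrides):
    """22 independent instruments, one carrying a direct (pleiotropic) outcome
    effect of ``outlier_z`` times that SNP's outcome standard error."""
    maf = 0.25
    n_gwas = N_GWAS_DEFAULT
    se_out = 1.0 / math.sqrt(2 * maf * (1 - maf) * n_gwas)
    base = dict(
        theta=theta,
        maf=maf,
        n_gwas=n_gwas,
        direct_effects={0: outlier_z * se_out},
        seed=seed,
    )
    base.update(overrides)
    return independent_cis_scenario(**base)


def mediation_scenario(
    proportion: float = 0.18,
    total: float = math.log(0.915),
    beta_xm: float = -0.25,
    seed: int = 0,
    **overrides,
):
    """Exposure -> mediator -> outcome chain with a planted proportion mediated.

    Defaults mirror a weight-loss mediation regime: total effect ln(0.915)
    on the outcome, of which 18% flows through the mediator.  ``beta_my`` and
    ``theta_direct`` are derived so that
    ``beta_xm * beta_my = proportion * total``.
    """
    indirect = proportion * total
    spec = MediationSpec(
        beta_xm=beta_xm,
        beta_my=indirect / beta_xm,
        theta_direct=total - indirect,
    )
    base = dict(mediation=spec, seed=seed)
    base.update(overrides)
    return independent_cis_scenario(**base)


# ---------------------------------------------------------------------------
# pharmacovigilance presets
# ---------------------------------------------------------------------------


def _psych_hierarchy():
    """Hierarchy with a dedicated psychiatric SOC carrying mood-disorder SMQs,
    plus background organ classes and a general-disorders chain for the
    filler PT."""
    from ..hierarchy import generate_term_hierarchy

    h = generate_term_hierarchy(n_soc=8, fanout=(2, 1, 2), seed=0)
    soc = "SOC_psych"
    pts = {}
    for concept, terms in {
        "suicide": ["suicidal_ideation", "suicide_attempt", "completed_suicide", "self_harm"],
        "depression": ["depressed_mood", "major_depression", "anhedonia"],
        "anxiety": ["anxiety", "nervousness", "panic_attack"],
        "mood": ["mood_swings", "emotional_distress", "irritability"],
    }.items():
        hlgt = f"{soc}.{concept}"
        hlt = f"{hlgt}.T1"
        for pt in terms:
            h.add_chain(pt, hlt, hlgt, soc)
            pts.setdefault(concept, []).append(pt)
    h.add_chain("PT_unspecified", "HLT_general", "HLGT_general", "SOC_general")
    h.add_smq("suicide_self_harm", narrow=pts["suicide"][:3], broad=pts["suicide"])
    h.add_smq("depression", narrow=pts["depression"][:2], broad=pts["depression"])
    h.add_smq("anxiety", narrow=pts["anxiety"][:2], broad=pts["anxiety"])
    h.add_smq("mood_disorders", narrow=pts["mood"][:2], broad=pts["mood"])
    return h


_GLP1_DRUGS = [
    "semaglutide",
    "liraglutide",
    "exenatide",
    "dulaglutide",
    "albiglutide",
    "lixisenatide",
    "tirzepatide",
]


def _default_catalog():
    gl = {"glucose_lowering": 0.6, "weight_loss": 0.35, "other": 0.05}
    diab = {"glucose_lowering": 0.9, "other": 0.1}
    wl = {"weight_loss": 0.9, "other": 0.1}
    other = {"other": 1.0}
    catalog = [DrugSpec(name, "glp1_ra", gl) for name in _GLP1_DRUGS]
    catalog += [
        DrugSpec("sitagliptin", "dpp4", diab),
        DrugSpec("empagliflozin", "sglt2", diab),
        DrugSpec("metformin", "biguanide", diab),
        DrugSpec("glimepiride", "sulfonylurea", diab),
        DrugSpec("orlistat", "lipase_inhibitor", wl),
        DrugSpec("phentermine", "sympathomimetic", wl),
        DrugSpec("venlafaxine", "snri", other),
        DrugSpec("levofloxacin", "quinolone", other),
    ]
    return catalog


def _default_events(hierarchy) -> dict[str, float]:
    """Baseline per-report probabilities for the psychiatric PTs plus a thin
    layer of background events from the mock organ classes."""
    events = {}
    psych = sorted(
        pt for pt in hierarchy.pts() if hierarchy.rollup(pt, "SOC") == "SOC_psych"
    )
    for i, pt in enumerate(psych):
        events[pt] = 0.002 + 0.001 * (i % 4)
    background = sorted(
        pt
        for pt in hierarchy.pts()
        if hierarchy.rollup(pt, "SOC") not in ("SOC_psych", "SOC_general")
    )
    for i, pt in enumerate(background):
        events[pt] = 0.01 + 0.005 * (i % 5)
    return events


def headline_pv_scenario(seed: int = 1, n_reports: int = 200_000, suicide_ror: float = 1.65):
    """The full study database: GLP-1-class drugs, comparator classes,
    positive-control drugs, and a suicide-related reporting signal planted
    only in the weight-loss indication stratum."""
    h = _psych_hierarchy()
    planted = [
        PlantedSignal("glp1_ra", "suicide_self_harm", suicide_ror, indication="weight_loss"),
        PlantedSignal("venlafaxine", "suicide_self_harm", 7.32),
        PlantedSignal("venlafaxine", "mood_disorders", 3.39),
        PlantedSignal("levofloxacin", "anxiety", 1.56),
        PlantedSignal("levofloxacin", "depression", 1.51),
    ]
    return PVScenario(
        n_reports=n_reports,
        drug_catalog=_default_catalog(),
        event_catalog=_default_events(h),
        hierarchy=h,
        planted=planted,
        seed=seed,
    )


def pv_planted_smq_scenario(ror: float = 5.0, seed: int = 1, n_reports: int = 200_000):
    """Single planted SMQ-level signal for the target class, no stratum
    restriction: the positive-recovery condition of the screening test."""
    h = _psych_hierarchy()
    return PVScenario(
        n_reports=n_reports,
        drug_catalog=_default_catalog(),
        event_catalog=_default_events(h),
        hierarchy=h,
        planted=[PlantedSignal("glp1_ra", "suicide_self_harm", ror)],
        seed=seed,
    )


def pv_null_scenario(seed: int = 0, n_reports: int = 20_000, n_soc: int = 27):
    """No planted effects; 27 organ classes for type-I-error screening."""
    from ..hierarchy import generate_term_hierarchy

    h = generate_term_hierarchy(n_soc=n_soc, fanout=(1, 1, 2), seed=0)
    h.add_chain("PT_unspecified", "HLT_general", "HLGT_general", "SOC_general")
    events = {pt: 0.008 + 0.004 * (i % 4) for i, pt in enumerate(sorted(h.pts() - {"PT_unspecified"}))}
    return PVScenario(
        n_reports=n_reports,
        drug_catalog=_default_catalog(),
        event_catalog=events,
        hierarchy=h,
        planted=[],
        seed=seed,
    )
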