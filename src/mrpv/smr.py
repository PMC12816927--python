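"""Summary-data-based MR (SMR) and the HEIDI linkage test.

SMR tests whether a trait is associated with gene expression through the
single top cis-eQTL: with z_e and z_g the eQTL and GWAS z-statistics at the
top SNP, the effect is b_smr = b_gwas / b_eqtl and the test statistic is

    T_SMR = z_g^2 z_e^2 / (z_g^2 + z_e^2)  ~  chi^2_1 under the null,

with se_smr = |b_smr| / sqrt(T_SMR).  In the strong-instrument limit
(z_e -> infinity) this reduces to the Wald-ratio test.

A significant SMR association can reflect a single shared causal variant
(causality or vertical pleiotropy) or two distinct causal variants in LD
(linkage).  The HEIDI test distinguishes these: if one variant drives both
traits, b_smr is the same at every SNP in LD with it, so the differences
d_i = b_smr(i) - b_smr(top) across linked SNPs should be jointly zero.
T_HEIDI = sum z_{d,i}^2 is referred to its null distribution -- a weighted
sum of chi^2_1 variables with weights the eigenvalues of the correlation
matrix of the z_d (which are correlated through LD) -- evaluated here by
seeded Monte Carlo.  A small HEIDI p (< 0.01 by convention) flags linkage.

SNP selection for HEIDI follows the published SMR-tool defaults: up to 20
SNPs with eQTL p < 1.57e-3 (z > 3.16) and r^2 with the top SNP inside
[0.05, 0.9]; fewer than 3 qualifying SNPs makes the test not applicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InstrumentSelectionError
from .instruments import harmonize
from .sumstats import LDMatrix, SummaryStats

__all__ = ["SMRResult", "HeidiResult", "smr_test", "heidi_test", "smr_analysis"]


@dataclass
class HeidiResult:
    p: float | None
    n_snps: int
    t_stat: float | None = None


@dataclass
class SMRResult:
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    t_smr: float
    heidi_p: float | None = None
    n_heidi_snps: int = 0
    verdict: str = "not-testable"
    n_snps_tested: int = 0

    @property
    def or_(self) -> float:
        return float(np.exp(self.b_smr))

    @property
    def or_ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.b_smr - 1.96 * self.se_smr)),
            float(np.exp(self.b_smr + 1.96 * self.se_smr)),
        )

    def summary(self) -> str:
        lo, hi = self.or_ci
        heidi = "n/a" if self.heidi_p is None else f"{self.heidi_p:.4f}"
        return (
            f"SMR at {self.top_snp}: OR={self.or_:.3f} [{lo:.3f}, {hi:.3f}], "
            f"p_SMR={self.p_smr:.3g}; HEIDI p={heidi} "
            f"({self.n_heidi_snps} SNPs) -> {self.verdict}"
        )


def _qualifying(eqtl: SummaryStats, gwas: SummaryStats, p_max: float, maf_min: float):
    """Harmonized eQTL/GWAS records passing the eQTL significance and MAF
    filters, with the eQTL p-value attached."""
    h = harmonize(eqtl, gwas)
    t = h.kept.copy()
    p_eqtl = 2.0 * stats.norm.sf(np.abs(t["b_exp"] / t["se_exp"]))
    t["p_eqtl"] = p_eqtl
    maf = np.minimum(t["eaf_exp"], 1 - t["eaf_exp"])
    return t[(t["p_eqtl"] < p_max) & (maf > maf_min)]


def smr_test(
    eqtl: SummaryStats,
    gwas: SummaryStats,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
) -> SMRResult:
    """SMR chi-square test at the top cis-eQTL (HEIDI not yet attached)."""
    t = _qualifying(eqtl, gwas, p_max, maf_min)
    if len(t) == 0:
        raise InstrumentSelectionError(
            "no eQTL variant passes the SMR significance and MAF filters",
            {"harmonized": 0},
        )
    top = t.loc[t["p_eqtl"].idxmin()]
    z_e = top["b_exp"] / top["se_exp"]
    z_g = top["b_out"] / top["se_out"]
    t_smr = float(z_g**2 * z_e**2 / (z_g**2 + z_e**2))
    p_smr = float(stats.chi2.sf(t_smr, 1))
    b_smr = float(top["b_out"] / top["b_exp"])
    se_smr = float(abs(b_smr) / np.sqrt(t_smr)) if t_smr > 0 else float("inf")
    return SMRResult(
        top_snp=str(top["snp"]),
        b_smr=b_smr,
        se_smr=se_smr,
        p_smr=p_smr,
        t_smr=t_smr,
        n_snps_tested=int(len(t)),
    )


def heidi_test(
    eqtl: SummaryStats,
    gwas: SummaryStats,
    ld: LDMatrix,
    top_snp: str,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
    min_snps: int = 3,
    p_eqtl_max: float = 1.57e-3,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> HeidiResult:
    """HEIDI heterogeneity test around ``top_snp``.

    Returns p=None (not testable) when fewer than ``min_snps`` SNPs qualify.
    The Monte-Carlo evaluation of the weighted-chi-square null is
    bit-reproducible for a fixed seed.
    """
    t = _qualifying(eqtl, gwas, p_eqtl_max, 0.0)
    t = t[t["snp"].isin(ld.snps)]
    if top_snp not in set(t["snp"]):
        return HeidiResult(p=None, n_snps=0)
    top = t[t["snp"] == top_snp].iloc[0]
    rest = t[t["snp"] != top_snp]
    r_to_top = np.array([ld.r[ld.index(s), ld.index(top_snp)] for s in rest["snp"]])
    lo, hi = r2_window
    rest = rest[(r_to_top**2 >= lo) & (r_to_top**2 <= hi)]
    rest = rest.sort_values("p_eqtl").head(max_snps)
    m = len(rest)
    if m < min_snps:
        return HeidiResult(p=None, n_snps=m)

    snps = [top_snp] + rest["snp"].tolist()
    sub = ld.submatrix(snps).r
    be = np.concatenate([[top["b_exp"]], rest["b_exp"].to_numpy(float)])
    se_e = np.concatenate([[top["se_exp"]], rest["se_exp"].to_numpy(float)])
    bg = np.concatenate([[top["b_out"]], rest["b_out"].to_numpy(float)])
    se_g = np.concatenate([[top["se_out"]], rest["se_out"].to_numpy(float)])
    bs = bg / be

    # first-order covariance of the per-SNP SMR ratios: the GWAS and eQTL
    # cohorts are independent, but SNPs within each are correlated through LD
    cov_bs = sub * (np.outer(se_g, se_g) + np.outer(bs, bs) * np.outer(se_e, se_e)) / np.outer(
        be, be
    )
    d = bs[1:] - bs[0]
    cov_d = cov_bs[1:, 1:] - cov_bs[1:, [0]] - cov_bs[[0], 1:] + cov_bs[0, 0]
    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    t_heidi = float(np.sum(z_d**2))
    corr = cov_d / np.outer(sd, sd)
    lam = np.clip(np.linalg.eigvalsh((corr + corr.T) / 2), 0.0, None)

    rng = np.random.default_rng(seed)
    draws = (rng.standard_normal((mc_draws, m)) ** 2) @ lam
    p = float((1 + np.sum(draws >= t_heidi)) / (mc_draws + 1))
    return HeidiResult(p=p, n_snps=m, t_stat=t_heidi)


def smr_analysis(
    eqtl: SummaryStats,
    gwas: SummaryStats,
    ld: LDMatrix,
    seed: int = 0,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    heidi_alpha: float = 0.01,
    **heidi_kwargs,
) -> SMRResult:
    """SMR test at the top cis-eQTL followed by HEIDI, with a verdict:
    ``pass`` (consistent with one shared causal variant),
    ``linkage-suspected`` (HEIDI p below ``heidi_alpha``), or
    ``not-testable`` (too few SNPs for HEIDI)."""
    result = smr_test(eqtl, gwas, p_max=p_max, maf_min=maf_min)
    heidi = heidi_test(eqtl, gwas, ld, result.top_snp, seed=seed, **heidi_kwargs)
    result.heidi_p = heidi.p
    result.n_heidi_snps = heidi.n_snps
    if heidi.p is None:
        result.verdict = "not-testable"
    elif heidi.p < heidi_alpha:
        result.verdict = "linkage-suspected"
    else:
        result.verdict = "pass"
    return result
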