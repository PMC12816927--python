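"""Two-step mediation MR with the product-of-coefficients (delta-method) test.

The total effect of the exposure on the outcome (estimated with the cis
instruments) is decomposed into an indirect, mediator-borne component and a
direct remainder.  Step 1 estimates the exposure -> mediator effect beta_1
with the cis instruments; step 2 estimates the mediator -> outcome effect
beta_2 with the mediator's own genome-wide instruments.  The indirect
effect is the product beta_1 * beta_2 with Sobel/delta SE

    se_ind = sqrt(beta_1^2 se_2^2 + beta_2^2 se_1^2)

(zero covariance across non-overlapping samples), and the proportion
mediated is indirect / total with first-order delta SE.  Mediation is only
computed when both steps are nominally significant (p < 0.05): without a
causal chain through the mediator there is nothing to attribute, and no
numbers are fabricated.

Step 2 is a univariable fit, not adjusted for the exposure; under a nonzero
direct exposure -> outcome path this can bias beta_2 when the mediator
instruments overlap the exposure's locus, which is why the pipeline
excludes the exposure's cis window from the mediator instrument set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import harmonize, select_instruments, steiger_filter
from .mr import MREstimate, MRAnalysis, ivw
from .sumstats import LDMatrix, SummaryStats

__all__ = ["MediationResult", "mediate", "run_mediation_pipeline"]


@dataclass
class MediationResult:
    total: MREstimate
    step1: MREstimate | None
    step2: MREstimate | None
    indirect_beta: float | None = None
    indirect_se: float | None = None
    indirect_p: float | None = None
    proportion: float | None = None
    proportion_se: float | None = None
    proportion_ci_low: float | None = None
    proportion_ci_high: float | None = None
    proportion_p: float | None = None
    gate_passed: bool = False
    note: str = ""
    sensitivity: dict | None = None

    def summary(self) -> str:
        lines = [f"Total effect: {self.total}"]
        if self.step1 is not None:
            lines.append(f"Step 1 (exposure -> mediator): {self.step1}")
        if self.step2 is not None:
            lines.append(f"Step 2 (mediator -> outcome): {self.step2}")
        if not self.gate_passed:
            lines.append(f"Mediation not established: {self.note}")
        else:
            lines.append(
                f"Indirect effect = {self.indirect_beta:.4f} (se {self.indirect_se:.4f}), "
                f"p = {self.indirect_p:.3g}"
            )
            if self.proportion is None:
                lines.append("Proportion mediated undefined (zero total effect)")
            else:
                lines.append(
                    f"Proportion mediated = {100 * self.proportion:.2f}% "
                    f"(95% CI {100 * self.proportion_ci_low:.2f}% to "
                    f"{100 * self.proportion_ci_high:.2f}%), p = {self.proportion_p:.3g}"
                )
        return "\n".join(lines)


def mediate(
    x_to_y: MREstimate,
    x_to_m: MREstimate,
    m_to_y: MREstimate,
    gate_alpha: float = 0.05,
) -> MediationResult:
    """Product-of-coefficients mediation from three MR estimates.

    ``x_to_y`` is the total effect, ``x_to_m`` step 1 and ``m_to_y`` step 2.
    """
    for est in (x_to_y, x_to_m, m_to_y):
        if not np.isfinite(est.beta) or not np.isfinite(est.se):
            raise ValueError("all three estimates must be finite")
    result = MediationResult(total=x_to_y, step1=x_to_m, step2=m_to_y)
    if x_to_m.p >= gate_alpha or m_to_y.p >= gate_alpha:
        result.note = (
            f"two-step gate failed (step1 p={x_to_m.p:.3g}, step2 p={m_to_y.p:.3g}); "
            "no causal chain through the mediator"
        )
        return result
    result.gate_passed = True
    b1, s1 = x_to_m.beta, x_to_m.se
    b2, s2 = m_to_y.beta, m_to_y.se
    bt, st = x_to_y.beta, x_to_y.se
    indirect = b1 * b2
    se_ind = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2))
    result.indirect_beta = float(indirect)
    result.indirect_se = se_ind
    result.indirect_p = float(2 * stats.norm.sf(abs(indirect / se_ind))) if se_ind > 0 else 1.0
    if bt == 0:
        result.note = "total effect is zero; proportion mediated undefined"
        return result
    prop = indirect / bt
    se_prop = float(np.sqrt(se_ind**2 / bt**2 + indirect**2 * st**2 / bt**4))
    result.proportion = float(prop)
    result.proportion_se = se_prop
    result.proportion_ci_low = float(prop - 1.96 * se_prop)
    result.proportion_ci_high = float(prop + 1.96 * se_prop)
    result.proportion_p = float(2 * stats.norm.sf(abs(prop / se_prop))) if se_prop > 0 else 1.0
    return result


def _exclude_cis_window(stats_: SummaryStats, chrom: str, centre: int, window: float) -> SummaryStats:
    t = stats_.table
    in_cis = (t["chr"].astype(str) == str(chrom)) & ((t["pos"] - centre).abs() <= window)
    return stats_.subset(t.loc[~in_cis, "snp"])


def run_mediation_pipeline(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    cis_window: float = 1e6,
    gate_alpha: float = 0.05,
    steiger: bool = True,
    select_kwargs: dict | None = None,
) -> MediationResult:
    """Full two-step mediation analysis from summary statistics.

    The total (X->Y) and step-1 (X->M) effects use the cis instruments; the
    step-2 (M->Y) effect uses the mediator's own instruments selected from
    its genome-wide statistics, excluding the exposure's cis window (+-1 Mb
    around the strongest cis instrument) to keep the mediator instruments
    free of direct exposure effects.  All three fits are IVW with the
    heterogeneity / pleiotropy sensitivity reports attached.
    """
    select_kwargs = select_kwargs or {}
    x_ivs = select_instruments(exposure, ld, **select_kwargs)
    top = x_ivs.table.loc[x_ivs.table["p"].idxmin()]

    def fit(ivs: SummaryStats, target: SummaryStats):
        h = harmonize(ivs, target)
        if steiger:
            h = steiger_filter(h)
        res = MRAnalysis(h).fit(loo=False)
        return res

    total_fit = fit(x_ivs, outcome)
    step1_fit = fit(x_ivs, mediator)
    mediator_gw = _exclude_cis_window(mediator, top["chr"], int(top["pos"]), cis_window)
    m_ivs = select_instruments(mediator_gw, ld, **select_kwargs)
    step2_fit = fit(m_ivs, outcome)

    result = mediate(total_fit.ivw, step1_fit.ivw, step2_fit.ivw, gate_alpha=gate_alpha)
    result.sensitivity = {
        "total": total_fit.sensitivity,
        "step1": step1_fit.sensitivity,
        "step2": step2_fit.sensitivity,
    }
    return result
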