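"""Two-sample Mendelian randomization estimators and sensitivity analyses.

Per-SNP causal estimates are Wald ratios r_j = b_out,j / b_exp,j with
first-order SE |se_out,j / b_exp,j|.  The primary estimator is the
inverse-variance-weighted (IVW) average with weights w_j = (b_exp,j /
se_out,j)^2, equivalent to a weighted zero-intercept regression of the
outcome betas on the exposure betas; by default the SE is inflated by
sqrt(Q / (k-1)) when Cochran's Q exceeds its degrees of freedom
(multiplicative random effects).  MR-Egger adds a free intercept whose
deviation from zero indicates directional horizontal pleiotropy (t-test,
k-2 df).  MR-PRESSO is the parametric-simulation global heterogeneity test
with per-SNP outlier detection and an outlier-removed corrected estimate.
Leave-one-out fits flag influential single instruments.

Estimates for binary outcomes are log odds ratios; ``MREstimate.or_``
and the CI properties report them on the OR scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedInstrumentSet

__all__ = [
    "MREstimate",
    "EggerIntercept",
    "PressoResult",
    "SensitivityReport",
    "wald_ratio",
    "ivw",
    "egger",
    "cochran_q",
    "mr_presso",
    "leave_one_out",
    "MRAnalysis",
    "MRResults",
]


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds (or SD-unit) scale."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    dist: str = "norm"  # "norm" or "t"
    df: int | None = None

    def _crit(self, alpha: float = 0.05) -> float:
        if self.dist == "t":
            return float(stats.t.ppf(1 - alpha / 2, self.df))
        return float(stats.norm.ppf(1 - alpha / 2))

    @property
    def ci_low(self) -> float:
        return self.beta - self._crit() * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + self._crit() * self.se

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.or_ci
        return (
            f"{self.method}: beta={self.beta:.4f} (se {self.se:.4f}), "
            f"OR={self.or_:.3f} [{lo:.3f}, {hi:.3f}], p={self.p:.3g}, k={self.n_snps}"
        )


def _p_value(z: float, dist: str = "norm", df: int | None = None) -> float:
    if dist == "t":
        p = float(2.0 * stats.t.sf(abs(z), df))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return max(p, 5e-324)  # keep p strictly positive under extreme z


def _arrays(hset) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(hset, HarmonizedInstrumentSet):
        return hset.arrays()
    b_exp, se_exp, b_out, se_out = (np.asarray(a, float) for a in hset)
    return b_exp, se_exp, b_out, se_out


def wald_ratio(b_exp: float, se_exp: float, b_out: float, se_out: float) -> MREstimate:
    """Single-SNP ratio estimate with first-order (outcome-only) SE."""
    if b_exp == 0:
        raise ValueError("Wald ratio undefined for a zero exposure effect")
    beta = b_out / b_exp
    se = abs(se_out / b_exp)
    return MREstimate(
        method="wald_ratio", beta=float(beta), se=float(se),
        p=_p_value(beta / se), n_snps=1,
    )


def ivw(hset, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate over the retained instruments.

    With ``random_effects`` (default) the fixed-effect SE is multiplied by
    sqrt(Q/(k-1)) whenever that exceeds 1; the point estimate is unchanged.
    """
    b_exp, se_exp, b_out, se_out = _arrays(hset)
    k = b_exp.size
    if k == 0:
        raise ValueError("empty instrument set")
    r = b_out / b_exp
    w = (b_exp / se_out) ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    method = "ivw_fe"
    if random_effects and k > 1:
        q = float(np.sum(w * (r - beta) ** 2))
        scale = np.sqrt(q / (k - 1))
        if scale > 1.0:
            se *= float(scale)
        method = "ivw_mre"
    return MREstimate(method=method, beta=beta, se=se, p=_p_value(beta / se), n_snps=int(k))


@dataclass
class EggerIntercept:
    intercept: float
    se: float
    p: float
    df: int

    @property
    def pleiotropic(self) -> bool:
        return self.p < 0.05


def egger(hset, fit_intercept: bool = True) -> tuple[MREstimate, EggerIntercept | None]:
    """MR-Egger weighted regression with a free intercept.

    SNPs are re-oriented so all exposure betas are non-negative before the
    fit (required for the intercept to be interpretable).  Inference is the
    classical weighted-least-squares t-test: standard errors are scaled by
    the residual dispersion sigma (k-2 df), which keeps the intercept test
    exactly calibrated whether the instruments are under- or over-dispersed.
    With ``fit_intercept=False`` the fit reduces exactly to fixed-effect IVW.
    """
    b_exp, se_exp, b_out, se_out = _arrays(hset)
    k = b_exp.size
    n_par = 2 if fit_intercept else 1
    if k < n_par + 1:
        raise ValueError(f"MR-Egger requires at least {n_par + 1} instruments")
    sign = np.where(b_exp < 0, -1.0, 1.0)
    x = b_exp * sign
    y = b_out * sign
    w = 1.0 / se_out**2
    X = np.column_stack([np.ones(k), x]) if fit_intercept else x[:, None]
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ y)
    resid = y - X @ coef
    dof = k - n_par
    sigma2 = float(np.sum(w * resid**2) / dof)
    # free-intercept fit: classical sigma-scaled WLS inference; constrained
    # fit: exact fixed-effect IVW (known weights, no dispersion estimate)
    cov = np.linalg.inv(xtx) * (sigma2 if fit_intercept else 1.0)
    if fit_intercept:
        slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
        icept, icept_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
        intercept = EggerIntercept(
            intercept=icept, se=icept_se, p=_p_value(icept / icept_se, "t", dof), df=dof
        )
    else:
        slope, slope_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
        intercept = None
    est = MREstimate(
        method="egger" if fit_intercept else "ivw_fe",
        beta=slope,
        se=slope_se,
        p=_p_value(slope / slope_se, "t", dof) if fit_intercept else _p_value(slope / slope_se),
        n_snps=int(k),
        dist="t" if fit_intercept else "norm",
        df=dof if fit_intercept else None,
    )
    return est, intercept


def cochran_q(hset, beta: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic over the per-SNP Wald ratios."""
    b_exp, se_exp, b_out, se_out = _arrays(hset)
    k = b_exp.size
    if k < 2:
        raise ValueError("Cochran's Q requires at least two instruments")
    r = b_out / b_exp
    w = (b_exp / se_out) ** 2
    if beta is None:
        beta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: np.ndarray  # Bonferroni-corrected per-SNP p-values
    outlier_idx: np.ndarray
    corrected: MREstimate | None
    n_sim: int
    seed: int


def mr_presso(
    hset,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global heterogeneity and per-SNP outlier test.

    The observed residual sum of squares (each SNP judged against the
    leave-that-SNP-out IVW fit) is compared with ``n_sim`` parametric
    simulations under the no-pleiotropy model; per-SNP outlier p-values come
    from each SNP's own simulated residual distribution and are
    Bonferroni-corrected.  The corrected estimate is IVW on the non-outliers
    (None when no outlier is flagged).  Deterministic for a fixed seed.
    """
    b_exp, se_exp, b_out, se_out = _arrays(hset)
    k = b_exp.size
    if k < 4:
        raise ValueError("MR-PRESSO requires at least four instruments")
    r = b_out / b_exp
    u = (b_exp / se_out) ** 2
    su, sur = np.sum(u), np.sum(u * r)
    beta_loo = (sur - u * r) / (su - u)  # IVW estimate excluding each SNP
    resid_obs = (b_out - beta_loo * b_exp) ** 2 / se_out**2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    expected = beta_loo * b_exp
    b_sim = expected + se_out * rng.standard_normal((n_sim, k))
    r_sim = b_sim / b_exp
    sur_sim = r_sim @ u
    beta_loo_sim = (sur_sim[:, None] - u * r_sim) / (su - u)
    resid_sim = (b_sim - beta_loo_sim * b_exp) ** 2 / se_out**2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(1.0, k * p_raw)
    outlier_idx = np.nonzero(p_bonf < outlier_alpha)[0]

    corrected = None
    if outlier_idx.size and outlier_idx.size < k:
        keep = np.setdiff1d(np.arange(k), outlier_idx)
        corrected = ivw((b_exp[keep], se_exp[keep], b_out[keep], se_out[keep]))
        corrected.method = "ivw_presso_corrected"
    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_p=p_bonf,
        outlier_idx=outlier_idx,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(hset, random_effects: bool = True) -> list[tuple[str, MREstimate, bool]]:
    """IVW re-fits each omitting one SNP.

    Returns ``(snp, estimate, influential)`` triples; a SNP is influential
    when omitting it moves the estimate outside the full-set 95% CI.
    """
    b_exp, se_exp, b_out, se_out = _arrays(hset)
    k = b_exp.size
    if k < 2:
        raise ValueError("leave-one-out requires at least two instruments")
    snps = hset.snps if isinstance(hset, HarmonizedInstrumentSet) else [f"snp{i}" for i in range(k)]
    full = ivw(hset, random_effects=random_effects)
    out = []
    for j in range(k):
        keep = np.arange(k) != j
        est = ivw((b_exp[keep], se_exp[keep], b_out[keep], se_out[keep]),
                  random_effects=random_effects)
        influential = not (full.ci_low <= est.beta <= full.ci_high)
        out.append((snps[j], est, influential))
    return out


@dataclass
class SensitivityReport:
    cochran_q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outlier_idx: list = field(default_factory=list)
    presso_corrected: MREstimate | None = None
    loo: list = field(default_factory=list)

    @property
    def loo_influential(self) -> list[str]:
        return [snp for snp, _, flag in self.loo if flag]


@dataclass
class MRResults:
    """Fit results: per-method estimates plus the sensitivity report."""

    estimates: dict[str, MREstimate]
    sensitivity: SensitivityReport
    exposure: str = "exposure"
    outcome: str = "outcome"

    @property
    def ivw(self) -> MREstimate:
        return self.estimates["ivw"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            lo, hi = est.or_ci
            rows.append(
                {
                    "method": name,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.or_,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                    "p": est.p,
                    "n_snps": est.n_snps,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.sensitivity
        lines = [
            f"Two-sample MR: {self.exposure} -> {self.outcome}",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if s.cochran_q is not None:
            lines.append(f"Cochran's Q = {s.cochran_q:.3f} (df {s.q_df}), p = {s.q_p:.3g}")
        if s.egger_intercept is not None:
            lines.append(
                f"Egger intercept = {s.egger_intercept:.4g} (se {s.intercept_se:.4g}), "
                f"p = {s.intercept_p:.3g}"
            )
        if s.presso_global_p is not None:
            lines.append(
                f"MR-PRESSO global p = {s.presso_global_p:.3g}, "
                f"outliers: {list(map(int, s.presso_outlier_idx)) or 'none'}"
            )
        if s.loo:
            flagged = s.loo_influential
            lines.append(f"Leave-one-out influential SNPs: {flagged or 'none'}")
        return "\n".join(lines)


class MRAnalysis:
    """Model-style front end: build from a harmonized instrument set and
    ``fit()`` to obtain estimates with sensitivity diagnostics."""

    def __init__(self, hset: HarmonizedInstrumentSet):
        self.hset = hset

    def fit(
        self,
        random_effects: bool = True,
        presso: bool = False,
        n_sim: int = 1000,
        seed: int = 0,
        loo: bool = True,
    ) -> MRResults:
        hset = self.hset
        k = hset.n_snps
        estimates = {"ivw": ivw(hset, random_effects=random_effects)}
        report = SensitivityReport()
        if k >= 2:
            report.cochran_q, report.q_df, report.q_p = cochran_q(hset)
            report.loo = leave_one_out(hset, random_effects=random_effects) if loo else []
        if k >= 3:
            slope, intercept = egger(hset)
            estimates["egger"] = slope
            report.egger_intercept = intercept.intercept
            report.intercept_se = intercept.se
            report.intercept_p = intercept.p
        if presso and k >= 4:
            pres = mr_presso(hset, n_sim=n_sim, seed=seed)
            report.presso_global_p = pres.global_p
            report.presso_outlier_idx = pres.outlier_idx.tolist()
            report.presso_corrected = pres.corrected
            if pres.corrected is not None:
                estimates["ivw_presso_corrected"] = pres.corrected
        return MRResults(
            estimates=estimates,
            sensitivity=report,
            exposure=hset.exposure,
            outcome=hset.outcome,
        )
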