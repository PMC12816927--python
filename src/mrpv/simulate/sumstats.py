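"""Synthetic GWAS/eQTL summary statistics with known causal structure.

Statistics are generated directly at the summary level under the standard
multivariate model: given joint (causal-scale) per-allele effects ``b`` and
an LD correlation matrix ``R``, the marginal effects are ``R @ b`` and the
observed estimates are drawn as

    b_hat ~ MVN(R @ b, D R D),     D = diag(se),
    se_j  = 1 / sqrt(2 * maf_j * (1 - maf_j) * n)

with independent noise across traits (two-sample, non-overlapping cohorts).
Binary-trait effects live on the log-odds scale; ``n`` is then the effective
sample size ``4 / (1/n_case + 1/n_ctrl)``.

The panel consists of the cis region (LD per the scenario) plus, when
configured, independent reverse-causal variants and independent genome-wide
mediator instruments.  Allele bookkeeping (palindromic variants, swapped
allele order, strand-flipped representation) is applied to the outcome and
mediator emissions only, so the exposure file and the LD matrix share one
canonical coding.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ..sumstats import LDMatrix, SummaryStats
from .scenarios import GeneticScenario

__all__ = ["SummaryStatsSet", "generate_summary_stats", "build_ld"]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_PLAIN_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryStatsSet(NamedTuple):
    exposure: SummaryStats
    outcome: SummaryStats
    mediator: SummaryStats | None
    ld: LDMatrix


def build_ld(spec, n_snps: int) -> np.ndarray:
    """Materialise the cis-region LD correlation matrix from its spec."""
    if isinstance(spec, np.ndarray):
        r = np.asarray(spec, dtype=float)
        if r.shape != (n_snps, n_snps):
            raise ValueError("explicit LD matrix has the wrong shape")
        if np.linalg.eigvalsh((r + r.T) / 2).min() < -1e-6:
            raise ValueError("explicit LD matrix is not positive semi-definite")
        return r
    if spec == "identity":
        return np.eye(n_snps)
    if isinstance(spec, tuple) and spec[0] == "ar1":
        rho = float(spec[1])
        if not 0 <= rho < 1:
            raise ValueError("AR-1 correlation must lie in [0, 1)")
        idx = np.arange(n_snps)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if isinstance(spec, tuple) and spec[0] == "blocks":
        _, size, rho = spec
        r = np.eye(n_snps)
        for start in range(0, n_snps, size):
            stop = min(start + size, n_snps)
            idx = np.arange(start, stop)
            r[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
        return r
    raise ValueError(f"unknown LD specification {spec!r}")


def _draw(values, n, rng, low, high):
    """Resolve a scalar / sequence / None field into an array of length n."""
    if values is None:
        return rng.uniform(low, high, size=n)
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"expected {n} values, got shape {arr.shape}")
    return arr.copy()


def _emit(
    snp, chrom, pos, a1, a2, eaf_true, beta, se, n, rng, *,
    swap_fraction=0.0, strand_flip_fraction=0.0, eaf_noise=True,
) -> pd.DataFrame:
    """Assemble one trait's records, optionally re-representing a fraction of
    them with swapped allele order and/or on the opposite strand."""
    m = len(snp)
    a1 = np.array(a1, dtype=object).copy()
    a2 = np.array(a2, dtype=object).copy()
    beta = beta.copy()
    eaf = eaf_true.copy()
    if eaf_noise:
        eaf = eaf + rng.normal(0.0, np.sqrt(eaf * (1 - eaf) / (2 * n)))
        eaf = np.clip(eaf, 1e-4, 1 - 1e-4)
    swap = rng.random(m) < swap_fraction
    a1[swap], a2[swap] = a2[swap], a1[swap].copy()
    beta[swap] = -beta[swap]
    eaf[swap] = 1.0 - eaf[swap]
    flip = rng.random(m) < strand_flip_fraction
    comp = np.vectorize(_COMPLEMENT.get)
    if flip.any():
        a1[flip] = comp(a1[flip])
        a2[flip] = comp(a2[flip])
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "snp": snp,
            "chr": chrom,
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )


def generate_summary_stats(scenario: GeneticScenario) -> SummaryStatsSet:
    """Generate (exposure, outcome, optional mediator, LD) for ``scenario``.

    Bit-reproducible for a fixed scenario seed; per-trait noise streams are
    spawned deterministically from the one scenario seed.
    """
    n_cis = scenario.n_snps
    n_rev = scenario.n_reverse if scenario.mode == "reverse" else 0
    med = scenario.mediation
    n_med = med.n_mediator_snps if med is not None else 0
    n_total = n_cis + n_rev + n_med
    rev_idx = np.arange(n_cis, n_cis + n_rev)
    med_idx = np.arange(n_cis + n_rev, n_total)

    ss = np.random.SeedSequence(scenario.seed)
    (rng_struct, rng_exp, rng_out, rng_med,
     rng_emit_out, rng_emit_med, rng_eaf_exp) = [np.random.default_rng(s) for s in ss.spawn(7)]

    r_cis = build_ld(scenario.ld, n_cis)

    # -- structure: frequencies, alleles, positions ----------------------
    maf = np.empty(n_total)
    maf[:n_cis] = _draw(scenario.maf, n_cis, rng_struct, 0.1, 0.4)
    if n_total > n_cis:
        maf[n_cis:] = rng_struct.uniform(0.1, 0.4, size=n_total - n_cis)
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    # effect allele is the minor or the major allele with equal probability
    eaf_true = np.where(rng_struct.random(n_total) < 0.5, maf, 1.0 - maf)

    palindromic = rng_struct.random(n_total) < scenario.palindromic_fraction
    pair_idx = rng_struct.integers(0, 4, size=n_total)
    plain_idx = rng_struct.integers(0, 8, size=n_total)
    a1 = np.empty(n_total, dtype=object)
    a2 = np.empty(n_total, dtype=object)
    for i in range(n_total):
        a1[i], a2[i] = (
            _PALINDROMIC_PAIRS[pair_idx[i]] if palindromic[i] else _PLAIN_PAIRS[plain_idx[i]]
        )

    snp = np.array([f"rs{100001 + i}" for i in range(n_total)], dtype=object)
    chrom = np.empty(n_total, dtype=object)
    pos = np.empty(n_total, dtype=int)
    anchor_chr, anchor_pos = scenario.anchor
    chrom[:n_cis] = anchor_chr
    pos[:n_cis] = anchor_pos + (np.arange(n_cis) - n_cis // 2) * 5000
    off_anchor = [str(c) for c in range(1, 23) if str(c) != str(anchor_chr)]
    for k, i in enumerate(range(n_cis, n_total)):
        chrom[i] = off_anchor[k % len(off_anchor)]
        pos[i] = 10_000_000 + k * 1_000_000

    # -- joint (causal-scale) effects ------------------------------------
    b_expr = np.zeros(n_total)
    causal = np.asarray(scenario.causal_idx, dtype=int)
    if scenario.mode == "linkage":
        expr_causal = causal[:1]
    else:
        expr_causal = causal
    vals = _draw(scenario.b_expr, len(expr_causal), rng_struct, 0.15, 0.45)
    if scenario.b_expr is None:
        vals *= rng_struct.choice([-1.0, 1.0], size=len(expr_causal))
    b_expr[expr_causal] = vals

    b_out = np.zeros(n_total)
    b_med_joint = np.zeros(n_total) if med is not None else None
    if med is not None:
        b_med_joint[:] = med.beta_xm * b_expr
        med_vals = _draw(med.b_med, n_med, rng_struct, 0.025, 0.06)
        if med.b_med is None:
            med_vals *= rng_struct.choice([-1.0, 1.0], size=n_med)
        b_med_joint[med_idx] = med_vals
        b_out += med.theta_direct * b_expr + med.beta_my * b_med_joint
    else:
        b_out += scenario.theta * b_expr

    if scenario.pleio_frac > 0:
        k = int(round(scenario.pleio_frac * len(expr_causal)))
        if k:
            chosen = rng_struct.choice(expr_causal, size=k, replace=False)
            # "directional" pleiotropy is defined in the orientation where the
            # effect allele increases expression (the MR-Egger convention), so
            # the direct effects are planted relative to that orientation
            direct = rng_struct.normal(scenario.pleio_mean, scenario.pleio_sd, size=k)
            b_out[chosen] += np.sign(b_expr[chosen]) * direct
    if scenario.direct_effects:
        for i, v in scenario.direct_effects.items():
            b_out[int(i)] += v
    if scenario.mode == "linkage":
        j = causal[1] if len(causal) > 1 else causal[0] + scenario.linkage_offset
        if j >= n_cis:
            raise ValueError("linkage outcome variant falls outside the cis region")
        b_out[j] += scenario.linkage_b_out
    if n_rev:
        signs = rng_struct.choice([-1.0, 1.0], size=n_rev)
        b_expr[rev_idx] = scenario.reverse_b_exp * signs
        b_out[rev_idx] += scenario.reverse_b_out * signs

    # -- marginal effects and observed estimates -------------------------
    def marginal(joint: np.ndarray) -> np.ndarray:
        out = joint.copy()
        out[:n_cis] = r_cis @ joint[:n_cis]
        return out

    chol = np.linalg.cholesky(r_cis + 1e-10 * np.eye(n_cis))

    def observe(joint, n_samples, rng_noise):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_samples)
        z = rng_noise.standard_normal(n_total)
        noise = z.copy()
        noise[:n_cis] = chol @ z[:n_cis]
        return marginal(joint) + se * noise, se

    beta_exp, se_exp = observe(b_expr, scenario.n_eqtl, rng_exp)
    beta_out, se_out = observe(b_out, scenario.n_gwas, rng_out)

    exposure = SummaryStats(
        _emit(snp, chrom, pos, a1, a2, eaf_true, beta_exp, se_exp, scenario.n_eqtl,
              rng_eaf_exp, eaf_noise=scenario.eaf_noise),
        trait="GLP1R_expression",
        trait_type="quantitative",
    )
    outcome = SummaryStats(
        _emit(snp, chrom, pos, a1, a2, eaf_true, beta_out, se_out, scenario.n_gwas,
              rng_emit_out, swap_fraction=scenario.swap_fraction,
              strand_flip_fraction=scenario.strand_flip_fraction,
              eaf_noise=scenario.eaf_noise),
        trait=scenario.outcome_name,
        trait_type="binary",
    )
    mediator = None
    if med is not None:
        beta_med, se_med = observe(b_med_joint, med.n_mediator, rng_med)
        mediator = SummaryStats(
            _emit(snp, chrom, pos, a1, a2, eaf_true, beta_med, se_med, med.n_mediator,
                  rng_emit_med, swap_fraction=scenario.swap_fraction,
                  strand_flip_fraction=scenario.strand_flip_fraction,
                  eaf_noise=scenario.eaf_noise),
            trait="mediator",
            trait_type="quantitative",
        )

    r_panel = np.eye(n_total)
    r_panel[:n_cis, :n_cis] = r_cis
    ld = LDMatrix(r_panel, list(snp))
    return SummaryStatsSet(exposure=exposure, outcome=outcome, mediator=mediator, ld=ld)
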