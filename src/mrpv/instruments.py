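"""Genetic instrument selection, allele harmonization and Steiger filtering.

Instrument selection follows the conventional cis-eQTL pipeline: keep
variants associated with target-gene expression at p < 5e-8 with minor
allele frequency above 1%, greedily clump them to pairwise r^2 < 0.01
(strongest association first), and drop weak instruments with
F = (beta/se)^2 below 10.

Harmonization re-expresses outcome-side records in the exposure's allele
coding.  Swapped allele order flips the sign of the outcome beta (and
complements the frequency); a strand-flipped representation (complemented
allele pair) is matched silently.  Palindromic (A/T, C/G) variants, whose
strand cannot be resolved from the alleles, are kept only when both
frequencies fall on the same side of 0.5 and the minor allele frequency is
below ``palindrome_eaf_limit``; otherwise they are dropped with a recorded
reason, never silently.

Steiger filtering removes instruments that explain more variance in the
outcome than in the exposure (a reverse-causation guard): per SNP,
r^2 = z^2 / (z^2 + n) for each trait, and the variant is retained when the
exposure r^2 exceeds the outcome r^2 with a significant two-sided z-test on
the difference of Fisher-transformed correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InstrumentSelectionError
from .sumstats import LDMatrix, SummaryStats

__all__ = [
    "HarmonizedInstrumentSet",
    "select_instruments",
    "harmonize",
    "steiger_filter",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == _complement(a1)


@dataclass
class HarmonizedInstrumentSet:
    """Aligned exposure/outcome effect pairs with QC provenance.

    ``table`` has one row per exposure SNP, including dropped rows; a row is
    retained when ``dropped_reason`` is null.  Columns: ``snp, chr, pos, a1,
    a2, b_exp, se_exp, eaf_exp, n_exp, b_out, se_out, eaf_out, n_out,
    f_stat, palindromic, flipped, steiger_keep, steiger_p, dropped_reason``.
    """

    table: pd.DataFrame
    exposure: str = "exposure"
    outcome: str = "outcome"

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["dropped_reason"].isna()]

    @property
    def n_snps(self) -> int:
        return len(self.kept)

    def __len__(self) -> int:
        return len(self.kept)

    @property
    def snps(self) -> list[str]:
        return self.kept["snp"].tolist()

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        k = self.kept
        return (
            k["b_exp"].to_numpy(float),
            k["se_exp"].to_numpy(float),
            k["b_out"].to_numpy(float),
            k["se_out"].to_numpy(float),
        )

    def subset(self, snps) -> "HarmonizedInstrumentSet":
        wanted = set(snps)
        mask = self.table["snp"].isin(wanted) | self.table["dropped_reason"].notna()
        return replace(self, table=self.table[mask].reset_index(drop=True))

    @classmethod
    def from_arrays(
        cls,
        b_exp,
        se_exp,
        b_out,
        se_out,
        snp=None,
        n_exp: int = 30_000,
        n_out: int = 500_000,
        eaf: float | np.ndarray = 0.3,
        exposure: str = "exposure",
        outcome: str = "outcome",
    ) -> "HarmonizedInstrumentSet":
        """Build an already-aligned set directly from effect arrays (handy in
        simulations and tests that do not exercise the allele machinery)."""
        b_exp = np.asarray(b_exp, float)
        k = b_exp.size
        table = pd.DataFrame(
            {
                "snp": snp if snp is not None else [f"snp{i}" for i in range(k)],
                "chr": "1",
                "pos": np.arange(k),
                "a1": "A",
                "a2": "G",
                "b_exp": b_exp,
                "se_exp": np.asarray(se_exp, float),
                "eaf_exp": np.broadcast_to(np.asarray(eaf, float), (k,)).copy(),
                "n_exp": n_exp,
                "b_out": np.asarray(b_out, float),
                "se_out": np.asarray(se_out, float),
                "eaf_out": np.broadcast_to(np.asarray(eaf, float), (k,)).copy(),
                "n_out": n_out,
                "palindromic": False,
                "flipped": False,
                "steiger_keep": True,
                "steiger_p": np.nan,
                "dropped_reason": pd.Series([None] * k, dtype=object),
            }
        )
        table["f_stat"] = (table["b_exp"] / table["se_exp"]) ** 2
        return cls(table=table, exposure=exposure, outcome=outcome)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, exposure="exposure", outcome="outcome"):
        table = pd.read_csv(path, sep="\t")
        table["dropped_reason"] = table["dropped_reason"].astype(object).where(
            table["dropped_reason"].notna(), None
        )
        return cls(table=table, exposure=exposure, outcome=outcome)


def select_instruments(
    eqtl: SummaryStats,
    ld: LDMatrix,
    p_max: float = 5e-8,
    eaf_min: float = 0.01,
    r2_max: float = 0.01,
    f_min: float = 10.0,
) -> SummaryStats:
    """Select cis instruments: significance and frequency filters, greedy
    LD clumping, then the weak-instrument F cut.

    Clumping sorts candidates by ascending p and keeps a SNP iff its r^2
    with every already-kept SNP is below ``r2_max``.  Raises
    :class:`InstrumentSelectionError` (with per-stage survivor counts) if no
    variant survives.
    """
    t = eqtl.table
    counts = {"input": len(t)}
    maf = np.minimum(t["eaf"], 1 - t["eaf"])
    t = t[(t["p"] < p_max) & (maf > eaf_min)]
    counts["p_and_eaf"] = len(t)

    order = t.sort_values(["p", "snp"]).index
    kept_pos: list[int] = []
    kept_idx: list[int] = []
    for idx in order:
        snp = t.at[idx, "snp"]
        pos = ld.index(snp)
        if all(ld.r[pos, q] ** 2 < r2_max for q in kept_pos):
            kept_pos.append(pos)
            kept_idx.append(idx)
    t = t.loc[sorted(kept_idx)]
    counts["clumped"] = len(t)

    f = (t["beta"] / t["se"]) ** 2
    t = t[f >= f_min]
    counts["f_filter"] = len(t)

    if len(t) == 0:
        raise InstrumentSelectionError("no instrument survived selection", counts)
    return replace(eqtl, table=t.reset_index(drop=True))


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonizedInstrumentSet:
    """Align outcome records to the exposure's effect-allele coding.

    Harmonizing an already-aligned pair is the identity, and the operation
    is idempotent.  Allele pairs that are neither a match, a swap, nor a
    strand flip of the exposure pair are dropped with a recorded reason.
    """
    exp = exposure.table.rename(
        columns={"eaf": "eaf_exp", "beta": "b_exp", "se": "se_exp", "n": "n_exp", "p": "p_exp"}
    )
    out = outcome.table.rename(
        columns={
            "a1": "o1",
            "a2": "o2",
            "eaf": "eaf_out",
            "beta": "b_out",
            "se": "se_out",
            "n": "n_out",
            "p": "p_out",
        }
    )[["snp", "o1", "o2", "eaf_out", "b_out", "se_out", "n_out", "p_out"]]
    m = exp.merge(out, on="snp", how="left")

    a1, a2, o1, o2 = m["a1"], m["a2"], m["o1"], m["o2"]
    present = m["o1"].notna()
    match = present & (o1 == a1) & (o2 == a2)
    swap = present & (o1 == a2) & (o2 == a1)
    strand = present & (o1 == _complement(a1)) & (o2 == _complement(a2))
    strand_swap = present & (o1 == _complement(a2)) & (o2 == _complement(a1))
    palindromic = _is_palindromic(a1, a2)

    aligned = (match | strand) & ~palindromic
    flipped = (swap | strand_swap) & ~palindromic

    # palindromic variants: allele order cannot distinguish swap from strand
    # flip, so orientation is taken from the frequencies -- same side of 0.5
    # means aligned; anything else (or a too-common variant) is ambiguous.
    pal_present = palindromic & present & (match | swap | strand | strand_swap)
    same_side = (m["eaf_exp"] - 0.5) * (m["eaf_out"] - 0.5) > 0
    informative = np.minimum(m["eaf_exp"], 1 - m["eaf_exp"]) < palindrome_eaf_limit
    pal_keep = pal_present & same_side & informative

    reason = pd.Series([None] * len(m), dtype=object)
    reason[~present] = "missing_in_outcome"
    mismatch = present & ~(match | swap | strand | strand_swap)
    reason[mismatch] = "allele_mismatch"
    reason[pal_present & ~pal_keep] = "palindromic_ambiguous"

    sign = np.where(flipped, -1.0, 1.0)
    b_out = m["b_out"] * sign
    eaf_out = np.where(flipped, 1 - m["eaf_out"], m["eaf_out"])

    table = pd.DataFrame(
        {
            "snp": m["snp"],
            "chr": m["chr"],
            "pos": m["pos"],
            "a1": a1,
            "a2": a2,
            "b_exp": m["b_exp"],
            "se_exp": m["se_exp"],
            "eaf_exp": m["eaf_exp"],
            "n_exp": m["n_exp"],
            "b_out": b_out,
            "se_out": m["se_out"],
            "eaf_out": eaf_out,
            "n_out": m["n_out"],
            "f_stat": (m["b_exp"] / m["se_exp"]) ** 2,
            "palindromic": palindromic,
            "flipped": pd.Series(flipped, dtype=bool),
            "steiger_keep": True,
            "steiger_p": np.nan,
            "dropped_reason": reason,
        }
    )
    return HarmonizedInstrumentSet(
        table=table, exposure=exposure.trait, outcome=outcome.trait
    )


def steiger_filter(hset: HarmonizedInstrumentSet, alpha: float = 0.05) -> HarmonizedInstrumentSet:
    """Directionality filter: keep instruments that explain significantly
    more variance in the exposure than in the outcome."""
    table = hset.table.copy()
    kept = table["dropped_reason"].isna()
    t = table[kept]
    z_exp = (t["b_exp"] / t["se_exp"]).to_numpy()
    z_out = (t["b_out"] / t["se_out"]).to_numpy()
    n_exp = t["n_exp"].to_numpy(float)
    n_out = t["n_out"].to_numpy(float)
    r2_exp = z_exp**2 / (z_exp**2 + n_exp)
    r2_out = z_out**2 / (z_out**2 + n_out)
    fisher = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
    se = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = 2.0 * stats.norm.sf(np.abs(fisher / se))
    keep = (r2_exp > r2_out) & (p < alpha)
    table.loc[kept, "steiger_p"] = p
    table.loc[kept, "steiger_keep"] = keep
    idx = t.index[~keep]
    table.loc[idx, "dropped_reason"] = "steiger"
    return replace(hset, table=table)
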