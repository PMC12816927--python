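"""Containers and text I/O for GWAS/eQTL summary statistics and LD matrices.

A :class:`SummaryStats` holds one trait's per-variant association records
(alleles, effect-allele frequency, beta, SE, p, sample size) as a pandas
DataFrame.  A :class:`LDMatrix` holds the signed genotype correlation matrix
for a region, with allele coding matching the exposure file it accompanies.

Files are plain tab-delimited text with the conventional header
``SNP CHR POS A1 A2 EAF BETA SE P N``; LD matrices are dense
whitespace-delimited text with a sidecar file listing the SNP order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SummaryStats", "LDMatrix", "SUMSTAT_COLUMNS"]

#: Column order of the on-disk tab-delimited format.
SUMSTAT_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]

_INTERNAL = ["snp", "chr", "pos", "a1", "a2", "eaf", "beta", "se", "p", "n"]

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class SummaryStats:
    """Per-variant summary association statistics for one trait.

    Parameters
    ----------
    table
        DataFrame with columns ``snp, chr, pos, a1, a2, eaf, beta, se, p, n``.
    trait
        Trait label (e.g. ``"GLP1R_expression"``).
    trait_type
        ``"quantitative"`` or ``"binary"``.  Binary-trait betas are log odds
        ratios; sample sizes are effective sizes ``4 / (1/n_case + 1/n_ctrl)``.
    """

    table: pd.DataFrame
    trait: str = "trait"
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        missing = [c for c in _INTERNAL if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t["snp"].duplicated().any():
            dup = t.loc[t["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate snp id {dup!r}")
        if (t["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        if ((t["eaf"] <= 0) | (t["eaf"] >= 1)).any():
            raise ValueError("EAF must lie strictly inside (0, 1)")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        bad = ~(t["a1"].isin(_VALID_ALLELES) & t["a2"].isin(_VALID_ALLELES))
        if bad.any():
            raise ValueError("alleles must be single bases from {A,C,G,T}")
        if (t["a1"] == t["a2"]).any():
            raise ValueError("effect and other allele must differ")

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()

    @property
    def snps(self) -> list[str]:
        return self.table["snp"].tolist()

    def subset(self, snps: Iterable[str]) -> "SummaryStats":
        wanted = set(snps)
        sub = self.table[self.table["snp"].isin(wanted)].reset_index(drop=True)
        return replace(self, table=sub)

    def significant(self, p_max: float) -> "SummaryStats":
        sub = self.table[self.table["p"] < p_max].reset_index(drop=True)
        return replace(self, table=sub)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.table[_INTERNAL].copy()
        out.columns = SUMSTAT_COLUMNS
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: str | Path, trait: str | None = None, trait_type: str = "quantitative"
    ) -> "SummaryStats":
        raw = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
        missing = [c for c in SUMSTAT_COLUMNS if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        raw = raw[SUMSTAT_COLUMNS].copy()
        raw.columns = _INTERNAL
        return cls(raw, trait=trait or Path(path).stem, trait_type=trait_type)


@dataclass
class LDMatrix:
    """Signed pairwise genotype correlation matrix for a set of variants.

    Correlations refer to the allele coding of the exposure summary
    statistics the matrix is distributed with; harmonization re-expresses
    other traits in that coding, so no sign adjustment of ``r`` is needed
    downstream.
    """

    r: np.ndarray
    snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.snps = list(self.snps)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape != (n, n):
            raise ValueError("LD matrix must be square")
        if len(self.snps) != n:
            raise ValueError("snp list length must match matrix dimension")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.r).min() < -1e-6:
            raise ValueError("LD matrix is not positive semi-definite")
        self._index = {s: i for i, s in enumerate(self.snps)}

    def __len__(self) -> int:
        return self.r.shape[0]

    def index(self, snp: str) -> int:
        try:
            return self._index[snp]
        except KeyError:
            raise KeyError(f"snp {snp!r} not covered by LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)

    def submatrix(self, snps: Sequence[str]) -> "LDMatrix":
        idx = [self.index(s) for s in snps]
        return LDMatrix(self.r[np.ix_(idx, idx)], list(snps))

    # -- I/O -------------------------------------------------------------
    def to_files(self, matrix_path: str | Path, snp_path: str | Path | None = None) -> None:
        matrix_path = Path(matrix_path)
        if snp_path is None:
            snp_path = matrix_path.with_suffix(matrix_path.suffix + ".snps")
        np.savetxt(matrix_path, self.r, fmt="%.8g")
        Path(snp_path).write_text("\n".join(self.snps) + "\n")

    @classmethod
    def read_files(cls, matrix_path: str | Path, snp_path: str | Path | None = None) -> "LDMatrix":
        matrix_path = Path(matrix_path)
        if snp_path is None:
            snp_path = matrix_path.with_suffix(matrix_path.suffix + ".snps")
        r = np.loadtxt(matrix_path, ndmin=2)
        snps = Path(snp_path).read_text().split()
        return cls(r, snps)
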