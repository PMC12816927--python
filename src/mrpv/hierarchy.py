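"""MedDRA-style term hierarchy: PT -> HLT -> HLGT -> SOC, plus SMQ sets.

Adverse events in spontaneous reports are coded at the preferred-term (PT)
level.  Each PT rolls up through exactly one high-level term (HLT), one
high-level group term (HLGT) and one system organ class (SOC).  Standardised
queries (SMQs) are curated PT sets for a clinical concept with a *narrow*
scope (high specificity) contained in a *broad* scope (high sensitivity).

The licensed dictionary itself is out of scope; :func:`generate_term_hierarchy`
builds a mock tree with the same structural guarantees for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import UnknownTermError

__all__ = ["TermHierarchy", "generate_term_hierarchy", "LEVELS"]

LEVELS = ("PT", "HLT", "HLGT", "SOC")


@dataclass
class TermHierarchy:
    pt_to_hlt: dict[str, str]
    hlt_to_hlgt: dict[str, str]
    hlgt_to_soc: dict[str, str]
    #: name -> (narrow PT set, broad PT set); narrow is a subset of broad
    smq: dict[str, tuple[frozenset, frozenset]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for hlt in set(self.pt_to_hlt.values()):
            if hlt not in self.hlt_to_hlgt:
                raise ValueError(f"HLT {hlt!r} has no HLGT parent")
        for hlgt in set(self.hlt_to_hlgt.values()):
            if hlgt not in self.hlgt_to_soc:
                raise ValueError(f"HLGT {hlgt!r} has no SOC parent")
        pts = set(self.pt_to_hlt)
        for name, (narrow, broad) in self.smq.items():
            if not narrow <= broad:
                raise ValueError(f"SMQ {name!r}: narrow scope is not a subset of broad")
            if not broad <= pts:
                raise ValueError(f"SMQ {name!r} references unknown PTs")

    # -- queries ---------------------------------------------------------
    def pts(self) -> set[str]:
        return set(self.pt_to_hlt)

    def terms(self, level: str) -> set[str]:
        if level == "PT":
            return set(self.pt_to_hlt)
        if level == "HLT":
            return set(self.hlt_to_hlgt)
        if level == "HLGT":
            return set(self.hlgt_to_soc)
        if level == "SOC":
            return set(self.hlgt_to_soc.values())
        raise ValueError(f"unknown level {level!r}")

    def rollup(self, pt: str, level: str) -> str:
        """Ancestor of ``pt`` at ``level``; single-valued by construction."""
        if pt not in self.pt_to_hlt:
            raise UnknownTermError(f"unknown preferred term {pt!r}")
        if level == "PT":
            return pt
        hlt = self.pt_to_hlt[pt]
        if level == "HLT":
            return hlt
        hlgt = self.hlt_to_hlgt[hlt]
        if level == "HLGT":
            return hlgt
        if level == "SOC":
            return self.hlgt_to_soc[hlgt]
        raise ValueError(f"unknown level {level!r}")

    def rollup_map(self, level: str) -> dict[str, str]:
        return {pt: self.rollup(pt, level) for pt in self.pt_to_hlt}

    def smq_members(self, name: str, scope: str = "narrow") -> frozenset:
        if name not in self.smq:
            raise KeyError(f"unknown SMQ {name!r}")
        narrow, broad = self.smq[name]
        if scope == "narrow":
            return narrow
        if scope == "broad":
            return broad
        raise ValueError(f"unknown SMQ scope {scope!r}")

    def add_smq(self, name: str, narrow: Iterable[str], broad: Iterable[str] | None = None) -> None:
        narrow = frozenset(narrow)
        broad = frozenset(broad) if broad is not None else narrow
        broad = broad | narrow
        unknown = (narrow | broad) - self.pts()
        if unknown:
            raise UnknownTermError(f"SMQ {name!r} references unknown PTs: {sorted(unknown)}")
        self.smq[name] = (narrow, broad)

    def add_chain(self, pt: str, hlt: str, hlgt: str, soc: str) -> None:
        self.pt_to_hlt[pt] = hlt
        self.hlt_to_hlgt[hlt] = hlgt
        self.hlgt_to_soc[hlgt] = soc

    # -- I/O -------------------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        rows = []
        for pt, hlt in sorted(self.pt_to_hlt.items()):
            hlgt = self.hlt_to_hlgt[hlt]
            rows.append((pt, hlt, hlgt, self.hlgt_to_soc[hlgt]))
        hier = pd.DataFrame(rows, columns=["pt", "hlt", "hlgt", "soc"])
        smq_rows = []
        for name, (narrow, broad) in sorted(self.smq.items()):
            for pt in sorted(broad):
                smq_rows.append((name, pt, "narrow" if pt in narrow else "broad"))
        smq = pd.DataFrame(smq_rows, columns=["smq", "pt", "scope"])
        return hier, smq

    @classmethod
    def from_frames(cls, hier: pd.DataFrame, smq: pd.DataFrame | None = None) -> "TermHierarchy":
        obj = cls(
            pt_to_hlt=dict(zip(hier["pt"], hier["hlt"])),
            hlt_to_hlgt=dict(zip(hier["hlt"], hier["hlgt"])),
            hlgt_to_soc=dict(zip(hier["hlgt"], hier["soc"])),
        )
        if smq is not None and len(smq):
            for name, grp in smq.groupby("smq"):
                narrow = grp.loc[grp["scope"] == "narrow", "pt"]
                obj.add_smq(name, narrow, grp["pt"])
        return obj

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        hier, smq = self.to_frames()
        hier.to_csv(directory / "hierarchy.csv", index=False)
        smq.to_csv(directory / "smq.csv", index=False)

    @classmethod
    def read_csv(cls, directory: str | Path) -> "TermHierarchy":
        directory = Path(directory)
        hier = pd.read_csv(directory / "hierarchy.csv")
        smq_path = directory / "smq.csv"
        smq = pd.read_csv(smq_path) if smq_path.exists() else None
        return cls.from_frames(hier, smq)


def generate_term_hierarchy(
    n_soc: int,
    fanout: tuple[int, int, int],
    seed: int = 0,
    n_smq: int = 0,
    smq_size: int = 4,
) -> TermHierarchy:
    """Build a mock coding hierarchy.

    ``fanout`` gives the number of HLGTs per SOC, HLTs per HLGT and PTs per
    HLT, so the tree has ``n_soc * prod(fanout)`` preferred terms, each with a
    unique three-step ancestor chain.  Optionally ``n_smq`` random SMQs are
    drawn, each a broad set of ``smq_size`` PTs with a narrow subset of half
    that size (at least one PT).
    """
    if n_soc < 1 or any(f < 1 for f in fanout):
        raise ValueError("n_soc and every fanout entry must be >= 1")
    f_hlgt, f_hlt, f_pt = fanout
    pt_to_hlt: dict[str, str] = {}
    hlt_to_hlgt: dict[str, str] = {}
    hlgt_to_soc: dict[str, str] = {}
    for i in range(1, n_soc + 1):
        soc = f"SOC{i:02d}"
        for j in range(1, f_hlgt + 1):
            hlgt = f"{soc}.G{j}"
            hlgt_to_soc[hlgt] = soc
            for k in range(1, f_hlt + 1):
                hlt = f"{hlgt}.T{k}"
                hlt_to_hlgt[hlt] = hlgt
                for m in range(1, f_pt + 1):
                    pt_to_hlt[f"{hlt}.P{m}"] = hlt
    hierarchy = TermHierarchy(pt_to_hlt, hlt_to_hlgt, hlgt_to_soc)
    if n_smq:
        rng = np.random.default_rng(seed)
        pts = sorted(pt_to_hlt)
        size = min(smq_size, len(pts))
        for s in range(1, n_smq + 1):
            broad = rng.choice(pts, size=size, replace=False)
            narrow = broad[: max(1, size // 2)]
            hierarchy.add_smq(f"SMQ{s:02d}", narrow, broad)
    return hierarchy
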