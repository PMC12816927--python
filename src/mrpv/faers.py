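"""Spontaneous adverse-event report containers in a FAERS-like layout.

A report database is held as four relational tables sharing a ``primaryid``
key, mirroring the quarterly FAERS extract layout at toy scale:

``demo``
    one row per report version: ``primaryid, caseid, caseversion, sex,
    age_band, weight_band, reporter_type, country, quarter``
``drug``
    one row per reported drug: ``primaryid, drugname, role_cod, drug_class``
    with role codes PS (primary suspect), SS (secondary suspect), C
    (concomitant)
``reac``
    one row per coded event: ``primaryid, pt``
``indi``
    one row per report: ``primaryid, indi_pt``

Several versions of the same case may be present (shared ``caseid``,
distinct ``caseversion``); deduplication keeps the latest version.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["ReportRecord", "ReportDatabase", "deduplicate", "ROLE_CODES"]

ROLE_CODES = ("PS", "SS", "C")

_TABLES = ("demo", "drug", "reac", "indi")


@dataclass
class ReportRecord:
    """One spontaneous report (a single case version)."""

    primaryid: int
    caseid: int
    version: int
    drugs: list[tuple[str, str]]  # (drug name, role code)
    events: list[str]  # preferred terms
    indication: str = "other"
    sex: str = "unknown"
    age_band: str = "unknown"
    weight_band: str = "unknown"
    country: str = "unknown"
    reporter_type: str = "unknown"
    quarter: str = "2024Q4"

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a report must carry at least one coded event")
        for _, role in self.drugs:
            if role not in ROLE_CODES:
                raise ValueError(f"unknown drug role code {role!r}")


@dataclass
class ReportDatabase:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame

    def __post_init__(self) -> None:
        if self.demo["primaryid"].duplicated().any():
            raise ValueError("primaryid must be unique in demo")

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def n_cases(self) -> int:
        return self.demo["caseid"].nunique()

    def drug_names(self) -> set[str]:
        return set(self.drug["drugname"].unique())

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[ReportRecord],
        drug_classes: Mapping[str, str] | None = None,
    ) -> "ReportDatabase":
        drug_classes = dict(drug_classes or {})
        demo_rows, drug_rows, reac_rows, indi_rows = [], [], [], []
        for rec in records:
            demo_rows.append(
                (
                    rec.primaryid,
                    rec.caseid,
                    rec.version,
                    rec.sex,
                    rec.age_band,
                    rec.weight_band,
                    rec.reporter_type,
                    rec.country,
                    rec.quarter,
                )
            )
            for name, role in rec.drugs:
                drug_rows.append((rec.primaryid, name, role, drug_classes.get(name, "unknown")))
            for pt in rec.events:
                reac_rows.append((rec.primaryid, pt))
            indi_rows.append((rec.primaryid, rec.indication))
        demo = pd.DataFrame(
            demo_rows,
            columns=[
                "primaryid",
                "caseid",
                "caseversion",
                "sex",
                "age_band",
                "weight_band",
                "reporter_type",
                "country",
                "quarter",
            ],
        )
        drug = pd.DataFrame(drug_rows, columns=["primaryid", "drugname", "role_cod", "drug_class"])
        reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"])
        indi = pd.DataFrame(indi_rows, columns=["primaryid", "indi_pt"])
        return cls(demo, drug, reac, indi)

    def to_records(self) -> list[ReportRecord]:
        drugs_by_id: dict[int, list[tuple[str, str]]] = {}
        for pid, name, role in self.drug[["primaryid", "drugname", "role_cod"]].itertuples(index=False):
            drugs_by_id.setdefault(pid, []).append((name, role))
        events_by_id: dict[int, list[str]] = {}
        for pid, pt in self.reac.itertuples(index=False):
            events_by_id.setdefault(pid, []).append(pt)
        indi_by_id = dict(self.indi.itertuples(index=False))
        records = []
        for row in self.demo.itertuples(index=False):
            records.append(
                ReportRecord(
                    primaryid=row.primaryid,
                    caseid=row.caseid,
                    version=row.caseversion,
                    drugs=drugs_by_id.get(row.primaryid, []),
                    events=events_by_id.get(row.primaryid, []),
                    indication=indi_by_id.get(row.primaryid, "other"),
                    sex=row.sex,
                    age_band=row.age_band,
                    weight_band=row.weight_band,
                    country=row.country,
                    reporter_type=row.reporter_type,
                    quarter=row.quarter,
                )
            )
        return records

    # -- operations ------------------------------------------------------
    def deduplicate(self) -> "ReportDatabase":
        """Keep one report per case: highest version, ties by highest primaryid."""
        demo = self.demo.sort_values(["caseid", "caseversion", "primaryid"])
        keep = demo.groupby("caseid", sort=False).tail(1)
        keep = keep.sort_values("primaryid").reset_index(drop=True)
        ids = set(keep["primaryid"])
        return ReportDatabase(
            demo=keep,
            drug=self.drug[self.drug["primaryid"].isin(ids)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(ids)].reset_index(drop=True),
            indi=self.indi[self.indi["primaryid"].isin(ids)].reset_index(drop=True),
        )

    def subset(self, primaryids: Sequence[int]) -> "ReportDatabase":
        ids = set(primaryids)
        return ReportDatabase(
            demo=self.demo[self.demo["primaryid"].isin(ids)].reset_index(drop=True),
            drug=self.drug[self.drug["primaryid"].isin(ids)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(ids)].reset_index(drop=True),
            indi=self.indi[self.indi["primaryid"].isin(ids)].reset_index(drop=True),
        )

    # -- I/O -------------------------------------------------------------
    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, directory: str | Path) -> "ReportDatabase":
        directory = Path(directory)
        frames = {name: pd.read_csv(directory / f"{name}.csv") for name in _TABLES}
        return cls(**frames)


def deduplicate(reports):
    """Deduplicate a :class:`ReportDatabase` or a list of :class:`ReportRecord`.

    Exactly one record per case survives: the one with the highest version,
    ties broken by the highest ``primaryid``.  Output order is deterministic
    (ascending ``primaryid``).
    """
    if isinstance(reports, ReportDatabase):
        return reports.deduplicate()
    best: dict[int, ReportRecord] = {}
    for rec in reports:
        cur = best.get(rec.caseid)
        if cur is None or (rec.version, rec.primaryid) > (cur.version, cur.primaryid):
            best[rec.caseid] = rec
    return sorted(best.values(), key=lambda r: r.primaryid)
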