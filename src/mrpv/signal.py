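"""Disproportionality analysis of spontaneous-report databases.

The reporting odds ratio (ROR) compares the odds of a target event set being
reported for a target drug against the reporting odds for all other drugs in
the (possibly stratified) database.  From the report-level 2x2 table

    a = target drug & target events     b = target drug & other events only
    c = other drugs & target events     d = other drugs & other events only

the estimate is ROR = ad / bc with Woolf standard error
SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d) and Wald confidence limits on the
log scale.  The signal criterion is the standard one: at least three target
cases and a lower 95% confidence limit above 1.

Reports count once per event set (a report listing two member PTs is a
single case); a report supports the target-drug margin only through a
primary-suspect (PS) role, while SS/C roles leave it in the comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnknownTermError, ZeroCellError
from .faers import ReportDatabase
from .hierarchy import LEVELS, TermHierarchy

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "ScreenResults",
    "ControlCheck",
    "ror",
    "rollup_events",
    "screen",
    "control_validation",
    "describe",
    "DisproportionalityScreen",
]


@dataclass
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    stratum: str = "all"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalResult:
    drug: str
    event_set: str
    level: str
    stratum: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ci_low: float
    ci_high: float
    is_signal: bool
    evaluable: bool = True
    note: str = ""

    @property
    def n_cases(self) -> int:
        return self.a


def ror(
    table: ContingencyTable,
    alpha: float = 0.05,
    correction: str = "none",
    drug: str = "drug",
    event_set: str = "event",
    level: str = "PT",
    min_cases: int = 3,
) -> SignalResult:
    """Reporting odds ratio with Wald CI and the a>=3 & lower-CI>1 criterion.

    ``correction="haldane"`` adds 0.5 to every cell whenever any cell is
    zero; with ``correction="none"`` a zero cell raises :class:`ZeroCellError`.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if correction == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        elif correction == "none":
            raise ZeroCellError(
                f"zero cell in 2x2 table (a={table.a}, b={table.b}, c={table.c}, "
                f"d={table.d}); request the Haldane correction to evaluate it"
            )
        else:
            raise ValueError(f"unknown correction {correction!r}")
    estimate = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = float(np.exp(np.log(estimate) - z * se))
    ci_high = float(np.exp(np.log(estimate) + z * se))
    return SignalResult(
        drug=drug,
        event_set=event_set,
        level=level,
        stratum=table.stratum,
        a=table.a,
        b=table.b,
        c=table.c,
        d=table.d,
        ror=float(estimate),
        ci_low=ci_low,
        ci_high=ci_high,
        is_signal=bool(table.a >= min_cases and ci_low > 1.0),
    )


def _case_pairs(
    db: ReportDatabase, hierarchy: TermHierarchy, level: str, scope: str
) -> pd.DataFrame:
    """Unique (primaryid, event_set) pairs after rolling PTs up to ``level``.

    ``level`` is one of PT/HLT/HLGT/SOC, or the name of an SMQ, in which case
    ``scope`` selects the narrow or broad PT set.
    """
    reac = db.reac
    unknown = set(reac["pt"]) - hierarchy.pts()
    if unknown:
        raise UnknownTermError(f"unknown preferred terms in reports: {sorted(unknown)[:5]}")
    if level in LEVELS:
        mapped = reac.assign(event_set=reac["pt"].map(hierarchy.rollup_map(level)))
    elif level in hierarchy.smq:
        members = hierarchy.smq_members(level, scope)
        mapped = reac[reac["pt"].isin(members)].assign(event_set=level)
    else:
        raise ValueError(f"{level!r} is neither a hierarchy level nor a known SMQ")
    return mapped[["primaryid", "event_set"]].drop_duplicates()


def rollup_events(
    db: ReportDatabase, hierarchy: TermHierarchy, level: str, scope: str = "narrow"
) -> dict[int, frozenset]:
    """Event set per report at the requested level (or SMQ membership).

    Every report appears in the result; reports with no event at the level
    (possible only for SMQ membership) map to the empty set.
    """
    pairs = _case_pairs(db, hierarchy, level, scope)
    sets = pairs.groupby("primaryid")["event_set"].agg(frozenset).to_dict()
    return {pid: sets.get(pid, frozenset()) for pid in db.demo["primaryid"]}


@dataclass
class ScreenResults:
    """Outcome of a disproportionality screen: one row per (target, event
    set, stratum), plus the number of tests performed for post-filtering."""

    results: list[SignalResult]
    level: str
    scope: str
    stratum: str
    n_tests: int = 0

    def __post_init__(self) -> None:
        if not self.n_tests:
            self.n_tests = sum(r.evaluable for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": r.drug,
                "event_set": r.event_set,
                "level": r.level,
                "stratum": r.stratum,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_cases": r.n_cases,
                "is_signal": r.is_signal,
                "evaluable": r.evaluable,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def signals(self) -> list[SignalResult]:
        return [r for r in self.results if r.is_signal]

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            f"Disproportionality screen: level={self.level} scope={self.scope} "
            f"stratum={self.stratum}",
            f"{len(frame)} event sets tested ({self.n_tests} evaluable), "
            f"{int(frame['is_signal'].sum())} signals",
            frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def _target_mask(db: ReportDatabase, targets: Sequence[str]) -> pd.Series:
    """Reports whose primary-suspect drug is one of ``targets`` (matched by
    drug name or by therapeutic class)."""
    targets = set(targets)
    ps = db.drug[db.drug["role_cod"] == "PS"]
    hit = ps[ps["drugname"].isin(targets) | ps["drug_class"].isin(targets)]
    flagged = set(hit["primaryid"])
    return db.demo["primaryid"].isin(flagged)


def screen(
    db: ReportDatabase,
    hierarchy: TermHierarchy,
    targets: Sequence[str],
    level: str = "SOC",
    scope: str = "narrow",
    event_sets: Sequence[str] | None = None,
    stratum: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    correction: str = "none",
    dedup: bool = True,
    min_cases: int = 3,
) -> ScreenResults:
    """Screen the database for disproportionality signals.

    ``level`` selects either a hierarchy level (one test per term at that
    level) or ``"SMQ"`` (one test per SMQ, restricted to ``event_sets`` when
    given).  ``stratum`` filters the database before the 2x2 tables are
    built -- keys ``indication`` and ``sex`` are supported -- so the
    comparator is the same-stratum remainder of the database.  Strata with
    no target-drug report yield not-evaluable results, not exceptions.
    """
    if dedup:
        db = db.deduplicate()
    label = "all"
    if stratum:
        keep = pd.Series(True, index=db.demo.index)
        for key, value in stratum.items():
            if key == "sex":
                keep &= (db.demo["sex"] == value).to_numpy()
            elif key == "indication":
                ids = set(db.indi.loc[db.indi["indi_pt"] == value, "primaryid"])
                keep &= db.demo["primaryid"].isin(ids).to_numpy()
            else:
                raise ValueError(f"unsupported stratum key {key!r}")
        db = db.subset(db.demo.loc[keep, "primaryid"])
        label = ",".join(f"{k}={v}" for k, v in sorted(stratum.items()))

    if level == "SMQ":
        names = list(event_sets) if event_sets else sorted(hierarchy.smq)
        pair_frames = [_case_pairs(db, hierarchy, name, scope) for name in names]
        pairs = pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame(
            columns=["primaryid", "event_set"]
        )
        sets = names
        out_level = "SMQ"
    else:
        pairs = _case_pairs(db, hierarchy, level, scope)
        sets = sorted(event_sets) if event_sets else sorted(hierarchy.terms(level))
        out_level = level

    is_target = _target_mask(db, targets)
    target_ids = set(db.demo.loc[is_target, "primaryid"])
    n_target = len(target_ids)
    n_other = db.n_reports - n_target
    drug_label = "+".join(targets)

    pairs = pairs.assign(is_target=pairs["primaryid"].isin(target_ids))
    counts = pairs.groupby(["event_set", "is_target"]).size().unstack(fill_value=0)

    results = []
    for name in sets:
        a = int(counts.at[name, True]) if name in counts.index and True in counts.columns else 0
        c = int(counts.at[name, False]) if name in counts.index and False in counts.columns else 0
        table = ContingencyTable(a=a, b=n_target - a, c=c, d=n_other - c, stratum=label)
        try:
            res = ror(
                table,
                alpha=alpha,
                correction=correction,
                drug=drug_label,
                event_set=name,
                level=out_level,
                min_cases=min_cases,
            )
        except ZeroCellError as exc:
            res = SignalResult(
                drug=drug_label,
                event_set=name,
                level=out_level,
                stratum=label,
                a=table.a,
                b=table.b,
                c=table.c,
                d=table.d,
                ror=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                is_signal=False,
                evaluable=False,
                note=str(exc),
            )
        results.append(res)
    return ScreenResults(results=results, level=out_level, scope=scope, stratum=label)


@dataclass
class ControlCheck:
    drug: str
    event_set: str
    expected_signal: bool
    observed_signal: bool

    @property
    def ok(self) -> bool:
        return self.expected_signal == self.observed_signal


@dataclass
class ControlValidationReport:
    checks: list[ControlCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.checks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug": c.drug,
                    "event_set": c.event_set,
                    "expected_signal": c.expected_signal,
                    "observed_signal": c.observed_signal,
                    "ok": c.ok,
                }
                for c in self.checks
            ]
        )


def control_validation(
    db: ReportDatabase,
    hierarchy: TermHierarchy,
    controls: Mapping[str, Mapping[str, bool]],
    scope: str = "narrow",
    **screen_kwargs,
) -> ControlValidationReport:
    """Check internal database consistency against control drugs.

    ``controls`` maps a control drug (or class) to ``{smq_name: expected}``,
    where ``expected`` is True for a positive control (the SMQ should
    signal) and False for a negative control.  Failures emit a warning and
    are reported, not raised.
    """
    report = ControlValidationReport()
    for drug_name, expectations in controls.items():
        if not expectations:
            continue
        res = screen(
            db,
            hierarchy,
            targets=[drug_name],
            level="SMQ",
            scope=scope,
            event_sets=sorted(expectations),
            **screen_kwargs,
        )
        observed = {r.event_set: r.is_signal for r in res.results}
        for event_set, expected in expectations.items():
            check = ControlCheck(
                drug=drug_name,
                event_set=event_set,
                expected_signal=bool(expected),
                observed_signal=bool(observed.get(event_set, False)),
            )
            if not check.ok:
                warnings.warn(
                    f"control validation failed: {drug_name}/{event_set} expected "
                    f"signal={expected}, observed {check.observed_signal}",
                    stacklevel=2,
                )
            report.checks.append(check)
    return report


_DESCRIBE_FIELDS = ("sex", "age_band", "weight_band", "reporter_type", "country", "quarter")


def describe(db: ReportDatabase, dedup: bool = True) -> dict[str, pd.DataFrame]:
    """Descriptive counts and percentages per demographic field."""
    if dedup:
        db = db.deduplicate()
    total = db.n_reports
    out = {}
    for column in _DESCRIBE_FIELDS:
        counts = db.demo[column].value_counts()
        out[column] = pd.DataFrame(
            {"count": counts, "pct": (100.0 * counts / total).round(2)}
        ).rename_axis(column)
    out["n_reports"] = total
    return out


class DisproportionalityScreen:
    """Model-style wrapper: build from a database + hierarchy, ``fit`` a screen.

    ``fit`` accepts the same keyword arguments as :func:`screen` and returns
    a :class:`ScreenResults` carrying estimates, intervals and verdicts with
    a ``summary()`` table.
    """

    def __init__(self, db: ReportDatabase, hierarchy: TermHierarchy):
        self.db = db
        self.hierarchy = hierarchy

    def fit(self, targets: Sequence[str], **kwargs) -> ScreenResults:
        return screen(self.db, self.hierarchy, targets, **kwargs)

    def describe(self) -> dict[str, pd.DataFrame]:
        return describe(self.db)
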