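"""Explore/compare tabulations: per-setting disaggregated views and
cross-setting benchmark tables.

These functions produce the *data* behind the two kinds of equity
visuals: horizontal bar charts of subgroup estimates within one setting
(with optional median / setting-average reference lines, sorting and
highlighting) and scatter-ready tables pairing each setting's average
with a chosen summary measure for benchmarking against peers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .measures import Stratum, compute_stratum, setting_average
from .template_io import Dataset, stratify

__all__ = [
    "BarRow",
    "BarTable",
    "CompareRow",
    "CompareTable",
    "TrendTables",
    "compare_table",
    "detailed_bar_table",
    "trend_table",
    "write_bar_table",
    "write_compare_table",
]


@dataclass(frozen=True)
class BarRow:
    subgroup: str
    estimate: float
    ci_lb: Optional[float] = None
    ci_ub: Optional[float] = None
    highlighted: bool = False


@dataclass
class BarTable:
    rows: list[BarRow]
    median: Optional[float] = None
    setting_average: Optional[float] = None
    sort: tuple[str, str] = ("name", "asc")
    axis_range: Optional[tuple[float, float]] = None
    titles: Optional[tuple[str, str]] = None

    @property
    def estimates(self) -> list[float]:
        return [r.estimate for r in self.rows]


@dataclass
class TrendTables:
    """One bar table per available year, ascending; gaps are not interpolated."""

    tables: list[tuple[int, BarTable]]
    diagnostic: Optional[str] = None

    @property
    def years(self) -> list[int]:
        return [y for y, _ in self.tables]


@dataclass(frozen=True)
class CompareRow:
    setting: str
    iso3: Optional[str]
    setting_average: Optional[float]
    measure_value: float
    year: int


@dataclass
class CompareTable:
    measure: str
    rows: list[CompareRow]
    benchmark_filter: Optional[str] = None
    notes: list[str] = field(default_factory=list)


def detailed_bar_table(stratum: Stratum,
                       sort_by: str = "name",
                       direction: str = "asc",
                       show_median: bool = False,
                       show_average: bool = False,
                       highlight: Sequence[str] = (),
                       axis_range: Optional[tuple[float, float]] = None,
                       titles: Optional[tuple[str, str]] = None) -> BarTable:
    """Bar-graph table for one stratum: one bar per subgroup.

    ``sort_by`` is ``"name"`` or ``"estimate"``; sorting is stable so
    equal estimates keep alphabetical name order.  The median reference
    line is the exact median of the plotted estimates (midpoint of the
    two central values for even counts); the setting-average line uses
    the reported average when supplied, else the population-weighted
    mean.  Unknown names in ``highlight`` raise a ValueError listing the
    valid subgroup names.
    """
    if sort_by not in ("name", "estimate"):
        raise ValueError(f"sort_by must be 'name' or 'estimate', got {sort_by!r}")
    if direction not in ("asc", "desc"):
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")

    valid = {g.name for g in stratum.subgroups}
    unknown = [h for h in highlight if h not in valid]
    if unknown:
        raise ValueError(f"unknown subgroup(s) {unknown}; valid names: {sorted(valid)}")

    groups = sorted(stratum.subgroups, key=lambda g: g.name)
    if sort_by == "estimate":
        groups = sorted(groups, key=lambda g: g.estimate)  # stable: name order kept on ties
    if direction == "desc":
        groups = groups[::-1]

    rows = [BarRow(g.name, g.estimate, g.ci_lb, g.ci_ub, g.name in set(highlight))
            for g in groups]
    return BarTable(
        rows=rows,
        median=float(np.median([g.estimate for g in stratum.subgroups])) if show_median else None,
        setting_average=setting_average(stratum) if show_average else None,
        sort=(sort_by, direction),
        axis_range=axis_range,
        titles=titles,
    )


def trend_table(dataset: Dataset, setting: str, indicator_abbr: str,
                dimension: str, **bar_options) -> TrendTables:
    """Bar tables for one setting x indicator x dimension across years.

    Years without a stratum are simply absent.  If the same year is
    covered by several sources, the alphabetically first source is used
    and noted in the diagnostic.
    """
    matching = [s for s in stratify(dataset)
                if s.key.setting == setting
                and s.key.indicator_abbr == indicator_abbr
                and s.key.dimension == dimension]
    if not matching:
        return TrendTables([], diagnostic=(
            f"no strata for setting={setting!r}, indicator={indicator_abbr!r}, "
            f"dimension={dimension!r}"))

    by_year: dict[int, Stratum] = {}
    notes = []
    for s in sorted(matching, key=lambda s: (s.key.year, s.key.source)):
        if s.key.year in by_year:
            notes.append(f"year {s.key.year}: multiple sources, using "
                         f"{by_year[s.key.year].key.source!r}")
            continue
        by_year[s.key.year] = s
    tables = [(year, detailed_bar_table(by_year[year], **bar_options))
              for year in sorted(by_year)]
    return TrendTables(tables, diagnostic="; ".join(notes) or None)


def _passes(tags: Mapping[str, object], flt: Mapping[str, object]) -> bool:
    for key, wanted in flt.items():
        have = tags.get(key)
        if isinstance(wanted, (set, frozenset, list, tuple)):
            if have not in wanted:
                return False
        elif have != wanted:
            return False
    return True


def compare_table(dataset: Dataset, measure: str, indicator_abbr: str,
                  dimension: str,
                  metadata: Optional[Mapping[str, Mapping[str, object]]] = None,
                  benchmark_filter: Optional[Mapping[str, object]] = None
                  ) -> CompareTable:
    """Benchmark table: one row per setting pairing its average with a measure.

    For each setting the latest year with a complete stratum for the
    chosen indicator x dimension is used.  ``metadata`` is an optional
    side table of tags per setting (e.g. region, income group) and
    ``benchmark_filter`` keeps only settings whose tags match (a filter
    value may be a single value or a collection of allowed values).
    Settings where the measure is unavailable are omitted with a note.
    """
    strata = [s for s in stratify(dataset)
              if s.key.indicator_abbr == indicator_abbr
              and s.key.dimension == dimension]
    notes: list[str] = []
    latest: dict[str, Stratum] = {}
    for s in sorted(strata, key=lambda s: (s.key.setting, s.key.year, s.key.source)):
        cur = latest.get(s.key.setting)
        if cur is None or s.key.year > cur.key.year:
            latest[s.key.setting] = s

    rows: list[CompareRow] = []
    for setting in sorted(latest):
        if benchmark_filter:
            tags = (metadata or {}).get(setting, {})
            if not _passes(tags, benchmark_filter):
                continue
        stratum = latest[setting]
        res = compute_stratum(stratum)
        try:
            value = res.value(measure)
        except KeyError:
            reason = res.skipped.get(measure, "not applicable to this stratum")
            notes.append(f"{setting}: {measure} unavailable ({reason})")
            continue
        rows.append(CompareRow(setting=setting,
                               iso3=_setting_iso3(dataset, setting),
                               setting_average=setting_average(stratum),
                               measure_value=value,
                               year=stratum.key.year))
    flt_desc = None
    if benchmark_filter:
        flt_desc = ", ".join(f"{k}={v}" for k, v in sorted(benchmark_filter.items(),
                                                           key=lambda kv: kv[0]))
    if not rows:
        notes.append("no settings matched the benchmark filter")
    return CompareTable(measure=measure, rows=rows, benchmark_filter=flt_desc, notes=notes)


def _setting_iso3(dataset: Dataset, setting: str) -> Optional[str]:
    for row in dataset.rows:
        if row.setting == setting and row.iso3:
            return row.iso3
    return None


# ---------------------------------------------------------------------------
# writers (graph-ready data downloads)
# ---------------------------------------------------------------------------

def _write_rows(path: Union[str, Path], header: list[str], rows: list[list],
                delimiter: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        writer.writerows(rows)


def write_bar_table(table: BarTable, path: Union[str, Path], tsv: bool = False) -> None:
    rows = [[r.subgroup, r.estimate,
             "" if r.ci_lb is None else r.ci_lb,
             "" if r.ci_ub is None else r.ci_ub,
             int(r.highlighted)] for r in table.rows]
    _write_rows(path, ["subgroup", "estimate", "ci_lb", "ci_ub", "highlighted"],
                rows, "\t" if tsv else ",")


def write_compare_table(table: CompareTable, path: Union[str, Path],
                        tsv: bool = False) -> None:
    rows = [[r.setting, r.iso3 or "", r.year,
             "" if r.setting_average is None else r.setting_average,
             r.measure_value] for r in table.rows]
    _write_rows(path, ["setting", "iso3", "year", "setting_average", table.measure],
                rows, "\t" if tsv else ",")
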