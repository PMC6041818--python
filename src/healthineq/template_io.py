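"""Read, validate and partition disaggregated-data template files.

The upload template has one row per setting x year x source x indicator
x dimension x subgroup.  Thirteen variables are mandatory (the row
identifiers, the subgroup estimate, and the five control flags that
steer measure computation: favourable_indicator, indicator_scale,
ordered_dimension, subgroup_order, reference_subgroup).  The
recommended variables (se, population, setting_average, iso3) unlock
weighted and regression-based measures; the optional ones (95% CI
bounds, flag) only annotate tables.

Files may be CSV (UTF-8, comma-delimited, header first) or Excel
(.xlsx via openpyxl; legacy .xls only when xlrd is installed).  Header
matching is case-insensitive and whitespace-trimmed; ``95ci_lb`` /
``ci_lb`` are accepted as aliases.  Empty cells, ``""`` and ``NA`` are
the only missing-value sentinels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .measures import Stratum, StratumKey, Subgroup

__all__ = [
    "CANONICAL_COLUMNS",
    "MANDATORY_COLUMNS",
    "Dataset",
    "ObservationRow",
    "TemplateError",
    "UnsupportedFormatError",
    "ValidationIssue",
    "ValidationReport",
    "load_dataset",
    "read_table",
    "stratify",
    "validate",
    "write_dataset",
]

# canonical template order: mandatory, recommended, optional
MANDATORY_COLUMNS = (
    "setting", "year", "source", "indicator_abbr", "indicator_name",
    "dimension", "subgroup", "estimate", "favourable_indicator",
    "indicator_scale", "ordered_dimension", "subgroup_order",
    "reference_subgroup",
)
RECOMMENDED_COLUMNS = ("se", "population", "setting_average", "iso3")
OPTIONAL_COLUMNS = ("ci_lb", "ci_ub", "flag")
CANONICAL_COLUMNS = MANDATORY_COLUMNS + RECOMMENDED_COLUMNS + OPTIONAL_COLUMNS

# header written on output for fields whose canonical template spelling
# starts with a digit (hostile to many tools, hence also aliased on input)
_OUTPUT_HEADER = {"ci_lb": "95ci_lb", "ci_ub": "95ci_ub"}
_ALIASES = {"95ci_lb": "ci_lb", "95ci_ub": "ci_ub"}

_MISSING_SENTINELS = {"", "NA"}


class TemplateError(Exception):
    """File-level problem: unreadable file, bad header, unknown format."""


class UnsupportedFormatError(TemplateError):
    pass


@dataclass(frozen=True)
class ObservationRow:
    """One validated template row: a subgroup estimate in context."""

    setting: str
    year: int
    source: str
    indicator_abbr: str
    indicator_name: str
    dimension: str
    subgroup: str
    estimate: float
    favourable_indicator: int
    indicator_scale: float
    ordered_dimension: int
    subgroup_order: int
    reference_subgroup: int
    se: Optional[float] = None
    population: Optional[float] = None
    setting_average: Optional[float] = None
    iso3: Optional[str] = None
    ci_lb: Optional[float] = None
    ci_ub: Optional[float] = None
    flag: Optional[str] = None

    @property
    def stratum_key(self) -> StratumKey:
        return StratumKey(self.setting, self.year, self.source,
                          self.indicator_abbr, self.dimension)


@dataclass(frozen=True)
class ValidationIssue:
    row: Optional[int]      # 0-based data-row index; None for dataset scope
    column: Optional[str]
    code: str
    message: str

    def to_json(self) -> str:
        return json.dumps({"row": self.row, "column": self.column,
                           "code": self.code, "message": self.message})


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.errors

    def error_codes(self) -> set[str]:
        return {e.code for e in self.errors}

    def warning_codes(self) -> set[str]:
        return {w.code for w in self.warnings}

    def to_json_lines(self) -> str:
        lines = [json.dumps({"severity": "error", "row": e.row, "column": e.column,
                             "code": e.code, "message": e.message})
                 for e in self.errors]
        lines += [json.dumps({"severity": "warning", "row": w.row, "column": w.column,
                              "code": w.code, "message": w.message})
                  for w in self.warnings]
        return "\n".join(lines)

    def to_text(self) -> str:
        out = [f"accepted: {self.accepted} "
               f"({len(self.errors)} errors, {len(self.warnings)} warnings)"]
        for e in self.errors:
            where = f"row {e.row}" if e.row is not None else "dataset"
            col = f", column {e.column}" if e.column else ""
            out.append(f"ERROR   [{e.code}] {where}{col}: {e.message}")
        for w in self.warnings:
            where = f"row {w.row}" if w.row is not None else "dataset"
            out.append(f"WARNING [{w.code}] {where}: {w.message}")
        return "\n".join(out)


@dataclass
class Dataset:
    """A named, validated collection of observation rows."""

    name: str
    rows: list[ObservationRow]
    report: ValidationReport = field(default_factory=ValidationReport)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _normalise_header(names: Iterable[str]) -> list[str]:
    out = []
    for raw in names:
        name = (raw or "").strip().lower()
        out.append(_ALIASES.get(name, name))
    return out


def _records_from_grid(header_row: list, data_rows: Iterable[list]) -> list[dict[str, str]]:
    header = _normalise_header(str(h) if h is not None else "" for h in header_row)
    if not any(header):
        raise TemplateError("missing header row")
    seen: set[str] = set()
    for name in header:
        if name and name in seen:
            raise TemplateError(f"duplicated header name: {name!r}")
        seen.add(name)
    records = []
    for cells in data_rows:
        if all(c is None or str(c).strip() == "" for c in cells):
            continue  # skip fully blank lines
        rec = {}
        for name, cell in zip(header, cells):
            if not name:
                continue
            rec[name] = _cell_to_text(cell)
        for name in header[len(cells):]:
            if name:
                rec[name] = ""
        records.append(rec)
    return records


def _cell_to_text(cell) -> str:
    if cell is None:
        return ""
    if isinstance(cell, float):
        return repr(cell)
    return str(cell).strip()


def read_table(path: Union[str, Path], fmt: str = "auto") -> list[dict[str, str]]:
    """Read a template file into raw text records keyed by canonical column name.

    Unknown columns are preserved in the records (and ignored by
    validation).  Raises :class:`TemplateError` on unreadable files,
    unsupported formats, a missing header row or duplicated headers.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "xls", "xlsx"):
        raise UnsupportedFormatError(f"unsupported format {fmt!r}: use csv, xls or xlsx")
    if not path.exists():
        raise TemplateError(f"file not found: {path}")

    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        if not rows:
            raise TemplateError("missing header row (empty file)")
        return _records_from_grid(rows[0], rows[1:])

    if fmt == "xlsx":
        from openpyxl import load_workbook
        wb = load_workbook(path, read_only=True, data_only=True)
        ws = wb.worksheets[0]
        grid = [list(r) for r in ws.iter_rows(values_only=True)]
        wb.close()
    else:  # xls
        try:
            import xlrd
        except ImportError as exc:  # pragma: no cover
            raise UnsupportedFormatError(
                "legacy .xls files need the xlrd package; convert to .xlsx or .csv"
            ) from exc
        book = xlrd.open_workbook(str(path))
        sheet = book.sheet_by_index(0)
        grid = [sheet.row_values(i) for i in range(sheet.nrows)]
    if not grid:
        raise TemplateError("missing header row (empty file)")
    return _records_from_grid(grid[0], grid[1:])


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _missing(value: Optional[str]) -> bool:
    return value is None or value.strip() in _MISSING_SENTINELS


def _parse_float(text: str) -> float:
    return float(text.strip())


def _parse_int(text: str) -> int:
    v = float(text.strip())
    if v != int(v):
        raise ValueError(f"not an integer: {text!r}")
    return int(v)


def validate(raw_rows: list[dict[str, str]], name: str = "dataset"
             ) -> Union[Dataset, ValidationReport]:
    """Validate raw records against the template contract.

    Returns a :class:`Dataset` (carrying its report with any warnings)
    when there are no errors, otherwise the :class:`ValidationReport`.
    Template violations are errors; missing recommended variables are
    warnings only.  Never raises on bad data values.
    """
    report = ValidationReport()
    err = report.errors.append
    warn = report.warnings.append

    if not raw_rows:
        err(ValidationIssue(None, None, "empty_dataset", "no data rows"))
        return report

    parsed: list[Optional[ObservationRow]] = []
    for i, rec in enumerate(raw_rows):
        parsed.append(_parse_row(i, rec, err))

    # stratum-level checks on rows that parsed cleanly
    strata: dict[StratumKey, list[tuple[int, ObservationRow]]] = {}
    for i, row in enumerate(parsed):
        if row is not None:
            strata.setdefault(row.stratum_key, []).append((i, row))

    for key, members in strata.items():
        _check_stratum(key, members, err, warn)

    # availability warnings for recommended variables
    ok_rows = [r for r in parsed if r is not None]
    if ok_rows:
        for col, code in (("se", "no_se"), ("population", "no_population"),
                          ("setting_average", "no_setting_average")):
            n_missing = sum(1 for r in ok_rows if getattr(r, col) is None)
            if n_missing:
                extent = "all" if n_missing == len(ok_rows) else "some"
                warn(ValidationIssue(None, col, code,
                                     f"{col} missing for {extent} observations "
                                     f"({n_missing}/{len(ok_rows)})"))
        if any(r.population is None for r in ok_rows):
            warn(ValidationIssue(None, "population", "unweighted_only",
                                 "only unweighted summary measures can be "
                                 "calculated where population is missing"))

    if not report.accepted:
        return report
    return Dataset(name=name, rows=[r for r in parsed if r is not None], report=report)


def _parse_row(i: int, rec: dict[str, str], err) -> Optional[ObservationRow]:
    vals: dict[str, object] = {}
    ok = True

    def fail(column: str, code: str, message: str) -> None:
        nonlocal ok
        ok = False
        err(ValidationIssue(i, column, code, message))

    for col in MANDATORY_COLUMNS:
        if _missing(rec.get(col)):
            fail(col, "missing_mandatory", f"mandatory variable {col!r} is missing")
    if not ok:
        return None

    for col in ("setting", "source", "indicator_abbr", "indicator_name",
                "dimension", "subgroup"):
        vals[col] = rec[col].strip()

    try:
        vals["year"] = _parse_int(rec["year"])
    except ValueError:
        fail("year", "bad_value", f"year must be an integer, got {rec['year']!r}")
    try:
        vals["estimate"] = _parse_float(rec["estimate"])
    except ValueError:
        fail("estimate", "bad_value", f"estimate must be numeric, got {rec['estimate']!r}")
    try:
        scale = _parse_float(rec["indicator_scale"])
        if scale <= 0:
            fail("indicator_scale", "bad_value", "indicator_scale must be > 0")
        vals["indicator_scale"] = scale
    except ValueError:
        fail("indicator_scale", "bad_value",
             f"indicator_scale must be numeric, got {rec['indicator_scale']!r}")

    try:
        fav = _parse_int(rec["favourable_indicator"])
        if fav not in (0, 1):
            fail("favourable_indicator", "bad_favourable_flag",
                 "favourable_indicator must be 1 for favourable and 0 for adverse "
                 f"indicators, got {fav}")
        vals["favourable_indicator"] = fav
    except ValueError:
        fail("favourable_indicator", "bad_favourable_flag",
             f"favourable_indicator must be 0 or 1, got {rec['favourable_indicator']!r}")

    try:
        ordered = _parse_int(rec["ordered_dimension"])
        if ordered not in (0, 1):
            fail("ordered_dimension", "bad_ordered_flag",
                 f"ordered_dimension must be 0 or 1, got {ordered}")
        vals["ordered_dimension"] = ordered
    except ValueError:
        ordered = None
        fail("ordered_dimension", "bad_ordered_flag",
             f"ordered_dimension must be 0 or 1, got {rec['ordered_dimension']!r}")

    try:
        order = _parse_int(rec["subgroup_order"])
        if order < 0:
            fail("subgroup_order", "bad_subgroup_order", "subgroup_order must be >= 0")
        vals["subgroup_order"] = order
    except ValueError:
        order = None
        fail("subgroup_order", "bad_subgroup_order",
             f"subgroup_order must be an integer, got {rec['subgroup_order']!r}")

    try:
        ref = _parse_int(rec["reference_subgroup"])
        if ref not in (0, 1):
            fail("reference_subgroup", "bad_reference_subgroup",
                 f"reference_subgroup must be 0 or 1, got {ref}")
        vals["reference_subgroup"] = ref
    except ValueError:
        ref = None
        fail("reference_subgroup", "bad_reference_subgroup",
             f"reference_subgroup must be 0 or 1, got {rec['reference_subgroup']!r}")

    # cross-field flag consistency
    if ordered == 1:
        if order is not None and order < 1:
            fail("subgroup_order", "bad_subgroup_order",
                 "ordered dimensions need subgroup_order >= 1")
        if ref not in (None, 0):
            fail("reference_subgroup", "bad_reference_subgroup",
                 "ordered dimensions must have reference_subgroup = 0")
    elif ordered == 0:
        if order not in (None, 0):
            fail("subgroup_order", "bad_subgroup_order",
                 "non-ordered and binary dimensions must have subgroup_order = 0")

    # recommended / optional
    for col, code in (("se", "bad_value"), ("population", "bad_value"),
                      ("setting_average", "bad_value"),
                      ("ci_lb", "bad_value"), ("ci_ub", "bad_value")):
        raw = rec.get(col)
        if _missing(raw):
            vals[col] = None
            continue
        try:
            v = _parse_float(raw)
        except ValueError:
            fail(col, code, f"{col} must be numeric, got {raw!r}")
            continue
        if col == "se" and v < 0:
            fail(col, code, "se must be >= 0")
        if col == "population" and v <= 0:
            fail(col, code, "population must be > 0")
        vals[col] = v
    vals["iso3"] = None if _missing(rec.get("iso3")) else rec["iso3"].strip()
    vals["flag"] = None if _missing(rec.get("flag")) else rec["flag"].strip()

    if ok and vals.get("estimate") is not None:
        lb, ub = vals.get("ci_lb"), vals.get("ci_ub")
        est = vals["estimate"]
        if lb is not None and ub is not None and not (lb <= est <= ub):
            fail("ci_lb", "bad_ci", f"estimate {est} outside CI [{lb}, {ub}]")

    if not ok:
        return None
    return ObservationRow(**vals)  # type: ignore[arg-type]


def _check_stratum(key: StratumKey, members: list[tuple[int, ObservationRow]],
                   err, warn) -> None:
    first_idx = members[0][0]
    rows = [r for _, r in members]

    # duplicate subgroup rows break key uniqueness
    seen: dict[str, int] = {}
    for i, row in members:
        if row.subgroup in seen:
            err(ValidationIssue(i, "subgroup", "duplicate_row",
                                f"duplicate subgroup {row.subgroup!r} in stratum {key}"))
        seen[row.subgroup] = i

    if len(rows) < 2:
        err(ValidationIssue(first_idx, None, "few_subgroups",
                            f"stratum {key} has fewer than 2 subgroups"))
        return

    for col in ("favourable_indicator", "indicator_scale", "ordered_dimension"):
        if len({getattr(r, col) for r in rows}) > 1:
            err(ValidationIssue(first_idx, col, "inconsistent_stratum",
                                f"{col} varies within stratum {key}"))

    ordered = rows[0].ordered_dimension
    if ordered == 1:
        if len(rows) == 2:
            err(ValidationIssue(first_idx, "ordered_dimension", "ordered_binary",
                                "dimensions with two subgroups must have "
                                f"ordered_dimension = 0 (stratum {key})"))
        orders = sorted(r.subgroup_order for r in rows)
        if len(set(orders)) != len(orders) or (orders and orders[0] != 1):
            err(ValidationIssue(first_idx, "subgroup_order", "bad_subgroup_order",
                                "subgroup_order must be an increasing sequence of "
                                f"integers starting with 1 (stratum {key}, got {orders})"))
        elif orders != list(range(1, len(orders) + 1)):
            warn(ValidationIssue(first_idx, "subgroup_order", "subgroup_order_gaps",
                                 f"subgroup_order has gaps in stratum {key}: {orders}"))
    n_ref = sum(r.reference_subgroup for r in rows)
    if n_ref > 1:
        err(ValidationIssue(first_idx, "reference_subgroup",
                            "multiple_reference_subgroups",
                            f"stratum {key} designates {n_ref} reference subgroups; "
                            "at most one subgroup may have reference_subgroup = 1"))

    averages = {r.setting_average for r in rows if r.setting_average is not None}
    if len(averages) > 1:
        warn(ValidationIssue(first_idx, "setting_average", "inconsistent_setting_average",
                             f"setting_average varies within stratum {key}; "
                             "the first value is used"))
    pops = [r.population for r in rows]
    if any(p is None for p in pops) and any(p is not None for p in pops):
        warn(ValidationIssue(first_idx, "population", "mixed_population",
                             f"stratum {key} mixes rows with and without population; "
                             "degraded to unweighted measures"))


# ---------------------------------------------------------------------------
# stratification and persistence
# ---------------------------------------------------------------------------

def stratify(dataset: Dataset) -> list[Stratum]:
    """Partition a validated dataset into measure-ready strata.

    Subgroups are sorted by ascending subgroup_order for ordered
    dimensions (most disadvantaged first) and alphabetically otherwise.
    A dimension with exactly two subgroups is typed ``binary``.
    """
    groups: dict[StratumKey, list[ObservationRow]] = {}
    for row in dataset.rows:
        groups.setdefault(row.stratum_key, []).append(row)

    strata = []
    for key in sorted(groups):
        rows = groups[key]
        ordered = rows[0].ordered_dimension == 1
        if ordered:
            rows = sorted(rows, key=lambda r: r.subgroup_order)
        else:
            rows = sorted(rows, key=lambda r: r.subgroup)
        if len(rows) == 2:
            dim_type = "binary"
        elif ordered:
            dim_type = "ordered"
        else:
            dim_type = "nonordered"
        avg = next((r.setting_average for r in rows if r.setting_average is not None), None)
        subgroups = [Subgroup(name=r.subgroup, estimate=r.estimate, se=r.se,
                              population=r.population, order=r.subgroup_order,
                              is_reference=bool(r.reference_subgroup),
                              ci_lb=r.ci_lb, ci_ub=r.ci_ub)
                     for r in rows]
        strata.append(Stratum(key=key, dimension_type=dim_type,
                              favourable=bool(rows[0].favourable_indicator),
                              scale=rows[0].indicator_scale,
                              subgroups=subgroups,
                              setting_average_provided=avg))
    return strata


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        # integral floats drop the ".0" so CSV and Excel reads agree
        if value.is_integer() and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    return str(value)


def write_dataset(dataset: Dataset, path: Union[str, Path]) -> None:
    """Persist an accepted dataset as CSV in canonical template column order.

    Floats are rendered with full (repr) precision so that re-reading
    reproduces every field bit-identically.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_OUTPUT_HEADER.get(c, c) for c in CANONICAL_COLUMNS)
        for row in dataset.rows:
            writer.writerow(_format_cell(getattr(row, c)) for c in CANONICAL_COLUMNS)


def load_dataset(path: Union[str, Path], name: Optional[str] = None,
                 fmt: str = "auto") -> Union[Dataset, ValidationReport]:
    """Convenience: read_table then validate, naming the dataset after the file."""
    raw = read_table(path, fmt=fmt)
    return validate(raw, name=name or Path(path).stem)
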