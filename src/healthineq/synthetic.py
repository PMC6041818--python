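"""Template-valid synthetic datasets with known inequality structure.

The generator emulates the kind of disaggregated indicator data the
toolkit is used on — coverage-style indicators by place of residence,
wealth/education gradients, or district breakdowns — with a controlled
advantaged-vs-disadvantaged gap, a per-year drift, optional sampling
noise, and switches that suppress the recommended variables (se,
population, setting_average) to exercise the availability gating.

Noise-free data recover the configured structure exactly: the
difference D equals ``gap``, the ratio R equals ``(base + gap)/base``,
and every other measure matches its closed form, which makes the
generator the ground-truth oracle for the rest of the package.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .template_io import CANONICAL_COLUMNS, _OUTPUT_HEADER, _format_cell

__all__ = [
    "DimensionSpec",
    "IndicatorSpec",
    "ScenarioSpec",
    "generate_dataset",
    "write_rows_csv",
    "write_rows_xlsx",
    "write_setting_tags",
]

_DEFAULT_SUBGROUP_POOLS = {
    "binary": ["Rural", "Urban"],
    "ordered": ["Quintile {i}", ],
    "nonordered": ["Region {i}", ],
}


class IndicatorSpec(BaseModel):
    abbr: str = "anc"
    name: str = "Antenatal care coverage"
    favourable: bool = True
    scale: float = Field(100.0, gt=0)


class DimensionSpec(BaseModel):
    name: str = "Place of residence"
    type: Literal["binary", "ordered", "nonordered"] = "binary"
    subgroups: int = Field(2, ge=2)
    subgroup_names: Optional[list[str]] = None

    @model_validator(mode="after")
    def _check(self) -> "DimensionSpec":
        if self.type == "binary" and self.subgroups != 2:
            raise ValueError("binary dimensions have exactly 2 subgroups")
        if self.type != "binary" and self.subgroups < 3:
            raise ValueError(f"{self.type} dimensions need more than 2 subgroups")
        if self.subgroup_names is not None and len(self.subgroup_names) != self.subgroups:
            raise ValueError("subgroup_names length must equal subgroups")
        return self

    def names(self) -> list[str]:
        if self.subgroup_names:
            return list(self.subgroup_names)
        if self.type == "binary":
            return ["Rural", "Urban"]
        if self.type == "ordered":
            return [f"Quintile {i}" for i in range(1, self.subgroups + 1)]
        return [f"Region {chr(ord('A') + i)}" for i in range(self.subgroups)]


class ScenarioSpec(BaseModel):
    """Controls for one synthetic scenario.

    ``gap`` is the target advantaged-minus-disadvantaged difference on
    the indicator scale; ``base`` the disadvantaged (noise-free)
    level; ``trend`` an additive per-year drift; ``noise_sd`` the SD of
    Gaussian sampling noise added to each estimate (clipped to
    [0, scale]).  Populations total ``population_total`` per stratum,
    split equally or by a seeded Dirichlet draw.
    """

    settings: list[str] = ["Setting A", "Setting B"]
    years: list[int] = [2010, 2015]
    source: str = "SYN"
    indicators: list[IndicatorSpec] = [IndicatorSpec()]
    dimensions: list[DimensionSpec] = [DimensionSpec()]
    base: float = 50.0
    gap: float = 30.0
    trend: float = 0.0
    noise_sd: float = Field(0.0, ge=0)
    population_total: float = Field(10000.0, gt=0)
    population_allocation: Literal["equal", "random"] = "equal"
    emit_se: bool = True
    emit_population: bool = True
    emit_setting_average: bool = True
    emit_ci: bool = False
    reference_subgroup: Optional[str] = None  # name, for binary/non-ordered dims
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "ScenarioSpec":
        span = abs(self.trend) * (max(self.years) - min(self.years)) if self.years else 0
        for ind in self.indicators:
            top = self.base + max(self.gap, 0.0) + span
            bottom = self.base + min(self.gap, 0.0) - span
            if top > ind.scale or bottom < 0:
                raise ValueError(
                    f"infeasible scenario: noise-free estimates leave [0, {ind.scale}] "
                    f"for indicator {ind.abbr!r} (base={self.base}, gap={self.gap}, "
                    f"trend span={span})")
        return self


def _rank_fractions(dim: DimensionSpec) -> np.ndarray:
    # 0 for the most disadvantaged subgroup, 1 for the most advantaged
    return np.linspace(0.0, 1.0, dim.subgroups)


def generate_dataset(spec: ScenarioSpec) -> list[dict[str, str]]:
    """Generate raw template records for a scenario (deterministic per seed).

    Noise-free subgroup estimates are
    ``base + gap * f_j + trend * (year - first year)`` for favourable
    indicators (advantaged subgroups high) and the mirror image for
    adverse ones, with ``f_j`` the subgroup's rank fraction in [0, 1].
    The output always passes template validation; suppressing
    recommended variables only downgrades it with warnings.
    """
    rng = np.random.default_rng(spec.seed)
    y0 = min(spec.years)
    records: list[dict[str, str]] = []

    for setting_idx, setting in enumerate(spec.settings):
        iso3 = f"S{setting_idx:02d}"
        for year in spec.years:
            for ind in spec.indicators:
                for dim in spec.dimensions:
                    J = dim.subgroups
                    names = dim.names()
                    fracs = _rank_fractions(dim)
                    if spec.population_allocation == "equal":
                        shares = np.full(J, 1.0 / J)
                    else:
                        shares = rng.dirichlet(np.full(J, 5.0))
                    pops = np.round(shares * spec.population_total)
                    pops = np.maximum(pops, 1.0)
                    shares = pops / pops.sum()

                    drift = spec.trend * (year - y0)
                    if ind.favourable:
                        clean = spec.base + spec.gap * fracs + drift
                    else:
                        clean = spec.base + spec.gap * (1.0 - fracs) + drift
                    noise = rng.normal(0.0, spec.noise_sd, size=J) if spec.noise_sd > 0 \
                        else np.zeros(J)
                    est = np.clip(clean + noise, 0.0, ind.scale)
                    # fixture convention: se shrinks with the subgroup's share
                    se = spec.noise_sd / np.sqrt(shares * J)
                    avg = float(shares @ est)

                    for j in range(J):
                        ref = 0
                        if dim.type != "ordered" and spec.reference_subgroup == names[j]:
                            ref = 1
                        rec = {
                            "setting": setting,
                            "year": year,
                            "source": spec.source,
                            "indicator_abbr": ind.abbr,
                            "indicator_name": ind.name,
                            "dimension": dim.name,
                            "subgroup": names[j],
                            "estimate": float(est[j]),
                            "favourable_indicator": int(ind.favourable),
                            "indicator_scale": ind.scale,
                            "ordered_dimension": 1 if dim.type == "ordered" else 0,
                            "subgroup_order": j + 1 if dim.type == "ordered" else 0,
                            "reference_subgroup": ref,
                            "se": float(se[j]) if spec.emit_se else None,
                            "population": float(pops[j]) if spec.emit_population else None,
                            "setting_average": avg if spec.emit_setting_average else None,
                            "iso3": iso3,
                            "ci_lb": float(max(est[j] - 1.96 * se[j], 0.0))
                                     if spec.emit_ci and spec.emit_se else None,
                            "ci_ub": float(min(est[j] + 1.96 * se[j], ind.scale))
                                     if spec.emit_ci and spec.emit_se else None,
                            "flag": None,
                        }
                        records.append({k: _format_cell(v) for k, v in rec.items()})
    return records


def write_rows_csv(records: Sequence[dict[str, str]], path: Union[str, Path]) -> None:
    """Write raw records as a template CSV in canonical column order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_OUTPUT_HEADER.get(c, c) for c in CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow(rec.get(c, "") for c in CANONICAL_COLUMNS)


def write_rows_xlsx(records: Sequence[dict[str, str]], path: Union[str, Path]) -> None:
    """Write raw records as a template XLSX (numbers stored as numbers)."""
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.append([_OUTPUT_HEADER.get(c, c) for c in CANONICAL_COLUMNS])
    numeric = {"year", "estimate", "favourable_indicator", "indicator_scale",
               "ordered_dimension", "subgroup_order", "reference_subgroup",
               "se", "population", "setting_average", "ci_lb", "ci_ub"}
    for rec in records:
        row = []
        for c in CANONICAL_COLUMNS:
            text = rec.get(c, "")
            if text == "":
                row.append(None)
            elif c in numeric:
                v = float(text)
                row.append(int(v) if v == int(v) and "." not in text else v)
            else:
                row.append(text)
        ws.append(row)
    wb.save(path)


def write_setting_tags(spec: ScenarioSpec, path: Union[str, Path],
                       regions: Sequence[str] = ("South", "North"),
                       income_groups: Sequence[str] = ("low", "middle")) -> dict:
    """Side table of benchmark tags (region, income group) per setting.

    Tags cycle deterministically through the given pools; returns the
    mapping also written to CSV so tests can use it directly.
    """
    tags = {}
    rows = []
    for i, setting in enumerate(spec.settings):
        tag = {"iso3": f"S{i:02d}",
               "region": regions[i % len(regions)],
               "income_group": income_groups[i % len(income_groups)]}
        tags[setting] = tag
        rows.append([setting, tag["iso3"], tag["region"], tag["income_group"]])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["setting", "iso3", "region", "income_group"])
        writer.writerows(rows)
    return tags
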