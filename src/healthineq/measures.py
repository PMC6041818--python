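"""Summary measures of health inequality computed on one stratum.

A *stratum* is the set of subgroup estimates for one setting x year x
source x indicator x dimension — the unit on which every summary measure
is defined.  Fifteen measures are supported; which of them apply to a
given stratum depends on the dimension type (binary, ordered,
non-ordered) and on data availability:

* ``D`` and ``R`` (difference and ratio) need only the subgroup
  estimates and apply everywhere;
* all other measures are population-weighted and require the number of
  people affected/at risk in every subgroup;
* the regression-based gradient measures ``SII``/``RII`` additionally
  require a standard error for every subgroup estimate.

Absolute measures (D, PAR, SII, ACI, BGV, MDB, MDM) keep the indicator's
units; relative measures (R, PAF, RII, RCI, IDIS, IDISW, MLD, TI) are
unitless.  Following common reporting practice, PAF, RCI, IDIS and IDISW
are expressed as percentages (x100) and MLD/TI are scaled x1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "ABSOLUTE_MEASURES",
    "ALL_MEASURES",
    "RELATIVE_MEASURES",
    "MeasureResult",
    "MeasureSet",
    "Stratum",
    "StratumKey",
    "Subgroup",
    "aci_rci",
    "applicable_measures",
    "bgv",
    "compute_stratum",
    "difference",
    "idis_idisw",
    "mdb_mdm",
    "mld_theil",
    "par_paf",
    "rank_midpoints",
    "ratio",
    "setting_average",
    "sii_rii",
]

ABSOLUTE_MEASURES = ("ACI", "BGV", "D", "MDB", "MDM", "PAR", "SII")
RELATIVE_MEASURES = ("IDIS", "IDISW", "MLD", "PAF", "R", "RCI", "RII", "TI")
ALL_MEASURES = tuple(sorted(ABSOLUTE_MEASURES + RELATIVE_MEASURES))

#: reporting scale factors (value stored = raw ratio x factor)
PERCENT_SCALE = 100.0   # PAF, RCI, IDIS, IDISW
MILLE_SCALE = 1000.0    # MLD, TI


class StratumKey(NamedTuple):
    setting: str
    year: int
    source: str
    indicator_abbr: str
    dimension: str


@dataclass(frozen=True)
class Subgroup:
    """One population subgroup's estimate with its weighting data."""

    name: str
    estimate: float
    se: Optional[float] = None
    population: Optional[float] = None
    order: int = 0
    is_reference: bool = False
    ci_lb: Optional[float] = None
    ci_ub: Optional[float] = None


@dataclass
class Stratum:
    """All subgroups for one setting x year x source x indicator x dimension.

    ``dimension_type`` is ``"binary"`` (exactly two subgroups),
    ``"ordered"`` (subgroups with an inherent ranking, most disadvantaged
    first) or ``"nonordered"``.  Ordered strata must be sorted by
    ascending ``order`` and carry no reference subgroup.
    """

    key: StratumKey
    dimension_type: str  # binary | ordered | nonordered
    favourable: bool
    scale: float
    subgroups: Sequence[Subgroup]
    setting_average_provided: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.subgroups) < 2:
            raise ValueError("a stratum needs at least 2 subgroups")
        if self.dimension_type not in ("binary", "ordered", "nonordered"):
            raise ValueError(f"unknown dimension_type {self.dimension_type!r}")
        if self.dimension_type == "ordered":
            orders = [g.order for g in self.subgroups]
            if orders != sorted(orders):
                raise ValueError("ordered stratum must be sorted by ascending subgroup order")
            if any(g.is_reference for g in self.subgroups):
                raise ValueError("ordered strata cannot designate a reference subgroup")
        if sum(g.is_reference for g in self.subgroups) > 1:
            raise ValueError("at most one reference subgroup per stratum")

    # -- data availability -------------------------------------------------
    @property
    def has_population(self) -> bool:
        return all(g.population is not None for g in self.subgroups)

    @property
    def has_se(self) -> bool:
        return all(g.se is not None for g in self.subgroups)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([g.estimate for g in self.subgroups], dtype=float)

    def population_shares(self) -> Optional[np.ndarray]:
        """p_j = population_j / total population, or None if unavailable."""
        if not self.has_population:
            return None
        pop = np.array([g.population for g in self.subgroups], dtype=float)
        return pop / pop.sum()

    @property
    def reference(self) -> Optional[Subgroup]:
        for g in self.subgroups:
            if g.is_reference:
                return g
        return None


@dataclass
class MeasureResult:
    measure: str
    value: float
    weighted: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class MeasureSet:
    """Results of :func:`compute_stratum` plus the skip log."""

    results: list[MeasureResult]
    skipped: dict[str, str]

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, measure: str) -> MeasureResult:
        for r in self.results:
            if r.measure == measure:
                return r
        raise KeyError(measure)

    def value(self, measure: str) -> float:
        return self[measure].value

    @property
    def measures(self) -> set[str]:
        return {r.measure for r in self.results}


class MeasureUnavailable(Exception):
    """Raised internally when a measure cannot be computed on a stratum."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def setting_average(stratum: Stratum) -> Optional[float]:
    """The overall level mu of the indicator in the setting.

    A reported setting average supplied with the data takes precedence
    (it is the authoritative national/setting figure); otherwise mu is
    the population-weighted mean of the subgroup estimates, or None when
    populations are missing.
    """
    if stratum.setting_average_provided is not None:
        return float(stratum.setting_average_provided)
    p = stratum.population_shares()
    if p is None:
        return None
    return float(p @ stratum.estimates)


def rank_midpoints(stratum: Stratum) -> Optional[np.ndarray]:
    """Population-rank midpoints X_j for an ordered stratum.

    With subgroups ranked from most disadvantaged to most advantaged,
    X_j is the cumulative population share up to and including subgroup
    j minus half the subgroup's own share; 0 < X_1 < ... < X_J < 1.
    These are the abscissae of the concentration and gradient indices.
    """
    p = stratum.population_shares()
    if p is None:
        return None
    return np.cumsum(p) - p / 2.0


def applicable_measures(stratum: Stratum, has_population: Optional[bool] = None,
                        has_se: Optional[bool] = None) -> set[str]:
    """Which of the 15 measures apply, by dimension type and availability.

    Binary dimensions get the pairwise measures D and R, plus the impact
    measures PAR/PAF when populations are known.  Non-ordered dimensions
    with >2 subgroups add the dispersion measures; ordered dimensions
    add the concentration indices and, when standard errors are also
    present, the regression-based SII/RII.  Without population data only
    the unweighted D and R can be computed.
    """
    if has_population is None:
        has_population = stratum.has_population
    if has_se is None:
        has_se = stratum.has_se

    out = {"D", "R"}
    if not has_population:
        return out
    out |= {"PAR", "PAF"}
    # a dimension with exactly two subgroups is binary whatever its label
    if stratum.dimension_type == "nonordered" and len(stratum.subgroups) > 2:
        out |= {"BGV", "MDB", "MDM", "IDIS", "IDISW", "MLD", "TI"}
    elif stratum.dimension_type == "ordered":
        out |= {"ACI", "RCI"}
        if has_se:
            out |= {"SII", "RII"}
    return out


def _tie_break(groups: Sequence[Subgroup], want_max: bool) -> Subgroup:
    # deterministic: by estimate, ties broken alphabetically by name
    return sorted(groups, key=lambda g: (-g.estimate if want_max else g.estimate, g.name))[0]


def _extreme_pair(stratum: Stratum) -> tuple[Subgroup, Subgroup, list[str]]:
    """Numerator and denominator subgroups for D and R.

    Ordered: the most-advantaged (highest rank) vs the most-disadvantaged
    subgroup, ordered so that a positive difference means the burden
    falls on the disadvantaged.  Non-ordered/binary: extreme vs the
    designated reference subgroup if one exists, else max vs min.
    """
    notes: list[str] = []
    if stratum.dimension_type == "ordered":
        disadv = stratum.subgroups[0]
        adv = stratum.subgroups[-1]
        if stratum.favourable:
            num, den = adv, disadv
        else:
            num, den = disadv, adv
        notes.append(f"compared {num.name} vs {den.name} (rank extremes)")
        return num, den, notes

    ref = stratum.reference
    if ref is not None:
        others = [g for g in stratum.subgroups if g is not ref]
        extreme = sorted(others, key=lambda g: (-abs(g.estimate - ref.estimate), g.name))[0]
        notes.append(f"compared {extreme.name} vs reference {ref.name}")
        return extreme, ref, notes

    num = _tie_break(list(stratum.subgroups), want_max=True)
    den = _tie_break([g for g in stratum.subgroups if g is not num], want_max=False)
    notes.append(f"compared {num.name} (max) vs {den.name} (min)")
    return num, den, notes


# ---------------------------------------------------------------------------
# the 15 measures
# ---------------------------------------------------------------------------

def difference(stratum: Stratum) -> MeasureResult:
    """D: absolute gap between the two comparison subgroups."""
    num, den, notes = _extreme_pair(stratum)
    return MeasureResult("D", num.estimate - den.estimate, weighted=False, notes=notes)


def ratio(stratum: Stratum) -> MeasureResult:
    """R: ratio of the two comparison subgroups (same pair as D)."""
    num, den, notes = _extreme_pair(stratum)
    if den.estimate == 0:
        raise MeasureUnavailable("zero_denominator")
    return MeasureResult("R", num.estimate / den.estimate, weighted=False, notes=notes)


def _par_reference(stratum: Stratum) -> tuple[Subgroup, list[str]]:
    notes: list[str] = []
    if stratum.dimension_type == "ordered":
        ref = stratum.subgroups[-1]
        notes.append(f"reference: most-advantaged subgroup {ref.name}")
    elif stratum.reference is not None:
        ref = stratum.reference
        notes.append(f"reference: designated subgroup {ref.name}")
    else:
        ref = _tie_break(list(stratum.subgroups), want_max=stratum.favourable)
        notes.append(f"reference: best-performing subgroup {ref.name}")
    return ref, notes


def par_paf(stratum: Stratum, mu: Optional[float]) -> tuple[MeasureResult, MeasureResult]:
    """PAR and PAF: attainable improvement of the setting average.

    PAR is the gap between the reference subgroup (most advantaged, or
    designated, or best performing) and the setting average mu; PAF
    expresses it as a percentage of mu.  When the gap points the wrong
    way (a favourable indicator whose reference lies below the average,
    or the adverse mirror image) no improvement is attainable and both
    are truncated to zero.
    """
    if mu is None:
        raise MeasureUnavailable("setting_average_unavailable")
    ref, notes = _par_reference(stratum)
    par = ref.estimate - mu
    if (stratum.favourable and par < 0) or (not stratum.favourable and par > 0):
        par = 0.0
        notes = notes + ["truncated to 0 (reference does not improve on the average)"]
    par_res = MeasureResult("PAR", par, weighted=True, notes=notes)
    if mu <= 0:
        raise MeasureUnavailable("nonpositive_setting_average")
    paf_res = MeasureResult("PAF", PERCENT_SCALE * par / mu, weighted=True, notes=list(notes))
    return par_res, paf_res


def bgv(stratum: Stratum, mu: Optional[float]) -> MeasureResult:
    """BGV: between-group variance, sum p_j (y_j - mu)^2 (squared units)."""
    p = stratum.population_shares()
    if p is None:
        raise MeasureUnavailable("population_missing")
    if mu is None:
        raise MeasureUnavailable("setting_average_unavailable")
    y = stratum.estimates
    return MeasureResult("BGV", float(p @ (y - mu) ** 2), weighted=True)


def mdb_mdm(stratum: Stratum, mu: Optional[float]) -> tuple[MeasureResult, MeasureResult]:
    """MDB / MDM: weighted mean absolute gap from the best subgroup / mean."""
    p = stratum.population_shares()
    if p is None:
        raise MeasureUnavailable("population_missing")
    if mu is None:
        raise MeasureUnavailable("setting_average_unavailable")
    y = stratum.estimates
    best = _tie_break(list(stratum.subgroups), want_max=stratum.favourable)
    mdb = MeasureResult("MDB", float(p @ np.abs(y - best.estimate)), weighted=True,
                        notes=[f"best-performing subgroup: {best.name}"])
    mdm = MeasureResult("MDM", float(p @ np.abs(y - mu)), weighted=True)
    return mdb, mdm


def idis_idisw(stratum: Stratum, mu: Optional[float]) -> tuple[MeasureResult, MeasureResult]:
    """IDIS / IDISW: (un)weighted mean absolute deviation from mu, % of mu."""
    if mu is None:
        raise MeasureUnavailable("setting_average_unavailable")
    if mu <= 0:
        raise MeasureUnavailable("nonpositive_setting_average")
    y = stratum.estimates
    idis = MeasureResult("IDIS", float(PERCENT_SCALE * np.mean(np.abs(y - mu)) / mu),
                         weighted=False)
    p = stratum.population_shares()
    if p is None:
        raise MeasureUnavailable("population_missing")
    idisw = MeasureResult("IDISW", float(PERCENT_SCALE * (p @ np.abs(y - mu)) / mu),
                          weighted=True)
    return idis, idisw


def mld_theil(stratum: Stratum, mu: Optional[float]) -> tuple[MeasureResult, MeasureResult]:
    """MLD / TI: entropy-type relative measures, reported x1000.

    MLD = 1000 sum p_j ln(mu/y_j); TI = 1000 sum p_j (y_j/mu) ln(y_j/mu).
    Undefined when any estimate (or mu) is non-positive.
    """
    p = stratum.population_shares()
    if p is None:
        raise MeasureUnavailable("population_missing")
    if mu is None:
        raise MeasureUnavailable("setting_average_unavailable")
    if mu <= 0:
        raise MeasureUnavailable("nonpositive_setting_average")
    y = stratum.estimates
    if np.any(y <= 0):
        raise MeasureUnavailable("nonpositive_estimate")
    mld = MeasureResult("MLD", float(MILLE_SCALE * (p @ np.log(mu / y))), weighted=True)
    r = y / mu
    ti = MeasureResult("TI", float(MILLE_SCALE * (p @ (r * np.log(r)))), weighted=True)
    return mld, ti


def aci_rci(stratum: Stratum, mu: Optional[float]) -> tuple[MeasureResult, MeasureResult]:
    """ACI / RCI: concentration of the indicator along the social gradient.

    ACI = sum p_j (2 X_j - 1) y_j with X_j the population-rank midpoints
    (disadvantaged first); RCI = 100 ACI / mu.  Positive values mean the
    indicator concentrates among the advantaged.
    """
    x = rank_midpoints(stratum)
    if x is None:
        raise MeasureUnavailable("population_missing")
    p = stratum.population_shares()
    y = stratum.estimates
    aci = MeasureResult("ACI", float(p @ ((2 * x - 1) * y)), weighted=True)
    if mu is None:
        raise MeasureUnavailable("setting_average_unavailable")
    if mu <= 0:
        raise MeasureUnavailable("nonpositive_setting_average")
    rci = MeasureResult("RCI", PERCENT_SCALE * aci.value / mu, weighted=True)
    return aci, rci


def sii_rii(stratum: Stratum) -> tuple[MeasureResult, MeasureResult]:
    """SII / RII: regression-based gradient across the social hierarchy.

    Weighted least squares of the subgroup estimates on the rank
    midpoints X_j with population-share weights.  SII is the fitted
    change over the whole hierarchy, yhat(1) - yhat(0); RII is the ratio
    yhat(1)/yhat(0).  Requires population and a standard error on every
    subgroup (the se is an availability gate, not part of the point
    estimate).
    """
    if not stratum.has_se:
        raise MeasureUnavailable("se_missing")
    x = rank_midpoints(stratum)
    if x is None:
        raise MeasureUnavailable("population_missing")
    p = stratum.population_shares()
    y = stratum.estimates
    fit = sm.WLS(y, sm.add_constant(x), weights=p).fit()
    intercept, slope = fit.params
    notes = []
    if not stratum.favourable:
        notes.append("adverse indicator: positive SII means higher burden among the advantaged")
    sii = MeasureResult("SII", float(slope), weighted=True, notes=notes)
    y0, y1 = float(intercept), float(intercept + slope)
    if y0 <= 0:
        raise MeasureUnavailable("nonpositive_fitted_origin")
    rii = MeasureResult("RII", y1 / y0, weighted=True, notes=list(notes))
    return sii, rii


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def compute_stratum(stratum: Stratum) -> MeasureSet:
    """Compute every applicable summary measure for one stratum.

    Never raises on degenerate data: measures whose preconditions fail
    (zero ratio denominator, non-positive estimates for the log-based
    measures, ...) are skipped and the reason recorded in the skip log.
    """
    wanted = applicable_measures(stratum)
    mu = setting_average(stratum)
    results: list[MeasureResult] = []
    skipped: dict[str, str] = {}

    def run(names: tuple[str, ...], fn, *args):
        try:
            out = fn(*args)
        except MeasureUnavailable as exc:
            for n in names:
                skipped[n] = exc.reason
            return
        for res in (out if isinstance(out, tuple) else (out,)):
            results.append(res)

    run(("D",), difference, stratum)
    run(("R",), ratio, stratum)
    if {"PAR", "PAF"} <= wanted:
        run(("PAR", "PAF"), par_paf, stratum, mu)
    if "BGV" in wanted:
        run(("BGV",), bgv, stratum, mu)
    if {"MDB", "MDM"} <= wanted:
        run(("MDB", "MDM"), mdb_mdm, stratum, mu)
    if {"IDIS", "IDISW"} <= wanted:
        run(("IDIS", "IDISW"), idis_idisw, stratum, mu)
    if {"MLD", "TI"} <= wanted:
        run(("MLD", "TI"), mld_theil, stratum, mu)
    if {"ACI", "RCI"} <= wanted:
        run(("ACI", "RCI"), aci_rci, stratum, mu)
    if {"SII", "RII"} <= wanted:
        run(("SII", "RII"), sii_rii, stratum)
    return MeasureSet(results, skipped)
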