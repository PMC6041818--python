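# Methods

## Data model

The unit of analysis is the **stratum**: all subgroup estimates for one
setting × year × source × indicator × dimension. Source is part of the
stratum key because distinct surveys may legitimately cover the same
setting and year. Three dimension types drive everything downstream:

* **binary** — exactly two subgroups, whatever the dimension is called
  (a two-subgroup dimension labelled "ordered" in the input is a
  template error, not silently coerced);
* **ordered** — more than two subgroups with an inherent ranking
  (wealth, education), recorded as `subgroup_order` = 1 for the most
  disadvantaged upward; ranks used downstream are the sort positions,
  so gaps in the integer sequence are allowed (with a warning) but
  duplicates or a sequence not starting at 1 are errors;
* **non-ordered** — more than two subgroups with no inherent ranking
  (regions, ethnic groups); an optional single reference subgroup may
  be designated.

Validation separates **errors** (violations of the mandatory-variable
contract; the file is rejected) from **warnings** (missing recommended
variables: `se`, `population`, `setting_average`). A stratum that mixes
rows with and without population is accepted with a warning and
degraded to unweighted measures, since row-level weighting with partial
populations has no defensible denominator.

Missing-value sentinels are the empty cell and `NA`, nothing else.
Column matching is case-insensitive and whitespace-trimmed, and
`95ci_lb`/`ci_lb` (likewise `_ub`) are aliases: the template spells the
CI columns with a leading digit, which many tools mishandle, so outputs
use the template spelling while the internal name is `ci_lb`. CSV is
UTF-8, comma-delimited, header first, no dialect sniffing, for
reproducibility. Legacy `.xls` is read only when `xlrd` is importable;
`.xlsx` goes through openpyxl. Integral floats are written without a
trailing `.0` so that a dataset round-trips bit-identically through
both CSV and Excel.

## Measures

Definitions are in the README. Numerical and orientation choices:

* **μ precedence** — a supplied `setting_average` wins over the
  computed population-weighted mean: it is treated as the authoritative
  reported figure (it may come from a census while the subgroups come
  from a survey).
* **D and R pair selection** — ordered: rank extremes, oriented so
  D > 0 means the burden falls on the disadvantaged; non-ordered/binary
  without a reference: max vs min; with a designated reference: the
  subgroup farthest from the reference vs the reference, sign kept
  (the comparison is recorded in the result notes). Ties on estimates
  are broken alphabetically by subgroup name, for determinism.
* **PAR truncation** — PAR is interpreted as attainable improvement of
  the average; when the reference subgroup does not improve on μ
  (favourable PAR < 0, adverse PAR > 0) it is truncated to 0 and a note
  records the truncation. PAF inherits the truncated value.
* **SII/RII estimator** — natural-scale weighted least squares of the
  subgroup estimates on the rank midpoints, weights = population
  shares, via statsmodels. A bounded-link (logit-scale) variant would
  need the indicator scale in the likelihood; the scale is carried on
  the stratum but unused by this estimator, which is isolated behind a
  single function should a link-based variant be wanted later. The
  standard error is an availability gate only (it does not enter the
  point estimate); confidence intervals for the summary measures
  themselves are out of scope.
* **Reporting scales** — PAF, RCI, IDIS, IDISW are ×100 (percent);
  MLD and TI are ×1000. The factors are named constants in
  `measures.py`.
* **Degenerate inputs never raise** in `compute_stratum`: a zero ratio
  denominator, a non-positive estimate under a log, a non-positive
  fitted origin for RII, or an unavailable μ become entries in the skip
  log with a reason code.

Applicability gating: D and R always; every other measure needs
population shares; SII/RII also need a standard error on every
subgroup; the dispersion family (BGV, MDB, MDM, IDIS, IDISW, MLD, TI)
is reserved for non-ordered strata with more than two subgroups and the
gradient family (ACI, RCI, SII, RII) for ordered strata. That yields 4
applicable measures for a binary stratum with population, 11 for a
non-ordered and 8 for an ordered stratum with full data — 15 distinct
measures overall.

## Explore / compare tables

Bar tables sort stably (equal estimates keep alphabetical order), never
alter estimates, and compute the median reference line as the exact
midpoint median. Trend tables emit one bar table per available year in
ascending order; missing years are absent, not interpolated, and when
two sources cover one year the alphabetically first source is used and
noted. Benchmark tables take each setting's latest year with a complete
stratum for the chosen indicator × dimension, pair the setting average
with the chosen measure, and filter on an optional side table of tags
(region, income group) — tags are a side table because the upload
template has no such columns. A stricter filter always yields a subset
of settings.

## Synthetic data

The generator emulates coverage-style survey data: per dimension it
places noise-free subgroup values at
`base + gap · f_j + trend · (year − first year)` for favourable
indicators, where `f_j` spans 0 (most disadvantaged) to 1 (most
advantaged); adverse indicators mirror the gradient so the burden sits
on the disadvantaged. Gaussian noise (`noise_sd`, on the estimate
scale) is added and clipped to `[0, scale]`; infeasible scenarios
(noise-free values outside the scale) are rejected before generation.
Populations split a configurable total equally or by a seeded Dirichlet
draw; the emitted `se = noise_sd / sqrt(p_j · J)` is a fixture
convention chosen for internal consistency, not a survey-design claim.
Defaults (base 50, gap 30, scale 100, 10 000 people per stratum) are
typical of national coverage indicators with a substantial
urban–rural divide.

What the generator does **not** emulate: cluster/stratified survey
design effects, correlated noise across years, non-Gaussian sampling
error near the scale bounds, and real-world missingness patterns.
Passing tests therefore demonstrate correctness of the measures and
plumbing on template-conformant data, not robustness to messy survey
microdata.

## Problem sizes and determinism

Everything is deterministic given the scenario seed (a NumPy
`default_rng`). The test suite and the acceptance script use small
strata (2–8 subgroups, ≤ a few hundred rows); property sweeps run
100–120 randomized strata per invariant with hypothesis derandomised;
the person-level concentration-index oracle expands populations up to
1000 individuals. The noise-recovery check averages the difference
measure over 8 settings × 200 seeds and requires the bias to stay
inside `noise_sd/√200`.

## Known limitations

* No standard errors or confidence intervals for the summary measures.
* SII/RII natural-scale WLS only (no logit link) in this version.
* Whether D/R against a designated reference should compare the
  reference to the extreme subgroup (implemented, noted in results) or
  to every subgroup is a genuinely open convention.
* Legacy `.xls` requires an optional dependency; `.csv`/`.xlsx` are the
  first-class formats.
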