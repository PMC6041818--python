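# healthineq

Summary measures of health inequality on disaggregated indicator data.

National averages hide who is being left behind. Health-equity
monitoring therefore works with *disaggregated* data: one estimate of an
indicator (antenatal care coverage, under-five mortality, access to
improved drinking water, ...) per population subgroup, where the
subgroups are defined by a *dimension of inequality* — place of
residence (urban/rural), wealth quintile, education, subnational region.
`healthineq` ingests such data laid out in a standard upload template
(one row per setting × year × source × indicator × dimension ×
subgroup), validates the template contract, computes the applicable
summary measures of inequality for every stratum, and produces the
graph-ready tables used to explore one setting or benchmark many.

## The measures

For a stratum with subgroup estimates $y_j$, population shares
$p_j = \mathrm{pop}_j / \sum_k \mathrm{pop}_k$ and setting average
$\mu$ (the reported average if supplied, else $\sum_j p_j y_j$):

| measure | definition | applies to |
|---|---|---|
| D | $y_{\text{advantaged}} - y_{\text{disadvantaged}}$ (extreme pair, or extreme vs reference subgroup) | all |
| R | same pair, as a ratio | all |
| PAR | $y_{\text{ref}} - \mu$, truncated to 0 when no improvement is attainable | all, needs population |
| PAF | $100 \cdot \text{PAR} / \mu$ | all, needs population |
| BGV | $\sum_j p_j (y_j-\mu)^2$ | non-ordered > 2 |
| MDB / MDM | $\sum_j p_j \lvert y_j - y_{\text{best}}\rvert$ / $\sum_j p_j \lvert y_j - \mu\rvert$ | non-ordered > 2 |
| IDIS / IDISW | $100 \cdot \frac{1}{J}\sum_j \lvert y_j-\mu\rvert / \mu$ and its $p_j$-weighted form | non-ordered > 2 |
| MLD / TI | $1000\sum_j p_j \ln(\mu/y_j)$ and $1000\sum_j p_j \frac{y_j}{\mu}\ln\frac{y_j}{\mu}$ | non-ordered > 2 |
| ACI / RCI | $\sum_j p_j (2X_j - 1)\, y_j$ and $100\cdot\text{ACI}/\mu$, with rank midpoints $X_j$ | ordered > 2 |
| SII / RII | WLS fit of $y_j$ on $X_j$ (weights $p_j$): $\hat y(1)-\hat y(0)$ and $\hat y(1)/\hat y(0)$ | ordered > 2, needs se |

$X_j$ is the cumulative population share up to subgroup $j$ minus
$p_j/2$, with subgroups ranked from most disadvantaged to most
advantaged. Fifteen measures in total; without population data only the
unweighted D and R can be computed, and SII/RII additionally require a
standard error on every subgroup.

## Worked example

```python
from healthineq import Stratum, StratumKey, Subgroup, compute_stratum

stratum = Stratum(
    key=StratumKey("Testland", 2015, "DHS", "anc", "Wealth tertile"),
    dimension_type="ordered", favourable=True, scale=100.0,
    subgroups=[  # most disadvantaged first
        Subgroup("T1 (poorest)", 20.0, se=1.0, population=100, order=1),
        Subgroup("T2", 50.0, se=1.0, population=100, order=2),
        Subgroup("T3 (richest)", 80.0, se=1.0, population=100, order=3),
    ])
for r in sorted(compute_stratum(stratum), key=lambda r: r.measure):
    print(f"{r.measure:>4} = {r.value:.4f}")
```

prints

```
 ACI = 13.3333
   D = 60.0000
 PAF = 60.0000
 PAR = 30.0000
   R = 4.0000
 RCI = 26.6667
 RII = 19.0000
 SII = 90.0000
```

Coverage rises from 20% in the poorest to 80% in the richest tertile,
so the richest–poorest gap is D = 60 percentage points (R = 4×). If
every group attained the most-advantaged level the average (μ = 50)
would rise by PAR = 30 points (PAF = 60%). The regression across the
population ranks puts the fitted top-to-bottom change at SII = 90
points, and the concentration index shows coverage concentrated among
the better-off (RCI = 26.7%).

The same computations are available from the shell:

```sh
healthineq simulate --seed 1 -o demo.csv      # synthetic template data
healthineq validate demo.csv                  # template contract check
healthineq compute demo.csv -o measures.csv   # long-format measure table
healthineq explore bar demo.csv --setting "Setting A" --indicator anc \
    --dimension "Place of residence" --sort-by estimate --median -o bar.csv
```

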