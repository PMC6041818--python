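import pytest

from healthineq.measures import Stratum, StratumKey, Subgroup
from healthineq.synthetic import DimensionSpec, IndicatorSpec, ScenarioSpec, generate_dataset


def make_stratum(estimates, *, dimension_type="nonordered", favourable=True,
                 populations=None, ses=None, names=None, reference=None,
                 setting_average=None, scale=100.0):
    """Build a measure-ready stratum from parallel value lists."""
    J = len(estimates)
    names = names or [f"g{j}" for j in range(J)]
    subgroups = []
    for j in range(J):
        subgroups.append(Subgroup(
            name=names[j],
            estimate=float(estimates[j]),
            se=None if ses is None else float(ses[j]),
            population=None if populations is None else float(populations[j]),
            order=j + 1 if dimension_type == "ordered" else 0,
            is_reference=(names[j] == reference),
        ))
    return Stratum(
        key=StratumKey("Testland", 2015, "SYN", "anc", "dim"),
        dimension_type=dimension_type,
        favourable=favourable,
        scale=scale,
        subgroups=subgroups,
        setting_average_provided=setting_average,
    )


@pytest.fixture
def full_scenario():
    """One binary, one non-ordered (J=4) and one ordered (J=4) dimension,
    with estimates, se and population for every subgroup."""
    return ScenarioSpec(
        settings=["Testland"],
        years=[2015],
        indicators=[IndicatorSpec(abbr="anc", name="Antenatal care coverage",
                                  favourable=True, scale=100.0)],
        dimensions=[
            DimensionSpec(name="Place of residence", type="binary", subgroups=2),
            DimensionSpec(name="Region", type="nonordered", subgroups=4),
            DimensionSpec(name="Wealth quintile", type="ordered", subgroups=4),
        ],
        base=40.0, gap=30.0, noise_sd=5.0, seed=7,
    )


@pytest.fixture
def full_records(full_scenario):
    return generate_dataset(full_scenario)
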