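import pytest

from myoflux.model import Metabolite, Reaction, StoichiometricModel


@pytest.fixture
def chain_model():
    """EX_A (ub 5) -> A -> B -> demand; optimum forced to 5 by the uptake."""
    return StoichiometricModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1.0}, 0.0, 5.0, subsystem="exchange"),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, 0.0, 100.0),
            Reaction("DM_B", {"B": -1.0}, 0.0, 100.0, subsystem="demand"),
        ],
        objective_id="DM_B",
        name="chain",
    )


@pytest.fixture(scope="session")
def reference_model_and_conditions():
    """Reference synthetic muscle model plus the two bundled plasma profiles."""
    from myoflux.conditions import fasting_condition, post_absorptive_condition
    from myoflux.synthetic import make_muscle_like_model, reference_muscle_spec

    fasting = fasting_condition()
    post = post_absorptive_condition()
    model = make_muscle_like_model(reference_muscle_spec(fasting))
    return model, fasting, post
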