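import pytest

from storflux.fba import Environment
from storflux.model import MetabolicModel, Metabolite, Reaction
from storflux.objectives import nonlimited_reference
from storflux.synthetic import make_toy_model, toy_environments


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def glucose_envs():
    return toy_environments("glucose")


@pytest.fixture(scope="session")
def acetate_envs():
    return toy_environments("acetate")


@pytest.fixture(scope="session")
def glucose_reference(toy_model, glucose_envs):
    return nonlimited_reference(toy_model, glucose_envs[0])


@pytest.fixture(scope="session")
def acetate_reference(toy_model, acetate_envs):
    return nonlimited_reference(toy_model, acetate_envs[0])


def build_mini_model(reactions: dict[str, dict], metabolite_ids=None,
                     extracellular=()) -> MetabolicModel:
    """Assemble a minimal formula-free model for solver oracle tests.

    ``reactions`` maps id -> {"stoich": {...}, "lb": .., "ub": ..,
    "kind": ..}.  Metabolites are inferred; those listed in
    ``extracellular`` are boundary species (excluded from S).
    """
    mids = set(metabolite_ids or [])
    for spec in reactions.values():
        mids |= set(spec["stoich"])
    mets = [Metabolite(id=m, compartment="e" if m in extracellular else "c")
            for m in sorted(mids)]
    rxns = [Reaction(id=rid, stoichiometry=dict(spec["stoich"]),
                     lower_bound=spec.get("lb", 0.0),
                     upper_bound=spec.get("ub", 1e4),
                     kind=spec.get("kind", "conversion"))
            for rid, spec in reactions.items()]
    return MetabolicModel(metabolites=mets, reactions=rxns)


def mini_env(substrate_exchange: str, uptake: float, ngam: float = 0.0,
             fixed=None) -> Environment:
    return Environment(substrate_exchange=substrate_exchange,
                       substrate_uptake=uptake, nh4_exchange="",
                       pi_exchange="", o2_exchange="", ngam=ngam,
                       fixed_rates=dict(fixed or {}))
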