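import pytest

from ribokinetics.model import build_riboflavin_model
from ribokinetics.stoichiometry import resolve_boundary_fluxes
from ribokinetics.synthetic import reference_parameters, toy_linear_chain


@pytest.fixture(scope="session")
def fixture_params():
    """The packaged synthetic parameter set for the canonical topology."""
    return reference_parameters()


@pytest.fixture(scope="session")
def default_model(fixture_params):
    """Canonical model, boundary fluxes still unresolved."""
    return build_riboflavin_model(fixture_params)


@pytest.fixture(scope="session")
def resolved_model(default_model):
    """Canonical model with closure-predicted boundary fluxes frozen."""
    return resolve_boundary_fluxes(default_model)


@pytest.fixture
def chain3():
    """Three-step linear chain, middle enzyme the bottleneck (capacity 1 < flux 2)."""
    return toy_linear_chain(
        3, vmaxes=[10.0, 1.0, 10.0], kms=[100.0, 100.0, 100.0], import_flux=2.0
    )
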