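import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_protein():
    from coronafit import make_toy_protein
    return make_toy_protein()


@pytest.fixture(scope="session")
def small_toy_protein():
    """Smaller cylinder for fast grid-scan tests."""
    from coronafit import make_toy_protein
    return make_toy_protein(radius=10.0, height=20.0, spacing=4.0)


@pytest.fixture(scope="session")
def default_densities():
    from coronafit import DensitySpec
    return DensitySpec()


@pytest.fixture
def single_atom_pdb(tmp_path):
    line = ("ATOM      1  CA  ALA A   1      11.104   6.134   1.169"
            "  1.00 20.00           C  \n")
    path = tmp_path / "one.pdb"
    path.write_text(line + "END\n")
    return path
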