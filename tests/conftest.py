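import numpy as np
import pytest
from hypothesis import settings

from peptube import assembly, rings
from peptube.sequences import make_design, parse_sequence

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def seq8():
    return parse_sequence("RRKWLWLW")


@pytest.fixture(scope="session")
def ring8(seq8):
    return rings.build_ring(seq8)


@pytest.fixture(scope="session")
def octamer_model(seq8, ring8):
    """The worked example: eight c-RRKWLWLW rings stacked antiparallel."""
    design = make_design(["RRKWLWLW"] * 8, ["antiparallel"] * 7, "octamer")
    return assembly.stack_rings(design, [ring8.copy() for _ in range(8)])


@pytest.fixture(scope="session")
def cg_mapping():
    from peptube.cgmap import load_bead_mapping

    return load_bead_mapping()


@pytest.fixture(scope="session")
def cg_params():
    import importlib.resources

    import yaml

    ref = importlib.resources.files("peptube.data") / "cg_params.yaml"
    return yaml.safe_load(ref.read_text())


@pytest.fixture(scope="session")
def gly4_linear():
    from peptube.formats import parse_molecule_itp
    from peptube.profiles import resolve_profile

    profile = resolve_profile("fixture-aa")
    return profile, parse_molecule_itp(profile.load_linear_template_text("GGGG"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)
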