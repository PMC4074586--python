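"""Shared fixtures.

Toy networks are rebuilt per test (cheap, deterministic).  The
genome-scale E. coli reconstruction iJO1366 is loaded once per session
from the SBML file shipped inside the installed cobra distribution
(cobra/data/iJO1366.xml.gz, the BiGG snapshot), and its reference FVA —
the expensive shared computation — is cached at session scope.
"""

from __future__ import annotations

import importlib.util
from pathlib import Path

import pytest

from fluxvar import (
    MediumSpec,
    StoichiometricLP,
    apply_medium,
    compute_reference_ranges,
    make_toy,
    read_model,
)


@pytest.fixture
def toy1():
    return make_toy("chain")


@pytest.fixture
def toy2():
    return make_toy("branched")


@pytest.fixture
def toy3():
    return make_toy("two_substrate")


def ijo1366_path() -> Path:
    spec = importlib.util.find_spec("cobra")
    if spec is None or not spec.submodule_search_locations:
        raise FileNotFoundError(
            "cobra is not installed; the genome-scale reconstruction "
            "iJO1366 is read from its packaged data directory"
        )
    path = Path(spec.submodule_search_locations[0]) / "data" / "iJO1366.xml.gz"
    if not path.exists():
        raise FileNotFoundError(f"packaged iJO1366 model not found at {path}")
    return path


@pytest.fixture(scope="session")
def ijo1366():
    """iJO1366 conditioned on the packaged glucose minimal medium."""
    model = read_model(ijo1366_path())
    medium_path = Path(__file__).resolve().parents[1] / "src" / "fluxvar" / "data" / "glucose_minimal.yaml"
    if not medium_path.exists():  # installed (non-editable) layout
        import fluxvar

        medium_path = Path(fluxvar.__file__).parent / "data" / "glucose_minimal.yaml"
    medium = MediumSpec.from_yaml(medium_path)
    return apply_medium(model, medium)


@pytest.fixture(scope="session")
def ijo1366_lp(ijo1366):
    return StoichiometricLP(ijo1366)


@pytest.fixture(scope="session")
def ijo1366_reference(ijo1366, ijo1366_lp):
    """Reference FVA over the internal reactions (a few minutes; shared)."""
    return compute_reference_ranges(ijo1366, lp=ijo1366_lp)
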