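"""Shared fixtures: the BMI toy KO, toy arithmetic models, and the demo shelf."""

from __future__ import annotations

import pytest
from hypothesis import settings

from kocompose.activator import Activator
from kocompose.ko_package import (
    DeploymentSpec,
    KnowledgeObjectPackage,
    KoMetadata,
    PersistentId,
    ServiceSpec,
)
from kocompose.synthetic_fixtures import build_demo_shelf, make_bmi_fixture

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

DEMO_SEED = 11


def make_toy_package(name: str, source: str, function_name: str = "run") -> KnowledgeObjectPackage:
    """A tiny single-file model KO at /toy/<name>/1.0/run."""
    entry = "model.py"
    return KnowledgeObjectPackage(
        metadata=KoMetadata(
            id=PersistentId("12345", name, "1.0.0"),
            title=f"toy {name}",
            ko_version="1.0.0",
        ),
        deployment=DeploymentSpec(
            endpoint_path="/run",
            engine="python",
            entry=entry,
            artifacts=(entry,),
            function_name=function_name,
        ),
        service=ServiceSpec(
            service_version="1.0",
            title=f"toy {name}",
            base_url=f"/toy/{name}/1.0",
            paths=("/run",),
        ),
        payload={entry: source.encode("utf-8")},
    )


@pytest.fixture
def bmi_pkg():
    return make_bmi_fixture()


@pytest.fixture
def activator():
    return Activator()


@pytest.fixture(scope="session")
def demo_shelf(tmp_path_factory):
    shelf_dir = tmp_path_factory.mktemp("demo-shelf")
    return build_demo_shelf(shelf_dir, seed=DEMO_SEED)


@pytest.fixture(scope="session")
def demo_activator(demo_shelf):
    """Session-wide activated shelf for read-only tests.

    Tests that mutate the context (deactivation) build their own activator
    from the same shelf directory.
    """
    act = Activator()
    act.activate_shelf(demo_shelf.shelf_dir)
    return act
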