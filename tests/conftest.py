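import pytest

from pepgraft import fixtures as fx
from pepgraft.grafting import Anchor, AnchorGroup, AnchorSet
from pepgraft.scaffoldlib import build_library_from_structures


@pytest.fixture(scope="session")
def ideal_helix():
    return fx.make_ideal_helix(12, seed=0)


@pytest.fixture(scope="session")
def ideal_strand():
    return fx.make_ideal_strand(6, seed=0)


@pytest.fixture(scope="session")
def hairpin():
    return fx.make_beta_hairpin(5, seed=0)


@pytest.fixture(scope="session")
def toy():
    return fx.make_toy_complex(seed=0)


def make_anchor_set(toy_complex) -> AnchorSet:
    groups = {
        label: AnchorGroup(
            label=label, ss_type=g["ss_type"], contiguity=g["contiguity"],
            anchors=[Anchor(a["chain"], a["seq_id"], a["name"],
                            a["keep_original"]) for a in g["anchors"]])
        for label, g in toy_complex.anchor_spec["groups"].items()
    }
    return AnchorSet(receptor=toy_complex.receptor, donor=toy_complex.donor,
                     groups=groups)


@pytest.fixture(scope="session")
def anchor_set(toy):
    return make_anchor_set(toy)


@pytest.fixture(scope="session")
def donor_library(toy):
    """Library built from the donor alone (planted fragments only)."""
    return build_library_from_structures([toy.donor])


@pytest.fixture(scope="session")
def full_library(toy):
    """Planted fragments hidden among 20 decoy scaffolds."""
    decoys = fx.make_decoy_library_structures(20, seed=1)
    return build_library_from_structures([toy.donor] + decoys)


@pytest.fixture(scope="session")
def pipeline_result(toy, anchor_set, full_library):
    """One full end-to-end run on the toy problem, shared across tests."""
    from pepgraft.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=7), full_library, anchor_set)
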