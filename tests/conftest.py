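import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from coralpopgen import GenotypeTable  # noqa: E402


@pytest.fixture
def two_site_table() -> GenotypeTable:
    """Six individuals, two sites, three loci; one missing call."""
    calls = np.array(
        [
            [[150, 152], [200, 204], [301, 301]],
            [[150, 150], [200, 200], [301, 303]],
            [[152, 152], [0, 0], [303, 303]],
            [[150, 154], [204, 204], [301, 301]],
            [[154, 154], [200, 204], [301, 303]],
            [[150, 152], [204, 204], [303, 303]],
        ]
    )
    return GenotypeTable(
        individuals=[f"ind{i}" for i in range(6)],
        loci=["LA", "LB", "LC"],
        calls=calls,
        sites=np.array(["s1", "s1", "s1", "s2", "s2", "s2"], dtype=object),
        repeat_units={"LA": 2, "LB": 4, "LC": 2},
    )


@pytest.fixture(scope="session")
def sole_preset():
    """Reduced-scale partially clonal structured dataset + truth."""
    from coralpopgen.simdata import preset_study, simulate

    cfg = preset_study("solenosmilia_like", seed=11, scale=0.3)
    return simulate(cfg)


@pytest.fixture(scope="session")
def desmo_preset():
    """Reduced-scale depth-stratified high-gene-flow dataset + truth."""
    from coralpopgen.simdata import preset_study, simulate

    cfg = preset_study("desmophyllum_like", seed=12, scale=0.3)
    return simulate(cfg)
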