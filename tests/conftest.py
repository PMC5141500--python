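from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import gpcrfp as g

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

REPO_ROOT = Path(__file__).resolve().parents[1]
CRYSTAL_DIR = REPO_ROOT / "data" / "crystal"


@pytest.fixture(scope="session")
def small_bundle():
    """Noise-free 7x16 poly-Ala bundle with a Trp/Phe/Pro on it."""
    from gpcrfp.synthetic import helix_seq

    spec = g.SyntheticSpec(
        seed=101,
        n_frames=1,
        noise_sigma=0.0,
        residue_types={
            helix_seq(6, 8): "TRP",
            helix_seq(6, 6): "PHE",
            helix_seq(5, 8): "PRO",
        },
    )
    structure, bwmap = g.build_bundle(spec)
    return structure, bwmap, spec


@pytest.fixture(scope="session")
def study_ensemble():
    """Default study conditions at 300 frames (shared across tests)."""
    spec = g.study_spec(seed=202, n_frames=300)
    ens, bwmap = g.generate(spec)
    return ens, bwmap, spec
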