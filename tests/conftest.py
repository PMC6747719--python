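import pytest
from hypothesis import HealthCheck, settings

from ubiqscan import profile_search as ps
from ubiqscan import synthetic_data as sd
from ubiqscan.io_formats import SystemModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,  # read-only model fixtures
    ],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def consensi():
    return sd.default_consensi(0)


@pytest.fixture(scope="session")
def calibrated_profiles(consensi):
    """Three calibrated family profiles built from diverged seed alignments."""
    profiles = []
    for i, (fam, cons) in enumerate(consensi.items()):
        aln = sd.gen_seed_alignment(cons, 30, 0.2, seed=100 + i)
        prof = ps.build_profile(aln, fam)
        profiles.append(ps.calibrate_profile(prof, seed=200 + i))
    return profiles


@pytest.fixture(scope="session")
def ubituv_model():
    return SystemModel(
        name="ubiTUV",
        mandatory=frozenset({"ubiT", "ubiU", "ubiV"}),
        accessory=frozenset({"U32"}),
        inter_gene_max_space=5,
    )
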