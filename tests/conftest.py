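import pytest
from hypothesis import HealthCheck, settings

import pollenflow as pf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gm():
    """The packaged 12-cultivar x 18-locus genotype matrix."""
    return pf.builtin_genotype_table()


@pytest.fixture(scope="session")
def panel(gm):
    """The private-allele panel derived from the packaged matrix."""
    return pf.find_private_alleles(gm)


def calls_for(panel, detected, bee_id="bee"):
    """AlleleCallSet with ALT detections at exactly ``detected`` loci."""
    return pf.AlleleCallSet(
        bee_id, {l: (l in detected, None) for l in panel.locus_ids}
    )
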