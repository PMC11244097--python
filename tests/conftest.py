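import hypothesis
import pytest

from emulgelopt import datasets
from emulgelopt.design import generate_ccd, EMULGEL_FACTOR_SPACE

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_design():
    return generate_ccd(EMULGEL_FACTOR_SPACE)


@pytest.fixture(scope="session")
def d50_means(ref_design):
    pct = datasets.particle_percentiles()
    return {rid: float(pct.loc[rid, "d50_mean"]) for rid in ref_design.run_ids}
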