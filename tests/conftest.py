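import pytest

from melbind.models import SipsParameters


@pytest.fixture
def chloroquine_sips() -> SipsParameters:
    """Sips parameters of the strongest binder in the reference panel."""
    return SipsParameters(kd=76.0, bmax=380.0, n=0.605)


@pytest.fixture
def papaverine_sips() -> SipsParameters:
    return SipsParameters(kd=66.0, bmax=66.0, n=0.715)


@pytest.fixture
def papaverine_design() -> tuple:
    """Traditional-assay dilution series for papaverine: 0.25-250 µM."""
    return tuple(250.0 / 2**i for i in range(11))
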