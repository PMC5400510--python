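import pytest

from nucpos import TemplateCoordinateSystem


@pytest.fixture(scope="session")
def coords():
    """3.8 kb template with the ACS anchored at absolute position 1000."""
    return TemplateCoordinateSystem("ARS1_template", acs_offset=1000, length_bp=3800)
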