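import pytest

from annotrack import Annotation, ChartContext


@pytest.fixture
def ctx() -> ChartContext:
    """Domain [0, 1000) onto pixel range [0, 500): 0.5 px per unit."""
    return ChartContext(domain_start=0, domain_end=1000, range_start=0.0, range_end=500.0)


@pytest.fixture
def unit_ctx() -> ChartContext:
    """Domain [0, 100) onto range [0, 1000): 10 px per unit."""
    return ChartContext(domain_start=0, domain_end=100, range_start=0.0, range_end=1000.0)


def make_annotation(id="a", start=0, end=10, strand="+", **attrs) -> Annotation:
    return Annotation(id=id, start=start, end=end, strand=strand, attributes=attrs)
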