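import numpy as np
import pytest

from anchorscape import (
    AnchorRecord,
    AnchorSet,
    Variant,
    fixture_with_wildtype,
    make_anchor_fixture,
    parse_mutation,
    parse_variant,
)

# a 120-residue reference with known letters at the sites the tests mutate
_REF = list("M" + "A" * 119)
for tok in ("D33E", "R43S", "S57R", "I80V", "P94L", "D119N"):
    m = parse_mutation(tok)
    _REF[m.site - 1] = m.wt_aa
TEST_REFERENCE = "".join(_REF)


@pytest.fixture(scope="session")
def reference():
    return TEST_REFERENCE


@pytest.fixture(scope="session")
def anchor_fixture():
    return make_anchor_fixture()


@pytest.fixture(scope="session")
def anchor_fixture_wt():
    return fixture_with_wildtype()


def make_variant(spec: str, reference: str = TEST_REFERENCE) -> Variant:
    return parse_variant(spec, reference)


def make_set(entries, reference: str = TEST_REFERENCE) -> AnchorSet:
    """AnchorSet from (variant_spec, fitness) pairs."""
    records = [
        AnchorRecord(variant=make_variant(spec, reference), fitness=fit,
                     record_id=f"t{i:02d}")
        for i, (spec, fit) in enumerate(entries)
    ]
    return AnchorSet(reference, records)


@pytest.fixture
def triangle_set():
    """WT, S57R and S57R;P94L — all pairwise distances <= 2."""
    return make_set([("WT", 5.0), ("S57R", 15.0), ("S57R;P94L", 30.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
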