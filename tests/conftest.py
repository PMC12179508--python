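import pytest

from indelstruct import fixtures as fx


@pytest.fixture(scope="session")
def bundle():
    """The packaged 20-variant study bundle as in-memory objects."""
    return {
        "variants": fx.load_variants(),
        "grades": fx.load_variant_grades(),
        "region_map": fx.load_region_map(),
        "lcr": fx.load_lcr_annotation(),
        "features": fx.load_features(),
    }


@pytest.fixture(scope="session")
def cohort_a(bundle):
    return [v for v in bundle["variants"] if v.cohort.value == "A"]


@pytest.fixture(scope="session")
def cohort_b(bundle):
    return [v for v in bundle["variants"] if v.cohort.value == "B"]


@pytest.fixture(scope="session")
def helix20():
    from indelstruct.synthetic import make_ideal_helix

    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def extended20():
    from indelstruct.synthetic import make_extended_chain

    return make_extended_chain(20)
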