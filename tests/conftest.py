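import pytest

from mitoej import ReferenceLocus, gen_reference_locus


def make_mini_locus(amplicon: str, fwd_len: int = 2, rev_len: int = 2) -> ReferenceLocus:
    """Tiny locus around an explicit amplicon, for decomposition unit tests."""
    from mitoej import revcomp

    return ReferenceLocus(
        name="mini",
        amplicon=amplicon,
        cut_position=len(amplicon) // 2,
        fwd_primer=amplicon[:fwd_len],
        rev_primer=revcomp(amplicon[-rev_len:]),
        recognition_site_span=None,
    )


@pytest.fixture(scope="session")
def locus() -> ReferenceLocus:
    """A 400-bp synthetic locus shared across tests."""
    return gen_reference_locus(length=400, cut_fraction=0.5, seed=1)
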