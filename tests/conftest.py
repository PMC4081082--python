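import warnings

import pytest

from triplexkit.io_model import TargetSite


@pytest.fixture(autouse=True)
def _quiet_overflow_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def make_site(
    seed_start: int,
    seed_end: int | None = None,
    mirna_id: str = "miR-x",
    gene_id: str = "G1",
    transcript_id: str = "T1",
    mirsvr: float = -0.5,
    phastcons: float = 0.8,
    pad: int = 3,
) -> TargetSite:
    """A valid site whose seed match is [seed_start, seed_end] (1-based)."""
    if seed_end is None:
        seed_end = seed_start + 6
    return TargetSite(
        gene_id=gene_id,
        transcript_id=transcript_id,
        mirna_id=mirna_id,
        site_start=max(1, seed_start - pad),
        site_end=seed_end + pad,
        seed_start=seed_start,
        seed_end=seed_end,
        mirsvr=mirsvr,
        phastcons=phastcons,
    )


@pytest.fixture
def site_factory():
    return make_site
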