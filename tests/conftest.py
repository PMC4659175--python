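import numpy as np
import pytest

from methsnp.chemistry import ChemistryParams, LocusSpec, SNPSpec
from methsnp.cohort import make_context


@pytest.fixture
def noise_free_params() -> ChemistryParams:
    return ChemistryParams(background=0.0, sdlog=0.0)


@pytest.fixture
def plain_locus() -> LocusSpec:
    """Interrogated CpG only, no SNP, no under-probe CpGs."""
    return LocusSpec("plain", make_context())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def locus_with_snp(position: int, alt: str, under_probe: bool = False) -> LocusSpec:
    offsets = (2, 4) if under_probe else ()
    return LocusSpec(
        f"snp{position}{alt}",
        make_context(offsets),
        snp=SNPSpec(position, alt, {"EUR": 0.2, "EAS": 0.7}),
        under_probe_cpg_offsets=offsets,
    )
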