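import pytest

from wrkycensus.io import load_reference_census
from wrkycensus.pipeline import RunConfig, run_census
from wrkycensus.synthetic import FamilyConfig, generate_family


@pytest.fixture(scope="session")
def census_table():
    """The published 94-gene sorghum census shipped with the package."""
    return load_reference_census()


@pytest.fixture(scope="session")
def family94():
    """Synthetic 94-gene family at the generator's default conditions."""
    return generate_family(FamilyConfig(seed=11))


@pytest.fixture(scope="session")
def census_result94(family94):
    """Full pipeline run on the default synthetic family (no bootstrap;
    supports are exercised separately on a smaller alignment)."""
    config = RunConfig(seed=11, run_bootstrap=False)
    return run_census(
        family94.proteins,
        loci=family94.loci,
        cds=family94.cds,
        genomic=family94.genomic,
        references=family94.references,
        reference_labels=family94.reference_labels,
        promoters=family94.promoters,
        ct_table=family94.ct_table,
        config=config,
    )
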