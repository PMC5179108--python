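import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_fixture():
    from irdx.fixture import load_cohort_fixture
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def cohort_run(cohort_fixture):
    from irdx.fixture import run_fixture_pipeline
    return run_fixture_pipeline(cohort_fixture)


@pytest.fixture(scope="session")
def panel(cohort_fixture):
    return cohort_fixture.panel


@pytest.fixture()
def rng():
    return np.random.default_rng(20160033)


@pytest.fixture()
def trio():
    """Father, mother, affected child."""
    from irdx.core import Affection, Pedigree, PedigreeMember, Sex
    return Pedigree("FAM1", [
        PedigreeMember("DAD", Sex.MALE, Affection.UNAFFECTED),
        PedigreeMember("MOM", Sex.FEMALE, Affection.UNAFFECTED),
        PedigreeMember("KID", Sex.FEMALE, Affection.AFFECTED,
                       father_id="DAD", mother_id="MOM"),
    ])


def make_variant(gene="USH2A", chrom="chr1", pos=100, ref="A", alt="C",
                 consequence=None, exac=None, reported=False, preds=None,
                 hgvs=""):
    """Terse variant constructor for tests."""
    from irdx.core import (Consequence, FrequencyStatus, PredictionProfile,
                           Reported, VariantRecord)
    consequence = consequence or Consequence.MISSENSE
    if exac is None:
        status, ac, an = FrequencyStatus.ABSENT, 0, 0
    elif exac == "unknown":
        status, ac, an = FrequencyStatus.UNKNOWN, 0, 0
    else:
        status, (ac, an) = FrequencyStatus.OBSERVED, exac
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, hgvs=hgvs,
        exac_status=status, exac_ac=ac, exac_an=an,
        reported=(Reported.REPORTED_PATHOGENIC if reported
                  else Reported.NOVEL),
        predictions=preds or PredictionProfile(),
    )
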