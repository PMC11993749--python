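import pytest

from stoichbench.bedrmod import BedRModHeader, SiteRecord


@pytest.fixture
def header():
    return BedRModHeader(
        entries={
            "fileformat": "bedRModv1.8",
            "modification_type": "m5C",
            "assembly": "ref1",
        }
    )


@pytest.fixture
def canonical_text():
    """A small canonical bedRMod file (as write_bedrmod would emit it)."""
    return (
        "#fileformat=bedRModv1.8\n"
        "#modification_type=m5C\n"
        "#assembly=ref1\n"
        "ref1\t11\t12\tm5C\t250\t+\t11\t12\t0,0,0\t40\t0.25\n"
        "ref1\t30\t31\tm5C\t120\t+\t30\t31\t0,0,0\t55\t0.12\n"
    )


def make_site(start, frequency, chrom="ref1", mod_name="m5C", coverage=50):
    return SiteRecord.from_frequency(chrom, start, mod_name, coverage, frequency)


@pytest.fixture
def site_factory():
    return make_site
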