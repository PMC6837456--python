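import pytest

from winternit import load_packaged_survey


@pytest.fixture(scope="session")
def survey():
    """The packaged 31-record winter survey table."""
    return load_packaged_survey()


@pytest.fixture(scope="session")
def study_lakes(survey):
    """The 13 study-lake records (prairie + boreal shield, under ice)."""
    return survey[survey["source"] == "this_study"]
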