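import pytest
from hypothesis import settings

from pvalopecia import case_definition as cd
from pvalopecia import datasets, faers_io
from pvalopecia import synthetic_data as sd

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_bundle():
    """The packaged deterministic end-to-end fixture (71 planted signal
    drugs, 7 of them on the exclusion list)."""
    return sd.make_reference_scale_fixture()


@pytest.fixture(scope="session")
def fixture_cases(fixture_bundle):
    demo = faers_io.deduplicate(fixture_bundle.tables["DEMO"])
    return faers_io.assemble_cases(
        demo,
        fixture_bundle.tables["DRUG"],
        fixture_bundle.tables["REAC"],
        fixture_bundle.tables["THER"],
        fixture_bundle.tables["OUTC"],
    )


@pytest.fixture(scope="session")
def fixture_index(fixture_cases):
    event_ids = cd.flag_event_cases(fixture_cases, datasets.load_alopecia_smq())
    return cd.build_drug_case_index(fixture_cases, event_ids)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
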