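import datetime as dt

import pytest

from crossvis import StudyDesign, SubjectHistory, WindowSpec, load_design

EVENT = dt.date(2010, 7, 1)


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    """Default design: case 1-50, CW1 101-150, CW2 151-200, horizon 200."""
    return load_design()


@pytest.fixture
def history():
    """Factory for a SubjectHistory from bare offsets."""

    def make(offsets, subject_id="s1", event_date=EVENT):
        return SubjectHistory(subject_id, event_date, tuple(sorted(offsets)))

    return make


@pytest.fixture
def narrow_design() -> StudyDesign:
    """A compact design (case 1-10, CW1 21-30, CW2 31-40) for boundary checks."""
    return StudyDesign(WindowSpec(1, 10), WindowSpec(21, 30), WindowSpec(31, 40), 40)
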