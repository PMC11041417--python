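import datetime as dt

import pytest
from hypothesis import settings

from pdacsym.estimator import SymptomExtractor

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")
from pdacsym.lexicon import default_lexicons
from pdacsym.preprocess import RawNote


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def symptom_lexicons(lexicons):
    return lexicons[0]


@pytest.fixture(scope="session")
def ctx(lexicons):
    return lexicons[1]


@pytest.fixture(scope="session")
def extractor():
    return SymptomExtractor().fit()


@pytest.fixture(scope="session")
def classify(extractor):
    """Classify a single snippet of note text under default rules."""

    def _classify(text, note_date=dt.date(2015, 6, 1),
                  encounter_type="outpatient", **kwargs):
        note = RawNote(note_id="n0", note_date=note_date,
                       encounter_type=encounter_type, text=text, **kwargs)
        return extractor.predict_note(note)

    return _classify
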