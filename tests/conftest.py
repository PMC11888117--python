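from datetime import date

import pytest

from amiomon.rules import LabPanel, default_profile


@pytest.fixture(scope="session")
def config():
    return default_profile()


@pytest.fixture
def make_panel():
    """Factory for panels; unspecified analytes default to reference midpoints."""

    def _make(**overrides):
        values = {
            "tsh": 2.2,
            "ft4": 17.0,
            "ft3": 4.95,
            "ast": 0.38,
            "alt": 0.55,
            "patient_id": "P1",
            "sample_date": date(2022, 6, 1),
        }
        values.update(overrides)
        return LabPanel(**values)

    return _make
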