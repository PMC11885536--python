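import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracle.py importable

from lolscout.fingerprint import HitProfile, TemplateHit


def profile(pid: str, sig=(), nonsig=()) -> HitProfile:
    """Build a HitProfile with significant (1e-6) and non-significant (0.5) hits."""
    hits = [TemplateHit(t, 1e-6) for t in sig] + [TemplateHit(t, 0.5) for t in nonsig]
    return HitProfile(pid, hits)


@pytest.fixture
def make_profile():
    return profile
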