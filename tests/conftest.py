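import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirmeta.io import RankedEntry, RankedStudyList

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


from mirmeta.scenarios import STUDY_DESIGN


@pytest.fixture
def study_design():
    """The 11-study design: (study id, tumor n, normal n, platform size)."""
    return STUDY_DESIGN


def make_list(study="s1", direction="up", mirnas=("a", "b", "c"),
              platform=100, pvals=None, fcs=None):
    entries = tuple(
        RankedEntry(m,
                    None if pvals is None else pvals[i],
                    None if fcs is None else fcs[i])
        for i, m in enumerate(mirnas))
    return RankedStudyList(study, direction, entries, platform)


@pytest.fixture
def mirna_universe():
    return [f"mir{i:03d}" for i in range(300)]
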