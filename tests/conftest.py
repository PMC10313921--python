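import numpy as np
import pytest

from slicescore import DoseResponseCurve

DOSES6 = tuple(np.logspace(-1.5, 1.5, 6))  # 6 log-spaced doses over 3 decades


def make_survival(values, doses=DOSES6, unit="uM", **kw):
    return DoseResponseCurve(
        doses=tuple(doses), values=tuple(values), kind="tumor_survival",
        dose_unit=unit, **kw,
    )


def make_tox(values, doses=DOSES6, unit="uM", **kw):
    return DoseResponseCurve(
        doses=tuple(doses), values=tuple(values), kind="slice_toxicity",
        dose_unit=unit, **kw,
    )


@pytest.fixture
def doses6():
    return np.array(DOSES6)
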