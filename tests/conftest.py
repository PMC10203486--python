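import numpy as np
import pandas as pd
import pytest

from phenolstress.formulas import Formula, parse_formula
from phenolstress.peaklist import PeakList


@pytest.fixture
def catechin() -> Formula:
    return parse_formula("C15H14O6")


def make_peaklist(mz, intensity=None, snr=None, **meta) -> PeakList:
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.full(len(mz), 100.0)
    if snr is None:
        snr = np.full(len(mz), 10.0)
    return PeakList(peaks=pd.DataFrame(
        {"mz": mz, "intensity": intensity, "snr": snr}), **meta)


@pytest.fixture
def peaklist_factory():
    return make_peaklist


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
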