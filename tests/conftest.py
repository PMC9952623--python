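import numpy as np
import pytest

from ctgkit import CTGRecord


@pytest.fixture
def constant_record():
    """30 min of perfectly clean 140 bpm at 4 Hz."""
    n = 30 * 60 * 4
    return CTGRecord(record_id="const", fs_hz=4.0, fhr_bpm=np.full(n, 140.0))


def make_record(fhr, fs_hz=4.0, **meta):
    return CTGRecord(record_id=meta.pop("record_id", "test"), fs_hz=fs_hz,
                     fhr_bpm=np.asarray(fhr, dtype=float), **meta)
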