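import numpy as np
import pytest

from covbias.models import CONDITIONS, DilutionSeries, TranscriptCoverage, TranscriptModel


@pytest.fixture
def single_exon_model():
    return TranscriptModel("T1", "chr1", "+", ((1000, 2000),))


@pytest.fixture
def two_exon_minus_model():
    return TranscriptModel("T2", "chr2", "-", ((0, 100), (200, 250)))


def make_series(replicate: int, depth_by_tid: dict, shares=None) -> DilutionSeries:
    """Build a dilution series whose conditions are scaled copies of one
    base coverage vector per transcript (mouse-only share 0)."""
    if shares is None:
        shares = {"ivt_only": 1.0, "1:1": 0.5, "1:2": 1 / 3, "1:10": 1 / 11,
                  "mouse_only": 0.0}
    coverage = {
        cond: {
            tid: TranscriptCoverage(tid, np.asarray(base, float) * share)
            for tid, base in depth_by_tid.items()
        }
        for cond, share in shares.items()
    }
    return DilutionSeries(replicate, coverage)
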