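import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def oracle_calls(values, low=0.1, min_low=4, min_high=4):
    """Independent run-rule implementation via explicit run-length segments.

    Segments the unmasked bins into alternating low/high runs, opens a call
    at a low run of >= min_low bins, and closes it at the last low bin
    before a high run of >= min_high bins (or the end).  Used as the oracle
    against the production scan.
    """
    idx = [i for i, v in enumerate(values) if v == v]
    segs = []
    for i in idx:
        is_low = values[i] <= low
        if segs and segs[-1][0] == is_low:
            segs[-1][1].append(i)
        else:
            segs.append((is_low, [i]))
    calls, k = [], 0
    while k < len(segs):
        is_low, ids = segs[k]
        if is_low and len(ids) >= min_low:
            start, last, n = ids[0], ids[-1], len(ids)
            k += 1
            while k < len(segs):
                is_low2, ids2 = segs[k]
                if not is_low2 and len(ids2) >= min_high:
                    break
                if is_low2:
                    last, n = ids2[-1], n + len(ids2)
                k += 1
            calls.append((start, last, n))
        else:
            k += 1
    return calls


@pytest.fixture
def oracle():
    return oracle_calls


def profile_from_values(values, chrom="chr1", bin_size=1_000_000, line_id="mut"):
    """Wrap a plain value sequence as a one-chromosome normalized profile."""
    from delscan import NormalizedCoverage

    n = len(values)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n, dtype=np.int64) * bin_size,
            "end": (np.arange(n, dtype=np.int64) + 1) * bin_size,
            "value": np.asarray(values, dtype=float),
        }
    )
    return NormalizedCoverage(line_id=line_id, reference_line_id="wt", bin_size=bin_size, df=df)


@pytest.fixture
def make_profile():
    return profile_from_values
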