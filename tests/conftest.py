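import numpy as np
import pandas as pd
import pytest

ALLC_COLUMNS = ["chrom", "pos", "strand", "tri", "context", "mc", "cov", "low_cov"]


def make_allc(rows):
    """Build an in-memory allc frame from (chrom, pos, strand, tri, context, mc, cov) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "tri", "context", "mc", "cov"])
    df["low_cov"] = False
    return df[ALLC_COLUMNS]


def uniform_chh_allc(chrom, positions, mc, cov):
    """CHH-context allc frame with constant counts at the given positions."""
    return make_allc([(chrom, int(p), "+", "CAA", "CHH", mc, cov) for p in positions])


@pytest.fixture
def two_sample_flat():
    """Two samples, identical counts: a fully homogeneous comparison."""
    pos = np.arange(100, 1100, 10)
    return {
        "a": uniform_chh_allc("Chr1", pos, 3, 10),
        "b": uniform_chh_allc("Chr1", pos, 3, 10),
    }


def reciprocal_overlap(a, b, frac=0.5):
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


def score_recovery(truth_intervals, called_intervals, frac=0.5):
    """(sensitivity, precision) at >= frac reciprocal overlap."""
    if not truth_intervals:
        return float("nan"), float("nan")
    sens = sum(any(reciprocal_overlap(t, p, frac) for p in called_intervals)
               for t in truth_intervals) / len(truth_intervals)
    prec = (sum(any(reciprocal_overlap(t, p, frac) for t in truth_intervals)
                for p in called_intervals) / len(called_intervals)) if called_intervals else float("nan")
    return sens, prec
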