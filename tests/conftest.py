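import itertools
from pathlib import Path

import numpy as np
import pytest

from ctdnakit.io import load_table2_counts

REPO_ROOT = Path(__file__).resolve().parent.parent
FIXTURES = REPO_ROOT / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture(scope="session")
def table2_pairs():
    """The five assayed somatic loci with their printed read counts."""
    return load_table2_counts()


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def brute_force_filter(calls_by_sample, thresholds):
    """Literal evaluation of the five somatic-candidate predicates per call."""
    n_samples = len(calls_by_sample)
    all_calls = [c for calls in calls_by_sample.values() for c in calls if c.is_snv]
    kept = []
    for call in all_calls:
        carriers = {
            c.sample_id
            for c in all_calls
            if (c.chrom, c.pos, c.alt) == (call.chrom, call.pos, call.alt)
        }
        ok = (
            call.region_class == "exonic"
            and call.aaf <= thresholds.max_aaf
            and (call.pop_maf is None or call.pop_maf < thresholds.max_pop_maf)
            and call.depth >= thresholds.min_depth
            and len(carriers) / n_samples <= thresholds.max_recurrence
        )
        if ok:
            kept.append(call)
    return kept


def average_ranks(values):
    """Average ranks of absolute values, written from the definition."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for k in order[i:j]:
            ranks[k] = avg
        i = j
    return ranks


def enumerate_wilcoxon(pre, post):
    """Literal 2^n sign-vector enumeration of the signed-rank test."""
    diffs = [b - a for a, b in zip(pre, post) if b != a]
    n = len(diffs)
    ranks = average_ranks([abs(d) for d in diffs])
    w_obs = sum(r for d, r in zip(diffs, ranks) if d > 0)
    mu = sum(ranks) / 2.0
    n_extreme = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            n_extreme += 1
    return w_obs, n_extreme / 2**n


def sort_and_interpolate_quartile(values, q):
    """Quartile by explicit linear interpolation between order statistics."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    h = q * (len(xs) - 1)
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
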