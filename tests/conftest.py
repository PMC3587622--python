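"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (memoized recursion, exhaustive
substring scans): they define expected values without sharing code with the
package's kernels.
"""

from __future__ import annotations

import random
from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from barkit.filters import DesignConstraints
from barkit.generator import generate_set

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def lev_oracle(a: str, b: str) -> int:
    """Memoized recursive edit distance; N matches nothing."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        x, y = a[i - 1], b[j - 1]
        sub = 1 if (x == "N" or y == "N" or x != y) else 0
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + sub)

    return rec(len(a), len(b))


def padded_oracle(a: str, b: str, padding: int) -> int:
    """Recursive wildcard-padded distance: wildcard columns are free,
    including against a gap."""
    w = "#"
    ap = w * padding + a + w * padding
    bp = w * padding + b + w * padding

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        opts = []
        if i > 0:
            opts.append(rec(i - 1, j) + (0 if ap[i - 1] == w else 1))
        if j > 0:
            opts.append(rec(i, j - 1) + (0 if bp[j - 1] == w else 1))
        if i > 0 and j > 0:
            x, y = ap[i - 1], bp[j - 1]
            if x == w or y == w:
                sub = 0
            else:
                sub = 1 if (x == "N" or y == "N" or x != y) else 0
            opts.append(rec(i - 1, j - 1) + sub)
        return min(opts)

    return rec(len(ap), len(bp))


def semi_global_oracle(barcode: str, window: str) -> int:
    """Minimum edit distance of the barcode to any substring of the window
    (free window flanks by exhaustion)."""
    best = len(barcode)  # empty substring: delete everything
    for i in range(len(window) + 1):
        for j in range(i, len(window) + 1):
            best = min(best, lev_oracle(barcode, window[i:j]))
    return best


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture(scope="session")
def small_barcode_set():
    """50 length-12 barcodes at uniqueness threshold 3 (pairs >= 4)."""
    constraints = DesignConstraints(length=12, count=50, min_distance=3,
                                    padding=0, seed=5)
    bset, report = generate_set(constraints)
    assert not report.exhausted
    return bset
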