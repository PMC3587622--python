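"""Greedy construction of minimum-distance barcode sets.

Random candidates of the configured length and GC content are drawn, pushed
through the composition and thermodynamic filters, and accepted into the
growing set only if their padded edit distance to every accepted barcode
strictly exceeds the uniqueness threshold ``min_distance``.  Generation is a
producer/consumer pipeline in spirit -- candidate generation and set
insertion are independent stages -- but runs single-worker by default so
that a seed reproduces the set bit-for-bit.

The distance screen uses a banded plain edit distance as a cheap lower-bound
filter: removing the ``4 P`` wildcard columns from an optimal padded
alignment costs at most one edit each, so
``levenshtein(a, b) <= padded_distance(a, b, P) + 4 P`` and any pair with
plain distance ``> d_min + 4 P`` is accepted without running the padded DP.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .distance import levenshtein_bounded, padded_distance
from .filters import DesignConstraints, passes_composition_filters

_BASES = "ACGT"


def recommended_min_distance(expected_errors: int) -> int:
    """Smallest set-level minimum edit distance guaranteeing unique
    demultiplexing of reads carrying up to ``expected_errors`` erroneous
    bases: more than twice the expected errors, i.e. ``2 e + 1``."""
    if expected_errors < 0:
        raise ValueError("expected_errors must be >= 0")
    return 2 * expected_errors + 1


@dataclass
class BarcodeSet:
    """An ordered barcode list plus its set-level guarantee: every pair is
    at padded edit distance strictly greater than ``min_distance``
    (padding ``padding``)."""

    barcodes: list[str]
    length: int
    min_distance: int
    padding: int
    constraints: DesignConstraints | None = None

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def __getitem__(self, i: int) -> str:
        return self.barcodes[i]

    @classmethod
    def from_barcodes(cls, barcodes: Sequence[str], min_distance: int = 1,
                      padding: int = 0) -> "BarcodeSet":
        """Wrap an existing barcode list (e.g. read from a file)."""
        barcodes = list(barcodes)
        if not barcodes:
            raise ValueError("empty barcode list")
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise ValueError("barcodes must share one length")
        return cls(barcodes=barcodes, length=lengths.pop(),
                   min_distance=min_distance, padding=padding)


@dataclass
class GenerationReport:
    """Accounting of a generation run: attempts consumed, how many
    candidates each filter rejected, and how many failed the distance
    screen."""

    requested: int
    generated: int = 0
    attempts: int = 0
    filter_failures: Counter = field(default_factory=Counter)
    distance_rejections: int = 0

    @property
    def exhausted(self) -> bool:
        return self.generated < self.requested


def random_candidate(c: DesignConstraints, rng: random.Random) -> str:
    """Uniformly random length-L sequence whose G+C count is drawn uniformly
    from the counts compatible with [gc_min, gc_max]."""
    lo, hi = c.gc_count_range()
    n_gc = rng.randint(lo, hi)
    positions = rng.sample(range(c.length), n_gc)
    strong = set(positions)
    return "".join(
        (rng.choice("GC") if i in strong else rng.choice("AT"))
        for i in range(c.length))


def _pair_ok(candidate: str, accepted: Sequence[str], d_min: int,
             padding: int) -> bool:
    """True iff candidate keeps padded distance strictly greater than
    ``d_min`` to every accepted barcode.  Partitioning ``accepted`` into
    sub-scans cannot change the outcome (it is a conjunction over
    independent pairs)."""
    if padding == 0:
        for b in accepted:
            if levenshtein_bounded(candidate, b, d_min) is not None:
                return False
        return True
    screen = d_min + 4 * padding
    for b in accepted:
        if levenshtein_bounded(candidate, b, screen) is None:
            continue  # plain distance alone already guarantees the bound
        if padded_distance(candidate, b, padding) <= d_min:
            return False
    return True


def try_insert(candidate: str, bset: BarcodeSet) -> bool:
    """Append ``candidate`` iff its padded distance to every accepted
    barcode strictly exceeds the set's threshold; returns whether it was
    accepted.  Strict inequality is what makes the error-tolerance claim
    exact: a set built at threshold ``d`` has all pairs at distance
    ``>= d + 1``, so reads with up to ``floor(d / 2)`` edits can never tie
    between two barcodes.  The candidate is assumed to have already passed
    the composition filters."""
    if _pair_ok(candidate, bset.barcodes, bset.min_distance, bset.padding):
        bset.barcodes.append(candidate)
        return True
    return False


def generate_set(c: DesignConstraints, max_attempts: int | None = None,
                 ) -> tuple[BarcodeSet, GenerationReport]:
    """Produce up to ``c.count`` barcodes satisfying all filters and the
    pairwise distance guarantee.

    Candidates are drawn and screened in strict arrival order from
    ``c.seed``, so identical constraints reproduce identical sets.  If
    ``max_attempts`` (default ``1000 * count``) is exhausted first -- e.g.
    under impossible constraint combinations -- a partial set is returned
    together with the report; exhaustion is a reported condition, never an
    infinite loop or an exception.
    """
    if max_attempts is None:
        max_attempts = 1000 * c.count
    if max_attempts < c.count:
        raise ValueError("max_attempts must be at least the requested count")
    rng = random.Random(c.seed)
    bset = BarcodeSet(barcodes=[], length=c.length,
                      min_distance=c.min_distance, padding=c.padding,
                      constraints=c)
    report = GenerationReport(requested=c.count)
    while len(bset) < c.count and report.attempts < max_attempts:
        report.attempts += 1
        candidate = random_candidate(c, rng)
        ok, label = passes_composition_filters(candidate, c)
        if not ok:
            report.filter_failures[label] += 1
            continue
        if try_insert(candidate, bset):
            report.generated += 1
        else:
            report.distance_rejections += 1
    return bset, report


def distance_histogram(bset: BarcodeSet) -> dict[int, int]:
    """Padded-distance counts over all barcode pairs (the screening metric);
    counts sum to n(n-1)/2 and never put mass at or below
    ``min_distance``."""
    hist: Counter = Counter()
    bc = bset.barcodes
    for i in range(len(bc)):
        for j in range(i + 1, len(bc)):
            hist[padded_distance(bc[i], bc[j], bset.padding)] += 1
    return dict(sorted(hist.items()))


def write_barcodes(bset: BarcodeSet, path: str | Path) -> None:
    """One barcode per line, no header."""
    Path(path).write_text("".join(b + "\n" for b in bset.barcodes))


def read_barcodes(path: str | Path, min_distance: int = 1,
                  padding: int = 0) -> BarcodeSet:
    """Read a one-barcode-per-line file (round-trips with
    :func:`write_barcodes`)."""
    lines = [ln.strip().upper() for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    return BarcodeSet.from_barcodes(lines, min_distance=min_distance,
                                    padding=padding)


def write_histogram(hist: dict[int, int], path: str | Path) -> None:
    """Tab-separated ``distance<TAB>pair_count``, ascending distance."""
    Path(path).write_text(
        "".join(f"{d}\t{n}\n" for d, n in sorted(hist.items())))
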