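"""Edit-distance kernels.

Three related measures are used throughout the package:

* :func:`levenshtein` -- plain unit-cost edit distance between two sequences.
* :func:`padded_distance` -- edit distance after flanking *both* sequences
  with ``P`` wildcard positions on each end.  A wildcard aligns to any base,
  and to a gap, at zero cost.  This is the metric used when designing barcode
  sets that must stay distinguishable under small positional shifts caused by
  insertions or deletions.
* :func:`semi_global_align` -- alignment of a (short) barcode against a
  (longer) read window in which the barcode must be covered end to end while
  the window's flanks are free.  This is the measure used at demultiplexing
  time.

The kernels treat ``N`` conservatively: an ``N`` in a read matches nothing,
i.e. it costs one edit against every base (including another ``N``).  Barcodes
themselves never contain ``N``.

For plain A/C/G/T inputs the bounded helpers delegate to ``edlib`` (Myers'
bit-parallel algorithm); the reference dynamic programs below define the
semantics and are exercised directly for everything edlib cannot express
(wildcard padding, alignment tie-breaking, ``N``-vs-``N`` columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

WILDCARD = "#"


def _match_cost(x: str, y: str) -> int:
    """Unit substitution cost; N never matches, a wildcard always does."""
    if x == WILDCARD or y == WILDCARD:
        return 0
    if x == "N" or y == "N":
        return 1
    return 0 if x == y else 1


def _lev_dp(a: str, b: str) -> int:
    """Row-wise reference DP, used when edlib's match semantics differ."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + _match_cost(ca, cb)))
        prev = cur
    return prev[-1]


def levenshtein(a: str, b: str) -> int:
    """Minimum number of substitutions, insertions and deletions turning
    ``a`` into ``b``.  Symmetric; satisfies the triangle inequality."""
    if not a or not b:
        return max(len(a), len(b))
    if "N" in a and "N" in b:
        # edlib would score N==N as a match; our semantics do not.
        return _lev_dp(a, b)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def levenshtein_bounded(a: str, b: str, limit: int) -> int | None:
    """Edit distance if it is ``<= limit``, else ``None``.

    Internal fast path (edlib with a band); callers must pass N-free
    sequences on at least one side.
    """
    d = edlib.align(a, b, mode="NW", task="distance", k=limit)["editDistance"]
    return None if d == -1 else d


def padded_distance(a: str, b: str, padding: int) -> int:
    """Edit distance between ``a`` and ``b`` after adding ``padding``
    wildcard positions to both ends of both sequences.

    A column containing a wildcard is free, whether the wildcard aligns to a
    base or to a gap, so the measure is tolerant to shifts of up to
    ``padding`` positions: ``padded_distance("ACGTAC", "CGTACA", 1) == 0``.
    Equals :func:`levenshtein` when ``padding`` is 0, and never exceeds it.
    """
    if padding < 0:
        raise ValueError("padding must be >= 0")
    if padding == 0:
        return levenshtein(a, b)
    pad = WILDCARD * padding
    ap = pad + a + pad
    bp = pad + b + pad
    # DP where deleting/inserting a wildcard costs nothing.
    prev = [0] * (len(bp) + 1)
    for j, cb in enumerate(bp, 1):
        prev[j] = prev[j - 1] + (0 if cb == WILDCARD else 1)
    for ca in ap:
        dcost = 0 if ca == WILDCARD else 1
        cur = [prev[0] + dcost]
        for j, cb in enumerate(bp, 1):
            icost = 0 if cb == WILDCARD else 1
            cur.append(min(prev[j] + dcost, cur[j - 1] + icost,
                           prev[j - 1] + _match_cost(ca, cb)))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning a barcode inside a read window.

    ``offset`` is the 0-based window position where the barcode's alignment
    starts; ``mismatch_positions`` lists one window position per edit column
    (substitution, insertion or deletion), so its length equals ``distance``.
    A deletion column (barcode base aligned to a gap) is charged to the
    window position at which the gap opens, which may equal ``len(window)``
    when the gap sits at the right edge.
    """

    distance: int
    offset: int
    mismatch_positions: tuple[int, ...]


def semi_global_distance(barcode: str, window: str,
                         limit: int | None = None) -> int | None:
    """Distance-only semi-global alignment via edlib's infix mode.

    Returns ``None`` when ``limit`` is given and the distance exceeds it.
    The barcode must be N-free (always true for designed barcodes).
    """
    if not window:
        return None if limit is not None and len(barcode) > limit else len(barcode)
    k = -1 if limit is None else limit
    d = edlib.align(barcode, window, mode="HW", task="distance", k=k)["editDistance"]
    return None if d == -1 else d


def semi_global_align(barcode: str, window: str) -> AlignmentResult:
    """Align ``barcode`` against ``window`` with free window flanks.

    Every base of the barcode is aligned; the minimum over all end positions
    is returned.  Ties on distance are broken deterministically: smallest
    offset first, then fewest indel columns, so ``mismatch_positions`` is a
    pure function of the inputs.
    """
    if not barcode:
        raise ValueError("barcode must be non-empty")
    if not window:
        raise ValueError("window must be non-empty")
    m, n = len(barcode), len(window)
    # Cell value: (cost, start_column, indel_count); lexicographic minimum is
    # taken over the three moves, which implements the documented tie-break.
    value = [[(0, j, 0) for j in range(n + 1)]]
    moves: list[list[str]] = [["S"] * (n + 1)]
    for i in range(1, m + 1):
        ca = barcode[i - 1]
        pv = value[i - 1]
        vrow = [(pv[0][0] + 1, pv[0][1], pv[0][2] + 1)]
        mrow = ["U"]
        for j in range(1, n + 1):
            sub = _match_cost(ca, window[j - 1])
            pc, ps, pi = pv[j - 1]
            best = (pc + sub, ps, pi)
            move = "D"
            uc, us, ui = pv[j]
            cand = (uc + 1, us, ui + 1)
            if cand < best:
                best, move = cand, "U"
            lc, ls, li = vrow[j - 1]
            cand = (lc + 1, ls, li + 1)
            if cand < best:
                best, move = cand, "L"
            vrow.append(best)
            mrow.append(move)
        value.append(vrow)
        moves.append(mrow)
    end = min(range(n + 1), key=lambda j: (value[m][j], j))
    cost, start, _ = value[m][end]
    positions: list[int] = []
    i, j = m, end
    while i > 0:
        move = moves[i][j]
        if move == "D":
            if _match_cost(barcode[i - 1], window[j - 1]):
                positions.append(j - 1)
            i -= 1
            j -= 1
        elif move == "U":
            positions.append(j)
            i -= 1
        else:  # "L"
            positions.append(j - 1)
            j -= 1
    positions.reverse()
    return AlignmentResult(distance=cost, offset=start,
                           mismatch_positions=tuple(positions))
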