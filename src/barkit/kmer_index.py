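"""k-mer index for candidate-barcode retrieval.

Demultiplexing never aligns a read window against every barcode.  Instead a
hash map from each k-mer to the barcodes containing it is built once; the
window's own k-mers then retrieve a small candidate set.  By the q-gram
lemma, a window within ``e`` substitutions of a length-``L`` barcode still
shares at least one intact k-mer with it whenever ``k <= floor(L / (e+1))``,
so retrieval is lossless at the recommended k.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping


def recommended_k(length: int, errors: int) -> int:
    """Largest k-mer length such that ``errors`` edits cannot destroy every
    length-k window of a length-``length`` barcode: ``floor(L / (e+1))``."""
    if errors < 0:
        raise ValueError("errors must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    k = length // (errors + 1)
    if k < 1:
        raise ValueError(
            f"no usable k-mer length for L={length} with {errors} errors")
    return k


def _kmers(s: str, k: int) -> Iterable[str]:
    for i in range(len(s) - k + 1):
        mer = s[i:i + k]
        if "N" not in mer:
            yield mer


@dataclass(frozen=True)
class KmerIndex:
    """Map from each length-``k`` substring to the barcodes containing it."""

    k: int
    entries: Mapping[str, tuple[int, ...]] = field(repr=False)

    def candidate_hits(self, window: str) -> Counter:
        """Barcode id -> number of window k-mers shared with that barcode
        (used to order alignment candidates most-promising first)."""
        hits: Counter = Counter()
        seen: set[str] = set()
        for mer in _kmers(window, self.k):
            if mer in seen:
                continue
            seen.add(mer)
            for ident in self.entries.get(mer, ()):
                hits[ident] += 1
        return hits


def build_index(barcodes, k: int) -> KmerIndex:
    """Index every overlapping k-mer of every barcode.

    ``barcodes`` may be a :class:`~barkit.generator.BarcodeSet` or any
    sequence of barcode strings; identifiers are positions in that order.
    k-mers containing N are never indexed.
    """
    seqs = getattr(barcodes, "barcodes", barcodes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if any(len(b) < k for b in seqs):
        raise ValueError("k exceeds a barcode length")
    entries: dict[str, list[int]] = {}
    for ident, b in enumerate(seqs):
        for mer in set(_kmers(b, k)):
            entries.setdefault(mer, []).append(ident)
    return KmerIndex(k=k, entries={m: tuple(ids) for m, ids in entries.items()})


def query_candidates(window: str, index: KmerIndex) -> set[int]:
    """Union of index hits over all overlapping k-mers of ``window``;
    empty when the window is shorter than k."""
    if len(window) < index.k:
        return set()
    return set(index.candidate_hits(window))
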