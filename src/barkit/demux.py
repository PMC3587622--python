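"""Read classification: assign FASTQ reads back to their barcodes.

For each read a window around the expected barcode position is extracted
(widened by the positional error, or the whole read when the position is
unknown), the k-mer index proposes candidate barcodes, and each candidate is
scored by semi-global alignment (full barcode coverage, free window flanks).
A read is *matched* when a unique candidate attains the minimal distance
within the acceptance cut-off, *ambiguous* when two or more candidates tie
even after the quality tie-break, and *unmatched* when no candidate is close
enough.

The quality tie-break sums the Phred scores of the read positions at which
each tied candidate's alignment places its edits; the candidate whose edits
sit on the lowest-confidence bases wins, because sequencing errors are most
plausible there.  Equal sums stay tied and the read is ambiguous.

Classification of each read is independent of every other read, so the work
may be partitioned freely across threads; output is restored to input order
by default.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from .distance import AlignmentResult, semi_global_align, semi_global_distance
from .generator import BarcodeSet, read_barcodes
from .kmer_index import KmerIndex, build_index, recommended_k

MATCHED = "matched"
AMBIGUOUS = "ambiguous"
UNMATCHED = "unmatched"

_PHRED_OFFSET = 33  # Sanger encoding


@dataclass
class SequenceRead:
    """A FASTQ record; ``qualities`` is the raw Phred+33 string."""

    identifier: str
    sequence: str
    qualities: str
    mate: "SequenceRead | None" = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.identifier!r}: sequence and quality lengths differ")

    def phred(self, i: int) -> int:
        return ord(self.qualities[i]) - _PHRED_OFFSET


@dataclass(frozen=True)
class DemuxParams:
    """Classification parameters.

    ``positional_error`` widens the extracted window by that many bases on
    each side; ``-1`` means the barcode position is unknown and the whole
    read is scanned (slower, less specific).  ``max_distance=None`` resolves
    to ``floor(min_distance / 2)`` of the barcode set, the largest cut-off
    at which the design guarantee still forces a unique correct answer.
    ``k=None`` resolves to ``recommended_k(L, floor(min_distance / 2))``.
    """

    barcode_start: int = 0
    positional_error: int = 0
    k: int | None = None
    max_distance: int | None = None
    padding: int = 0

    def __post_init__(self) -> None:
        if self.positional_error < -1:
            raise ValueError("positional_error must be >= -1")
        if self.max_distance is not None and self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.barcode_start < 0:
            raise ValueError("barcode_start must be >= 0")


@dataclass(frozen=True)
class DemuxResult:
    read_id: str
    status: str  # MATCHED | AMBIGUOUS | UNMATCHED
    barcode_id: int | None = None
    distance: int | None = None
    offset: int | None = None  # read coordinate where the barcode aligns


def extract_window(read: SequenceRead, p: DemuxParams, length: int,
                   ) -> tuple[str, int]:
    """Window of the read that can contain the barcode, and its start.

    With positional error ``pe >= 0`` this is
    ``[max(0, start - pe), min(len, start + L + pe))``; with ``pe == -1``
    the whole read.  An empty window (barcode start beyond the read end)
    is returned as ``("", start)`` and classified unmatched upstream.
    """
    seq = read.sequence
    if p.positional_error == -1:
        return seq, 0
    lo = max(0, p.barcode_start - p.positional_error)
    hi = min(len(seq), p.barcode_start + length + p.positional_error)
    if lo >= len(seq):
        return "", lo
    return seq[lo:hi], lo


def _resolve(p: DemuxParams, bset: BarcodeSet) -> tuple[int, int]:
    tolerated = bset.min_distance // 2
    max_d = p.max_distance if p.max_distance is not None else tolerated
    k = p.k if p.k is not None else recommended_k(bset.length, tolerated)
    return k, max_d


def quality_tie_break(tied: Sequence[tuple[int, AlignmentResult]],
                      read: SequenceRead) -> list[tuple[int, AlignmentResult]]:
    """Keep the tied candidate(s) whose edit columns fall on the
    lowest-quality read bases (summed Phred).  A single survivor resolves
    the tie; several survivors stay ambiguous."""
    if len(tied) < 2:
        return list(tied)
    last = len(read.sequence) - 1
    scored = []
    for ident, aln in tied:
        total = sum(read.phred(min(pos, last)) for pos in aln.mismatch_positions)
        scored.append((total, ident, aln))
    best = min(s[0] for s in scored)
    return [(ident, aln) for total, ident, aln in scored if total == best]


def classify_read(read: SequenceRead, index: KmerIndex, bset: BarcodeSet,
                  p: DemuxParams) -> DemuxResult:
    """Classify one read against the barcode set.

    Candidates come from the k-mer index; each is scored by semi-global
    alignment, with a banded distance-only pass (most-shared-k-mers first)
    pruning candidates before the full alignment with positions is computed
    for the minimal-distance ties only.
    """
    _, max_d = _resolve(p, bset)
    window, wstart = extract_window(read, p, bset.length)
    if not window:
        return DemuxResult(read.identifier, UNMATCHED)
    hits = index.candidate_hits(window)
    if not hits:
        return DemuxResult(read.identifier, UNMATCHED)
    # Most shared k-mers first: the true barcode is found early, which
    # shrinks the distance band for everyone after it.
    order = sorted(hits, key=lambda ident: (-hits[ident], ident))
    best = max_d
    tied_ids: list[int] = []
    for ident in order:
        d = semi_global_distance(bset[ident], window, limit=best)
        if d is None:
            continue
        if d < best:
            best = d
            tied_ids = [ident]
        else:  # d == best
            tied_ids.append(ident)
    if not tied_ids:
        return DemuxResult(read.identifier, UNMATCHED)
    aligned = [(ident, semi_global_align(bset[ident], window))
               for ident in sorted(tied_ids)]
    # Window coordinates -> read coordinates for quality lookups and output.
    shifted = [(ident,
                AlignmentResult(a.distance, a.offset + wstart,
                                tuple(pos + wstart
                                      for pos in a.mismatch_positions)))
               for ident, a in aligned]
    if len(shifted) > 1:
        shifted = quality_tie_break(shifted, read)
    if len(shifted) > 1:
        return DemuxResult(read.identifier, AMBIGUOUS, distance=best)
    ident, aln = shifted[0]
    return DemuxResult(read.identifier, MATCHED, barcode_id=ident,
                       distance=aln.distance, offset=aln.offset)


def _parse_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """4-line FASTQ records; raises naming the failing record index."""
    with open(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            if not lines[3]:
                raise ValueError(f"{path}: truncated FASTQ record {record}")
            header, seq, sep, qual = (ln.rstrip("\n") for ln in lines)
            if not header.startswith("@") or not sep.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record {record}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {record}: sequence/quality length mismatch")
            yield SequenceRead(identifier=header[1:].split()[0],
                               sequence=seq.upper(), qualities=qual)
            record += 1


def _format_record(read: SequenceRead, sep: str) -> str:
    return f"@{read.identifier}\n{read.sequence}\n{sep}\n{read.qualities}\n"


def _annotation(result: DemuxResult, bset: BarcodeSet) -> str:
    return (f"+BC:{bset[result.barcode_id]} ID:{result.barcode_id} "
            f"ED:{result.distance}")


def _classify_many(reads: Sequence[SequenceRead], index: KmerIndex,
                   bset: BarcodeSet, p: DemuxParams,
                   threads: int = 1) -> list[DemuxResult]:
    if threads <= 1 or len(reads) < 2 * threads:
        return [classify_read(r, index, bset, p) for r in reads]
    with ThreadPoolExecutor(max_workers=threads) as pool:
        return list(pool.map(lambda r: classify_read(r, index, bset, p),
                             reads, chunksize=256))


def demultiplex_fastq(fastq1: str | Path, barcodes: str | Path | BarcodeSet,
                      p: DemuxParams, out_prefix: str | Path,
                      fastq2: str | Path | None = None, threads: int = 1,
                      ) -> tuple[dict[str, int], list[DemuxResult]]:
    """Demultiplex single- or paired-end FASTQ into per-status streams.

    Matched records carry ``+BC:<sequence> ID:<id> ED:<distance>`` on the
    separator line.  For paired input the barcode is located on read 1 and
    the mate inherits the assignment into the paired (``.R2``) outputs.
    Returns per-status counts and the per-read results, in input order.
    """
    if isinstance(barcodes, BarcodeSet):
        bset = barcodes
    else:
        bset = read_barcodes(barcodes)
        if p.max_distance is None or p.k is None:
            raise ValueError("max_distance and k must be given explicitly "
                             "when barcodes come from a bare list file")
    reads = list(_parse_fastq(fastq1))
    mates: list[SequenceRead] | None = None
    if fastq2 is not None:
        mates = list(_parse_fastq(fastq2))
        if len(mates) != len(reads):
            raise ValueError("paired FASTQ files differ in record count")
    index = build_index(bset, _resolve(p, bset)[0])
    results = _classify_many(reads, index, bset, p, threads=threads)

    prefix = str(out_prefix)
    suffix1 = ".R1" if mates is not None else ""
    handles = {status: open(f"{prefix}.{status}{suffix1}.fastq", "w")
               for status in (MATCHED, AMBIGUOUS, UNMATCHED)}
    handles2 = {}
    if mates is not None:
        handles2 = {status: open(f"{prefix}.{status}.R2.fastq", "w")
                    for status in (MATCHED, AMBIGUOUS, UNMATCHED)}
    counts = {MATCHED: 0, AMBIGUOUS: 0, UNMATCHED: 0}
    try:
        for i, (read, result) in enumerate(zip(reads, results)):
            counts[result.status] += 1
            sep = (_annotation(result, bset)
                   if result.status == MATCHED else "+")
            handles[result.status].write(_format_record(read, sep))
            if mates is not None:
                handles2[result.status].write(_format_record(mates[i], sep))
    finally:
        for h in (*handles.values(), *handles2.values()):
            h.close()
    return counts, results
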