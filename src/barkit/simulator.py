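"""Read simulation with a per-base error model, and accuracy evaluation.

Each simulated read picks a barcode uniformly at random, places it at the
configured start position, fills any flanks with uniform random bases, and
then walks the sequence base by base applying independent substitution,
insertion and deletion events.  Ground truth (read id -> source barcode id)
travels with the read set, so demultiplexing accuracy -- wrongly classified,
ambiguous, unmatched -- can be measured exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .demux import AMBIGUOUS, MATCHED, DemuxResult, SequenceRead
from .generator import BarcodeSet

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base event probabilities.

    ``substitutions_only(rate)`` models platforms whose errors are almost
    exclusively miscalls; ``mixed(total)`` splits a total per-base error
    rate among substitutions, insertions and deletions (80/10/10 by
    default)."""

    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.substitution, self.insertion, self.deletion):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @classmethod
    def substitutions_only(cls, rate: float) -> "ErrorModel":
        return cls(substitution=rate)

    @classmethod
    def mixed(cls, total: float,
              split: tuple[float, float, float] = (0.8, 0.1, 0.1),
              ) -> "ErrorModel":
        if abs(sum(split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        return cls(substitution=total * split[0],
                   insertion=total * split[1],
                   deletion=total * split[2])


@dataclass
class SimulatedReadSet:
    """Simulated FASTQ records plus their ground-truth labels and the edit
    counts actually applied (for rate audits)."""

    reads: list[SequenceRead]
    truth: dict[str, int]
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0

    def __len__(self) -> int:
        return len(self.reads)


def _apply_errors(seq: str, em: ErrorModel, rng: random.Random,
                  ) -> tuple[str, int, int, int]:
    if em.substitution == em.insertion == em.deletion == 0.0:
        return seq, 0, 0, 0
    out: list[str] = []
    n_sub = n_ins = n_del = 0
    for base in seq:
        if em.deletion and rng.random() < em.deletion:
            n_del += 1
            continue
        if em.substitution and rng.random() < em.substitution:
            base = rng.choice(_OTHER[base])
            n_sub += 1
        out.append(base)
        if em.insertion and rng.random() < em.insertion:
            out.append(rng.choice(_BASES))
            n_ins += 1
    return "".join(out), n_sub, n_ins, n_del


def simulate_reads(bset: BarcodeSet, n: int, em: ErrorModel,
                   read_length: int | None = None, barcode_start: int = 0,
                   seed: int = 0, quality: int = 30) -> SimulatedReadSet:
    """Simulate ``n`` barcoded reads with ground truth.

    ``read_length`` defaults to the barcode length (bare-barcode reads);
    longer reads get uniform random flanking bases.  Qualities are constant
    (Q30 by default) so that quality tie-breaking can be exercised
    separately with hand-built inputs.  Reproducible from ``seed``.
    """
    length = bset.length if read_length is None else read_length
    if length < bset.length + barcode_start:
        raise ValueError("read_length must fit barcode_start + barcode")
    rng = random.Random(seed)
    n_barcodes = len(bset)
    tail = length - bset.length - barcode_start
    reads: list[SequenceRead] = []
    truth: dict[str, int] = {}
    totals = [0, 0, 0]
    for i in range(n):
        ident = rng.randrange(n_barcodes)
        left = "".join(rng.choice(_BASES) for _ in range(barcode_start))
        right = "".join(rng.choice(_BASES) for _ in range(tail))
        seq, n_sub, n_ins, n_del = _apply_errors(
            left + bset[ident] + right, em, rng)
        totals[0] += n_sub
        totals[1] += n_ins
        totals[2] += n_del
        name = f"read{i}"
        reads.append(SequenceRead(identifier=name, sequence=seq,
                                  qualities=chr(33 + quality) * len(seq)))
        truth[name] = ident
    return SimulatedReadSet(reads=reads, truth=truth,
                            n_substitutions=totals[0],
                            n_insertions=totals[1], n_deletions=totals[2])


def write_fastq(readset: SimulatedReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f"@{r.identifier}\n{r.sequence}\n+\n{r.qualities}\n")


def write_truth(readset: SimulatedReadSet, path: str | Path) -> None:
    """Tab-separated ``read_id<TAB>barcode_id``."""
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f"{r.identifier}\t{readset.truth[r.identifier]}\n")


def read_truth(path: str | Path) -> dict[str, int]:
    truth: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            name, ident = line.split("\t")
            truth[name] = int(ident)
    return truth


@dataclass(frozen=True)
class AccuracyReport:
    """Demultiplexing accuracy against ground truth.

    ``pct_not_unique`` counts every read without a unique correct-or-wrong
    assignment (ties plus no-acceptable-hit), the headline
    "cannot be uniquely classified" figure."""

    n_reads: int
    n_correct: int
    n_wrong: int
    n_ambiguous: int
    n_unmatched: int

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_reads if self.n_reads else 0.0

    @property
    def pct_wrong(self) -> float:
        return self._pct(self.n_wrong)

    @property
    def pct_ambiguous(self) -> float:
        return self._pct(self.n_ambiguous)

    @property
    def pct_unmatched(self) -> float:
        return self._pct(self.n_unmatched)

    @property
    def pct_not_unique(self) -> float:
        return self._pct(self.n_ambiguous + self.n_unmatched)

    def summary(self) -> str:
        return ("reads\tcorrect\twrong\tambiguous\tunmatched\n"
                f"{self.n_reads}\t{self.n_correct}\t{self.n_wrong}\t"
                f"{self.n_ambiguous}\t{self.n_unmatched}\n")


def evaluate(results: Iterable[DemuxResult],
             truth: SimulatedReadSet | Mapping[str, int]) -> AccuracyReport:
    """Score demultiplexing results against the simulation's truth map."""
    labels = truth.truth if isinstance(truth, SimulatedReadSet) else truth
    n = n_correct = n_wrong = n_ambiguous = n_unmatched = 0
    for res in results:
        if res.read_id not in labels:
            raise ValueError(f"unknown read identifier {res.read_id!r}")
        n += 1
        if res.status == MATCHED:
            if res.barcode_id == labels[res.read_id]:
                n_correct += 1
            else:
                n_wrong += 1
        elif res.status == AMBIGUOUS:
            n_ambiguous += 1
        else:
            n_unmatched += 1
    return AccuracyReport(n_reads=n, n_correct=n_correct, n_wrong=n_wrong,
                          n_ambiguous=n_ambiguous, n_unmatched=n_unmatched)
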