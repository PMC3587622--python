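"""Sequence-composition screens applied to every candidate barcode.

A candidate must sit inside the configured GC window, avoid long mono-, di-
and tri-nucleotide tandem repeats, be linguistically complex, contain no
forbidden motif (e.g. restriction sites) on either strand, stay distant from
its own reverse complement, and pass the thermodynamic screens of
:mod:`barkit.thermo`.  Filters are evaluated in a fixed order so that the
reported first failure is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

from Bio import SeqIO

from . import thermo
from .distance import levenshtein

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

#: Filter evaluation order; the first failing label is reported.
FILTER_ORDER = ("gc", "homopolymer", "dimer_repeat", "trimer_repeat",
                "complexity", "motif", "revcomp_distance", "self_hyb",
                "cross_hyb")


def _validate(s: str) -> str:
    if set(s) - _VALID:
        raise ValueError(f"non-ACGTN character in sequence: {s!r}")
    return s


def reverse_complement(s: str) -> str:
    """Watson-Crick complement, reversed.  An involution; N maps to N."""
    _validate(s)
    return s.translate(_COMPLEMENT)[::-1]


def gc_content(s: str) -> float:
    """Fraction of G and C bases, in [0, 1]."""
    if not s:
        raise ValueError("empty sequence has no GC content")
    return (s.count("G") + s.count("C")) / len(s)


def max_repeat_run(s: str, unit_length: int) -> int:
    """Maximum number of consecutive tandem copies of any repeat unit of the
    given length; ``unit_length=1`` is the homopolymer run length in bases."""
    if unit_length not in (1, 2, 3):
        raise ValueError("unit_length must be 1, 2 or 3")
    if not s:
        raise ValueError("empty sequence")
    u = unit_length
    best = 1 if len(s) >= u else 0
    for i in range(len(s) - u + 1):
        unit = s[i:i + u]
        n = 1
        while s[i + n * u:i + (n + 1) * u] == unit:
            n += 1
        if n > best:
            best = n
    return best


def complexity_score(s: str) -> float:
    """Distinct overlapping 3-mers divided by the number of 3-mer windows.

    Low-complexity sequences (repeat-degenerate, e.g. ``ACGTACGT...``) score
    low; a sequence whose 3-mers are all distinct scores 1.0.
    """
    if len(s) < 3:
        raise ValueError("complexity needs at least 3 bases")
    windows = len(s) - 2
    return len({s[i:i + 3] for i in range(windows)}) / windows


def contains_motif(s: str, motifs: Sequence[str]) -> bool:
    """True iff any motif occurs in ``s`` or in its reverse complement
    (restriction sites are double-stranded, so both strands are screened)."""
    if not motifs:
        return False
    rc = reverse_complement(s)
    return any(m in s or m in rc for m in motifs)


@dataclass(frozen=True)
class DesignConstraints:
    """Every threshold governing barcode design.

    Composition defaults (GC 45-65%, homopolymer limit 4, self-hybridisation
    ceiling 50 degC) are the tool's standard operating point for length-18
    tags.  ``min_revcomp_distance=None`` means "use ``min_distance``".
    """

    length: int = 18
    count: int = 1000
    gc_min: float = 0.45
    gc_max: float = 0.65
    max_homopolymer: int = 4
    max_dimer_repeat: int = 3
    max_trimer_repeat: int = 3
    min_complexity: float = 0.5
    self_hyb_tm_max: float = 50.0
    forbidden_motifs: tuple[str, ...] = ()
    primer_sequences: tuple[str, ...] = ()
    cross_hyb_tm_max: float = 50.0
    min_revcomp_distance: int | None = None
    min_distance: int = 4
    padding: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min <= self.gc_max <= 1:
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        for m in self.forbidden_motifs + self.primer_sequences:
            _validate(m)

    @property
    def revcomp_distance(self) -> int:
        return (self.min_revcomp_distance
                if self.min_revcomp_distance is not None
                else self.min_distance)

    def gc_count_range(self) -> tuple[int, int]:
        """Inclusive range of G+C counts compatible with the GC bounds."""
        lo = math.ceil(self.gc_min * self.length - 1e-9)
        hi = math.floor(self.gc_max * self.length + 1e-9)
        lo, hi = max(lo, 0), min(hi, self.length)
        if lo > hi:
            raise ValueError("GC bounds admit no integer base count "
                             f"for length {self.length}")
        return lo, hi

    @classmethod
    def from_config_file(cls, path: str | Path, **overrides) -> "DesignConstraints":
        """Read ``key=value`` lines (# starts a comment) into constraints.

        List-valued keys (``forbidden_motifs``, ``primer_sequences``) take
        comma-separated sequences.  Keyword overrides win over file values.
        """
        values: dict = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key in ("forbidden_motifs", "primer_sequences"):
                values[key] = tuple(v.strip().upper()
                                    for v in val.split(",") if v.strip())
            elif key in ("gc_min", "gc_max", "self_hyb_tm_max",
                         "cross_hyb_tm_max", "min_complexity"):
                values[key] = float(val)
            else:
                values[key] = int(val)
        values.update(overrides)
        return cls(**values)

    def with_sequences_from_fasta(self, motifs: str | Path | None = None,
                                  primers: str | Path | None = None,
                                  ) -> "DesignConstraints":
        """Return a copy with forbidden motifs and/or primers loaded from
        FASTA files."""
        out = self
        if motifs is not None:
            seqs = tuple(str(r.seq).upper() for r in SeqIO.parse(str(motifs), "fasta"))
            out = replace(out, forbidden_motifs=seqs)
        if primers is not None:
            seqs = tuple(str(r.seq).upper() for r in SeqIO.parse(str(primers), "fasta"))
            out = replace(out, primer_sequences=seqs)
        return out


class FilterResult(NamedTuple):
    passed: bool
    failed: str | None  # first failing label from FILTER_ORDER, or None


def passes_composition_filters(s: str, c: DesignConstraints) -> FilterResult:
    """Apply every composition and thermodynamic screen, in the fixed order
    of :data:`FILTER_ORDER`, reporting the first failure."""
    if len(s) != c.length:
        raise ValueError(f"candidate length {len(s)} != configured {c.length}")
    _validate(s)
    if not c.gc_min <= gc_content(s) <= c.gc_max:
        return FilterResult(False, "gc")
    if max_repeat_run(s, 1) > c.max_homopolymer:
        return FilterResult(False, "homopolymer")
    if max_repeat_run(s, 2) > c.max_dimer_repeat:
        return FilterResult(False, "dimer_repeat")
    if len(s) >= 6 and max_repeat_run(s, 3) > c.max_trimer_repeat:
        return FilterResult(False, "trimer_repeat")
    if len(s) >= 3 and complexity_score(s) < c.min_complexity:
        return FilterResult(False, "complexity")
    if contains_motif(s, c.forbidden_motifs):
        return FilterResult(False, "motif")
    if levenshtein(s, reverse_complement(s)) < c.revcomp_distance:
        return FilterResult(False, "revcomp_distance")
    if thermo.best_self_structure(s).tm > c.self_hyb_tm_max:
        return FilterResult(False, "self_hyb")
    for primer in c.primer_sequences:
        if thermo.cross_hyb_tm(s, primer).tm > c.cross_hyb_tm_max:
            return FilterResult(False, "cross_hyb")
    return FilterResult(True, None)
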