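"""Secondary-structure and cross-hybridisation screening.

Barcodes that fold on themselves (hairpins), dimerise with their own copies,
or anneal to the experiment's primers/adapters interfere with library
preparation.  This module scores such structures with a nearest-neighbor
stacked-stem model and a two-state melting temperature, and the filter layer
rejects candidates whose strongest structure melts above a configurable
threshold (50 degC by default).

The model is deliberately a screen, not a folding engine: only perfectly
complementary, ungapped stems are considered (no bulges or internal loops),
with a minimum stem of 3 bp and, for hairpins, a minimum loop of 3 nt.
Thermodynamics come from the unified nearest-neighbor parameter set as
shipped with Biopython, evaluated at 50 mM monovalent salt and 0.25 uM
strand concentration.  Absolute Tm accuracy is not the point -- threshold
behaviour on strong versus absent stems is, and that is what the tests
assert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

from Bio.SeqUtils import MeltingTemp as mt

MIN_STEM = 3
MIN_LOOP = 3
_MIN_SELF_LENGTH = 8  # stem 3 + loop 3 + at least 2 more stem bases
_SALT_NA = 50.0  # mM monovalent
_DNAC1 = 250.0  # nM; 0.25 uM strand concentration
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _comp(s: str) -> str:
    return s.translate(_COMPLEMENT)


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DuplexEstimate:
    """Nearest-neighbor estimate for the strongest duplex found.

    ``tm`` is -inf when no stem of at least :data:`MIN_STEM` base pairs
    exists (the "no structure" sentinel); ``structure_kind`` is then
    ``"none"``.
    """

    delta_g: float  # kcal/mol at 37 degC
    tm: float  # degC
    stem_length: int
    structure_kind: str  # "hairpin" | "self-dimer" | "cross-dimer" | "none"

    @property
    def has_structure(self) -> bool:
        return self.tm != -math.inf


NO_STRUCTURE = DuplexEstimate(0.0, -math.inf, 0, "none")


@lru_cache(maxsize=131072)
def _stem_thermo(stem: str) -> tuple[float, float]:
    """(Tm degC, deltaG37 kcal/mol) of a perfectly complementary stem."""
    tm = mt.Tm_NN(stem, nn_table=mt.DNA_NN3, Na=_SALT_NA,
                  dnac1=_DNAC1, dnac2=0)
    tbl = mt.DNA_NN3
    dh, ds = tbl["init"][0], tbl["init"][1]
    for terminal in (stem[0], stem[-1]):
        key = "init_A/T" if terminal in "AT" else "init_G/C"
        dh += tbl[key][0]
        ds += tbl[key][1]
    for i in range(len(stem) - 1):
        step = stem[i:i + 2]
        key = step + "/" + _comp(step)
        if key not in tbl:
            step = _revcomp(step)
            key = step + "/" + _comp(step)
        dh += tbl[key][0]
        ds += tbl[key][1]
    dg37 = dh - 310.15 * ds / 1000.0
    return tm, dg37


def _estimate(stem: str, kind: str) -> DuplexEstimate:
    tm, dg = _stem_thermo(stem)
    return DuplexEstimate(delta_g=dg, tm=tm, stem_length=len(stem),
                          structure_kind=kind)


def _ungapped_runs(a: str, b: str) -> Iterator[str]:
    """Maximal perfectly complementary runs (>= MIN_STEM) between ``a`` and
    ``b`` over every ungapped antiparallel register, reported as substrings
    of ``a``."""
    c = _revcomp(b)
    la, lc = len(a), len(c)
    for shift in range(-(lc - 1), la):
        i = max(0, shift)
        j = i - shift
        run = 0
        while i < la and j < lc:
            if a[i] == c[j]:
                run += 1
            else:
                if run >= MIN_STEM:
                    yield a[i - run:i]
                run = 0
            i += 1
            j += 1
        if run >= MIN_STEM:
            yield a[i - run:i]


def _hairpin_stems(s: str) -> Iterator[str]:
    """All complementary stem arms (>= MIN_STEM bp) closable by a loop of at
    least MIN_LOOP nt."""
    n = len(s)
    for a in range(n):
        for m in range(MIN_STEM, n - a + 1):
            arm = s[a:a + m]
            rc = _revcomp(arm)
            for b in range(a + m + MIN_LOOP, n - m + 1):
                if s[b:b + m] == rc:
                    yield arm


def _best(cands: Iterator[DuplexEstimate]) -> DuplexEstimate:
    best = NO_STRUCTURE
    for est in cands:
        if (est.tm, est.stem_length) > (best.tm, best.stem_length):
            best = est
    return best


def best_self_structure(s: str) -> DuplexEstimate:
    """Strongest intramolecular hairpin or self-dimer of ``s``.

    Sequences shorter than 8 nt cannot close a scored hairpin and are
    returned as structure-free.
    """
    if len(s) < _MIN_SELF_LENGTH:
        return NO_STRUCTURE
    hairpins = (_estimate(arm, "hairpin") for arm in set(_hairpin_stems(s)))
    dimers = (_estimate(run, "self-dimer")
              for run in set(_ungapped_runs(s, s)))
    best = _best(hairpins)
    best_dimer = _best(dimers)
    if (best_dimer.tm, best_dimer.stem_length) > (best.tm, best.stem_length):
        best = best_dimer
    return best


def cross_hyb_tm(s: str, primer: str) -> DuplexEstimate:
    """Strongest ungapped duplex between ``s`` and ``primer``.

    Symmetric in its arguments: the complementary runs of (s, primer) are the
    reverse complements of those of (primer, s) and score identically under
    the nearest-neighbor sums.
    """
    if not s or not primer:
        raise ValueError("sequences must be non-empty")
    return _best(_estimate(run, "cross-dimer")
                 for run in set(_ungapped_runs(s, primer)))
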