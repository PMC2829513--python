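"""Perfect microsatellite (SSR) detection in nucleotide sequences.

Finds every maximal perfect run of a primitive 2-6 bp unit whose whole-copy
repeat count meets a per-unit-length threshold, and assigns each locus to
its canonical motif class (the representative of the unit's equivalence
class under cyclic rotation and reverse complement, e.g. CTT -> AAG so the
AAG/CTT family is counted once regardless of strand or phase).

Thresholds default to the common EST-survey settings: at least 6 copies for
dinucleotides and 5/4/4/4 for tri- through hexanucleotides; mononucleotide
runs are never reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ssrmine._util import revcomp
from ssrmine.sequence_io import SeqRecord

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRThresholds",
    "SSRLocus",
    "is_primitive",
    "canonical_class",
    "enumerate_classes",
    "find_ssrs",
    "find_ssrs_in_records",
    "write_loci_tsv",
    "read_loci_tsv",
]

DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum whole-unit repeat count per unit length (2..6 bp)."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {2, 3, 4, 5, 6}:
            raise ValueError(
                "thresholds must cover unit lengths 2..6 exactly "
                f"(mononucleotides are excluded); got {sorted(self.min_repeats)}"
            )
        for k, m in self.min_repeats.items():
            if int(m) < 2:
                raise ValueError(f"minimum repeat count for k={k} must be >= 2")

    def __getitem__(self, k: int) -> int:
        return int(self.min_repeats[k])


@dataclass(frozen=True)
class SSRLocus:
    """One detected perfect repeat.

    Coordinates are 1-based inclusive; ``unit`` is the primitive motif in
    the phase it occurs at ``start``; ``canonical_class`` is the
    rotation/reverse-complement representative used for aggregation.
    """

    seq_id: str
    start: int
    end: int
    unit: str
    repeat_count: int
    canonical_class: str

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length != len(self.unit) * self.repeat_count:
            raise ValueError(
                f"locus span {self.length} != {len(self.unit)} x {self.repeat_count}"
            )


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number power of a shorter string
    (ATAT is a power of AT, hence not primitive)."""
    n = len(unit)
    if not 1 <= n <= 6:
        raise ValueError(f"unit length must be 1..6, got {n}")
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


@lru_cache(maxsize=None)
def canonical_class(unit: str) -> str:
    """Representative of the motif class: the lexicographically smallest
    string among all cyclic rotations of ``unit`` and of its reverse
    complement.  Strand- and phase-invariant by construction."""
    if set(unit) - _ACGT:
        raise ValueError(f"unit {unit!r} contains non-ACGT characters")
    if not is_primitive(unit):
        raise ValueError(f"unit {unit!r} is not primitive")
    rc = revcomp(unit)
    candidates = [
        s[i:] + s[:i] for s in (unit, rc) for i in range(len(unit))
    ]
    return min(candidates)


@lru_cache(maxsize=None)
def _classes_for_k(k: int) -> tuple[str, ...]:
    if not 2 <= k <= 6:
        raise ValueError(f"unit length must be 2..6, got {k}")
    from itertools import product

    reps = {
        canonical_class("".join(p))
        for p in product("ACGT", repeat=k)
        if is_primitive("".join(p))
    }
    return tuple(sorted(reps))


def enumerate_classes(k: int) -> int:
    """Number of distinct canonical motif classes among primitive k-mers
    (4, 10, 33, 102 and 350 for k = 2..6)."""
    return len(_classes_for_k(k))


def motif_classes(k: int) -> tuple[str, ...]:
    """All canonical class representatives of unit length k, sorted."""
    return _classes_for_k(k)


def find_ssrs(
    record: SeqRecord,
    thresholds: SSRThresholds | None = None,
) -> list[SSRLocus]:
    """Report every perfect SSR in ``record`` meeting the thresholds.

    A locus is a maximal run of period k (not extendable by even one base
    on either side) whose leading k-mer is primitive and whose whole-copy
    count floor(L/k) meets the threshold; a trailing partial unit is
    excluded from the coordinates and the count.  Characters outside
    A/C/G/T terminate runs.  Loci are sorted by start, then unit length.
    """
    if thresholds is None:
        thresholds = SSRThresholds()
    seq = record.sequence
    n = len(seq)
    loci: list[SSRLocus] = []
    for k in range(2, 7):
        min_count = thresholds[k]
        i = 0
        while i + k * min_count <= n:
            unit = seq[i:i + k]
            if set(unit) - _ACGT:
                # runs cannot cross an ambiguity code; skip past it
                i += 1
                continue
            # left-maximality: a period-k run starting here must not be
            # extendable one base to the left
            if i > 0 and seq[i - 1] in _ACGT and seq[i - 1] == seq[i + k - 1]:
                i += 1
                continue
            j = i + k
            while j < n and seq[j] in _ACGT and seq[j] == seq[j - k]:
                j += 1
            run_len = j - i
            count = run_len // k
            if count >= min_count and is_primitive(unit):
                end = i + count * k
                loci.append(
                    SSRLocus(
                        seq_id=record.id,
                        start=i + 1,
                        end=end,
                        unit=unit,
                        repeat_count=count,
                        canonical_class=canonical_class(unit),
                    )
                )
            # next period-k run can start no earlier than j-k+1
            i = max(i + 1, j - k + 1)
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def find_ssrs_in_records(
    records: Sequence[SeqRecord],
    thresholds: SSRThresholds | None = None,
) -> list[SSRLocus]:
    """Concatenate per-record detection over a record list, in file order."""
    out: list[SSRLocus] = []
    for rec in records:
        out.extend(find_ssrs(rec, thresholds))
    return out


_TSV_HEADER = (
    "seq_id", "start", "end", "unit", "unit_length", "repeat_count",
    "canonical_class",
)


def write_loci_tsv(loci: Iterable[SSRLocus], path: str | Path) -> None:
    """One row per locus, 1-based inclusive coordinates."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_HEADER)
        for l in loci:
            w.writerow(
                (l.seq_id, l.start, l.end, l.unit, l.unit_length,
                 l.repeat_count, l.canonical_class)
            )


def read_loci_tsv(path: str | Path) -> list[SSRLocus]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != _TSV_HEADER:
            raise ValueError(f"{path}: unexpected locus TSV header {header}")
        loci = []
        for row in reader:
            if not row:
                continue
            seq_id, start, end, unit, _klen, count, cls = row
            loci.append(
                SSRLocus(
                    seq_id=seq_id, start=int(start), end=int(end), unit=unit,
                    repeat_count=int(count), canonical_class=cls,
                )
            )
    return loci
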