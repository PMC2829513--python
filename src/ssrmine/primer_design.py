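"""Flanking-primer design for SSR loci.

Enumerates every candidate forward/reverse primer pair in the flanks of a
locus that satisfies hard constraints — primer length 18-28 nt, GC content
40-70%, no homopolymer run over 4 bases, product size 100-300 bp, the
product containing the whole repeat and neither primer overlapping it —
and ranks survivors by a transparent L1 penalty against the optima
(20 nt, 60 deg C, 50% GC):

    penalty = sum over both primers of
              |length - length_opt| + |Tm - tm_opt| + 0.5*|GC - gc_opt|

Tm is the Wallace rule 2(A+T) + 4(G+C), which is exactly 60 deg C at the
20-nt/50%-GC optimum; nearest-neighbor thermodynamics, dimer and hairpin
screening are deliberately out of scope.
"""

from __future__ import annotations

import csv
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from ssrmine._util import revcomp
from ssrmine.sequence_io import SeqRecord
from ssrmine.ssr_detection import SSRLocus

__all__ = [
    "PrimerParams",
    "PrimerPair",
    "DesignResult",
    "gc_content",
    "melting_temp",
    "max_homopolymer",
    "design_primers",
    "write_primer_tsv",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class PrimerParams:
    """Design constraints and optima; defaults are the conventional
    EST-SSR settings (18-28 nt primers with 20 optimal, 100-300 bp
    product, 60 deg C annealing optimum, 40-70% GC with 50% optimal)."""

    length_min: int = 18
    length_opt: int = 20
    length_max: int = 28
    product_min: int = 100
    product_max: int = 300
    tm_opt: float = 60.0
    gc_min: float = 40.0
    gc_opt: float = 50.0
    gc_max: float = 70.0
    max_homopolymer_run: int = 4
    template_cap: int = 5000

    def __post_init__(self) -> None:
        if not self.length_min <= self.length_opt <= self.length_max:
            raise ValueError("need length_min <= length_opt <= length_max")
        if not self.gc_min <= self.gc_opt <= self.gc_max:
            raise ValueError("need gc_min <= gc_opt <= gc_max")
        if not self.product_min < self.product_max:
            raise ValueError("need product_min < product_max")


@dataclass(frozen=True)
class PrimerPair:
    """One candidate pair.  ``fwd_start`` is the 1-based template position
    of the forward primer's 5' end; ``rev_start`` the 1-based template
    position of the reverse primer's 3' end (its leftmost annealed base).
    ``rev_seq`` is given 5'->3' in reverse-complement orientation."""

    fwd_seq: str
    fwd_start: int
    rev_seq: str
    rev_start: int
    product_size: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    penalty: float


@dataclass(frozen=True)
class DesignResult:
    """Ranked pairs, or an empty list with a machine-readable reason."""

    pairs: tuple[PrimerPair, ...]
    failure_reason: str | None = None

    def __bool__(self) -> bool:
        return bool(self.pairs)


def gc_content(seq: str) -> float:
    """G+C percentage of an ACGT string."""
    if not seq:
        raise ValueError("empty primer sequence")
    if set(seq) - _ACGT:
        raise ValueError(f"ambiguity codes not allowed in primers: {seq!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str) -> float:
    """Wallace-rule melting temperature, 2(A+T) + 4(G+C) deg C.

    Valid only for primer-scale oligos; lengths below 14 are rejected.
    """
    if len(seq) < 14:
        raise ValueError(f"Wallace rule not applied below 14 nt (got {len(seq)})")
    if set(seq) - _ACGT:
        raise ValueError(f"ambiguity codes not allowed in primers: {seq!r}")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * (len(seq) - gc) + 4.0 * gc


def max_homopolymer(seq: str) -> int:
    """Length of the longest run of one base."""
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _primer_ok(seq: str, params: PrimerParams) -> bool:
    if set(seq) - _ACGT:
        return False
    if not params.gc_min <= gc_content(seq) <= params.gc_max:
        return False
    if max_homopolymer(seq) > params.max_homopolymer_run:
        return False
    return True


def _primer_penalty(seq: str, params: PrimerParams) -> float:
    return (
        abs(len(seq) - params.length_opt)
        + abs(melting_temp(seq) - params.tm_opt)
        + 0.5 * abs(gc_content(seq) - params.gc_opt)
    )


def design_primers(
    record: SeqRecord,
    locus: SSRLocus,
    params: PrimerParams | None = None,
    max_pairs: int = 5,
) -> DesignResult:
    """Enumerate and rank primer pairs flanking ``locus`` on ``record``.

    The search considers every forward primer ending left of the repeat
    and every reverse primer starting right of it whose product (forward
    5' end through reverse 3'... rightmost base) lies in the size window
    and contains the repeat.  Pairs are sorted by ascending penalty with
    ties broken by smaller product, then leftmost forward start, then
    leftmost reverse start.  On failure the result carries a reason:
    ``product_window_empty``, ``flank_too_short``, ``no_valid_forward``,
    ``no_valid_reverse`` or ``no_valid_pair``.
    """
    if params is None:
        params = PrimerParams()
    if locus.seq_id != record.id:
        raise ValueError(f"locus {locus.seq_id!r} does not belong to record {record.id!r}")
    seq = record.sequence
    n = len(seq)
    if n > params.template_cap:
        raise ValueError(
            f"template {record.id!r} is {n} bp, above the search cap "
            f"{params.template_cap}; trim the template around the locus"
        )
    if not (1 <= locus.start <= locus.end <= n):
        raise ValueError("locus coordinates fall outside the record")
    if n < params.product_min:
        return DesignResult((), "product_window_empty")
    if locus.start - 1 < params.length_min or n - locus.end < params.length_min:
        return DesignResult((), "flank_too_short")

    # 0-based template windows the product can reach while containing
    # the repeat and staying inside the size bounds
    lo0 = max(0, locus.end - params.product_max)          # min fwd 5' index
    fwd_starts = range(lo0, locus.start - params.length_min)
    forwards = []
    for s in fwd_starts:
        for L in range(params.length_min, params.length_max + 1):
            e = s + L  # exclusive
            if e > locus.start - 1:  # would overlap the repeat
                break
            cand = seq[s:e]
            if _primer_ok(cand, params):
                forwards.append((s, e, cand, _primer_penalty(cand, params)))
    if not forwards:
        return DesignResult((), "no_valid_forward")

    hi0 = min(n, locus.start - 1 + params.product_max)    # max rev 3' bound
    reverses = []
    for e in range(locus.end + params.length_min, hi0 + 1):  # exclusive end
        for L in range(params.length_min, params.length_max + 1):
            s = e - L
            if s < locus.end:  # would overlap the repeat
                break
            cand = revcomp(seq[s:e])
            if _primer_ok(cand, params):
                reverses.append((s, e, cand, _primer_penalty(cand, params)))
    if not reverses:
        return DesignResult((), "no_valid_reverse")

    # pair forwards with reverses whose product end falls in the size
    # window; keep only the max_pairs best under the tie-broken ordering
    reverses.sort(key=lambda r: r[1])
    rev_ends = [r[1] for r in reverses]
    best: list[tuple] = []  # sort keys + payload, bounded to max_pairs
    worst_pen = float("inf")  # penalty of current max_pairs-th best
    for fs, fe, fseq, fpen in forwards:
        lo = bisect_left(rev_ends, fs + params.product_min)
        hi = bisect_right(rev_ends, fs + params.product_max)
        for rs, re_, rseq, rpen in reverses[lo:hi]:
            # repeat containment is implied: fs+1 < locus.start and
            # re_ > locus.end by candidate construction
            pen = fpen + rpen
            if pen > worst_pen:
                continue
            key = (pen, re_ - fs, fs, rs)
            if len(best) < max_pairs:
                best.append((key, fseq, fs, rseq, rs, re_, fpen, rpen))
                best.sort(key=lambda t: t[0])
            elif key < best[-1][0]:
                best[-1] = (key, fseq, fs, rseq, rs, re_, fpen, rpen)
                best.sort(key=lambda t: t[0])
            if len(best) == max_pairs:
                worst_pen = best[-1][0][0]
    if not best:
        return DesignResult((), "no_valid_pair")
    pairs = tuple(
        PrimerPair(
            fwd_seq=fseq,
            fwd_start=fs + 1,
            rev_seq=rseq,
            rev_start=rs + 1,
            product_size=re_ - fs,
            tm_f=melting_temp(fseq),
            tm_r=melting_temp(rseq),
            gc_f=round(gc_content(fseq), 2),
            gc_r=round(gc_content(rseq), 2),
            penalty=round(fpen + rpen, 6),
        )
        for (_key, fseq, fs, rseq, rs, re_, fpen, rpen) in best
    )
    return DesignResult(pairs)


def write_primer_tsv(
    rows: Iterable[tuple[str, str, DesignResult]], path: str | Path
) -> None:
    """Write ranked pairs, one row per pair; loci with no feasible pair
    get a single row carrying the failure reason.

    ``rows`` yields (seq_id, locus_id, DesignResult) triples.
    """
    header = (
        "seq_id", "locus_id", "rank", "fwd_seq", "fwd_start", "rev_seq",
        "rev_start", "product_size", "tm_f", "tm_r", "gc_f", "gc_r",
        "penalty", "status",
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for seq_id, locus_id, result in rows:
            if not result.pairs:
                w.writerow(
                    (seq_id, locus_id, "", "", "", "", "", "", "", "", "",
                     "", "", f"failed:{result.failure_reason}")
                )
                continue
            for rank, p in enumerate(result.pairs, start=1):
                w.writerow(
                    (seq_id, locus_id, rank, p.fwd_seq, p.fwd_start,
                     p.rev_seq, p.rev_start, p.product_size, p.tm_f, p.tm_r,
                     p.gc_f, p.gc_r, p.penalty, "ok")
                )
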