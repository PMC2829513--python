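"""FASTA input/output and assembly-style summaries.

Reads EST/consensus nucleotide sequences, normalizes them (uppercase,
U→T), and produces the two bookkeeping summaries used when describing an
EST assembly: a length distribution over fixed bins and a histogram of
reads-per-consensus membership counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ssrmine._util import round_half_up

__all__ = [
    "SeqRecord",
    "LengthBinning",
    "MembershipHistogram",
    "MEMBERSHIP_BINS",
    "read_fasta",
    "write_fasta",
    "length_distribution",
    "membership_histogram",
    "read_membership_tsv",
]

_VALID_BASES = frozenset("ACGTNRYSWKMBDHVU")


@dataclass(frozen=True)
class SeqRecord:
    """One nucleotide sequence: id (first header token), free-text
    description, and an uppercase sequence over the IUPAC alphabet."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LengthBinning:
    """Counts of sequence lengths over bins (edge_{k-1}, edge_k], with the
    first bin starting at 1 bp and an open-ended last bin."""

    bin_edges: tuple[int, ...]
    counts: tuple[int, ...]
    total_count: int
    total_length_bp: int
    mean_length_bp: float | None

    @property
    def labels(self) -> tuple[str, ...]:
        labels = []
        lo = 1
        for edge in self.bin_edges:
            labels.append(f"{lo}-{edge} bp")
            lo = edge + 1
        labels.append(f">{self.bin_edges[-1]} bp")
        return tuple(labels)


@dataclass(frozen=True)
class MembershipHistogram:
    """Reads-per-consensus histogram over the conventional bins
    (2..10 singly, then 5-wide bins, then an open top bin)."""

    bin_labels: tuple[str, ...]
    counts: tuple[int, ...]
    percentages: tuple[float, ...]
    total: int


# Exact counts 2..10, then 5-wide bins, then everything >= 51.
MEMBERSHIP_BINS: tuple[str, ...] = (
    *(str(i) for i in range(2, 11)),
    "11-15", "16-20", "21-25", "26-30", "31-35", "36-40", "41-45", "46-50",
    ">51",
)


def _normalize(seq: str, *, record_id: str, line_no: int | None = None) -> str:
    seq = "".join(seq.split()).upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        where = f" near line {line_no}" if line_no else ""
        raise ValueError(
            f"record {record_id!r}{where}: invalid characters {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a FASTA file into records, in file order.

    Sequences are uppercased with U mapped to T; ids must be unique.
    Raises ``ValueError`` on a malformed header, an empty sequence, or a
    duplicate id, naming the offending line or record.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        line_no = 0
        for line_no, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise ValueError(
                f"{path}: line {line_no}: expected FASTA header starting "
                f"with '>', got {first.strip()[:30]!r}"
            )
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty header id")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), record_id=rec.id)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(SeqRecord(id=rec.id, description=rec.description, sequence=seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id,
                      description=r.description[len(r.id):].strip()
                      if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def length_distribution(
    records: Sequence[SeqRecord],
    edges: Sequence[int] = (100, 200, 300, 400),
) -> LengthBinning:
    """Bin record lengths into (edge_{k-1}, edge_k] intervals.

    The default edges give the five conventional EST report bins
    1-100, 101-200, 201-300, 301-400 and >400 bp.  An empty record list
    yields all-zero bins with an absent mean.
    """
    edges = tuple(int(e) for e in edges)
    if list(edges) != sorted(set(edges)) or (edges and edges[0] < 1):
        raise ValueError(f"bin edges must be ascending positive integers, got {edges}")
    counts = [0] * (len(edges) + 1)
    total_len = 0
    for rec in records:
        n = len(rec)
        total_len += n
        for i, edge in enumerate(edges):
            if n <= edge:
                counts[i] += 1
                break
        else:
            counts[-1] += 1
    total = len(records)
    return LengthBinning(
        bin_edges=edges,
        counts=tuple(counts),
        total_count=total,
        total_length_bp=total_len,
        mean_length_bp=total_len / total if total else None,
    )


def _membership_bin(n_reads: int) -> str:
    if n_reads <= 10:
        return str(n_reads)
    if n_reads >= 51:
        return ">51"
    lo = 11 + 5 * ((n_reads - 11) // 5)
    return f"{lo}-{lo + 4}"


def membership_histogram(membership: Mapping[str, int]) -> MembershipHistogram:
    """Tally reads-per-consensus counts into the standard report bins.

    Only multi-read consensuses (contigs) belong here; a read count below
    2 is rejected.  Percentages are against the contig total, rounded
    half-up to 1 decimal.  The top bin collects all counts >= 51 (its
    conventional label ">51" notwithstanding).
    """
    tallies = {label: 0 for label in MEMBERSHIP_BINS}
    for cid, n in membership.items():
        n = int(n)
        if n < 2:
            raise ValueError(
                f"consensus {cid!r} has read count {n}; singlets (<2 reads) "
                "are excluded from the membership histogram"
            )
        tallies[_membership_bin(n)] += 1
    total = sum(tallies.values())
    pcts = tuple(
        round_half_up(100.0 * c / total, 1) if total else 0.0
        for c in tallies.values()
    )
    return MembershipHistogram(
        bin_labels=MEMBERSHIP_BINS,
        counts=tuple(tallies.values()),
        percentages=pcts,
        total=total,
    )


def read_membership_tsv(path: str | Path) -> dict[str, int]:
    """Read a 2-column ``consensus_id<TAB>n_reads`` table."""
    membership: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {line_no}: expected 2 columns")
            cid, n = parts
            if cid in membership:
                raise ValueError(f"{path}: line {line_no}: duplicate id {cid!r}")
            try:
                membership[cid] = int(n)
            except ValueError:
                raise ValueError(
                    f"{path}: line {line_no}: non-integer read count {n!r}"
                ) from None
    return membership
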