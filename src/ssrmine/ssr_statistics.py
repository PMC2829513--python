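"""Summary tables for detected SSRs.

Aggregates loci into the two tables an EST-SSR survey reports — counts and
percentages by unit length x repeat-number bin, and by canonical motif
class — plus overall frequency (loci per scanned sequence, and
SSR-containing sequences per scanned sequence) and density per Mb.

All percentages are rounded half-up to one decimal, the convention of
printed report tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ssrmine._util import percentage, round_half_up
from ssrmine.sequence_io import SeqRecord
from ssrmine.ssr_detection import SSRLocus

__all__ = [
    "REPEAT_NUMBER_BINS",
    "UNIT_LENGTH_NAMES",
    "SSRSummary",
    "repeat_number_bin",
    "summarize",
    "density_per_mb",
    "percentage",  # re-exported: the table-percentage convention lives here
]

REPEAT_NUMBER_BINS: tuple[str, ...] = ("4", "5", "6", "7", "8", "9", "10", ">10")

UNIT_LENGTH_NAMES: dict[int, str] = {
    2: "Di", 3: "Tri", 4: "Tetra", 5: "Penta", 6: "Hexa",
}


def repeat_number_bin(repeat_count: int) -> str:
    """Bin label for a whole-unit repeat count: exact 4..10, then '>10'."""
    if repeat_count < 4:
        raise ValueError(
            f"repeat count {repeat_count} is below any detection threshold"
        )
    return str(repeat_count) if repeat_count <= 10 else ">10"


def density_per_mb(n_loci: int, total_length_bp: float, ndigits: int = 1) -> float:
    """Loci per megabase of scanned sequence, rounded half-up.

    Accepts the total length in bp; 1 Mb = 1e6 bp.
    """
    if total_length_bp <= 0:
        raise ValueError("total scanned length must be positive")
    return round_half_up(n_loci / (total_length_bp / 1e6), ndigits)


@dataclass(frozen=True)
class SSRSummary:
    """The survey tables plus scan-level frequency/density figures.

    ``repeat_table``: unit length k -> {bin label -> count}.
    ``class_table``: canonical class -> (count, percentage of total loci).
    ``frequency_pct_loci`` divides loci by scanned sequences; the
    ``_sequences`` variant divides SSR-bearing sequences instead (surveys
    quote either basis, so both are reported with explicit names).
    """

    total_loci: int
    loci_by_unit_length: dict[int, int]
    unit_length_pct: dict[int, float]
    repeat_table: dict[int, dict[str, int]]
    repeat_bin_totals: dict[str, int]
    repeat_bin_pct: dict[str, float]
    class_table: dict[str, tuple[int, float]]
    n_sequences_scanned: int
    n_sequences_with_ssr: int
    n_sequences_with_2plus: int
    total_length_bp: int
    frequency_pct_loci: float
    frequency_pct_sequences: float
    density_per_mb: float

    # -- table renditions ------------------------------------------------

    def repeat_frame(self) -> pd.DataFrame:
        """Unit-length x repeat-number table with total and % columns.

        Cells below a unit length's detection minimum are '-' as surveys
        print them (e.g. dinucleotide columns 4 and 5 when the threshold
        is 6 copies).
        """
        rows = []
        for k in sorted(self.repeat_table):
            row: dict[str, object] = {"Motif length": UNIT_LENGTH_NAMES[k]}
            for b in REPEAT_NUMBER_BINS:
                count = self.repeat_table[k][b]
                low_bin = b != ">10" and int(b) < self._min_observed_bin(k)
                row[b] = "-" if (count == 0 and low_bin) else count
            row["total"] = self.loci_by_unit_length[k]
            row["%"] = self.unit_length_pct[k]
            rows.append(row)
        total_row: dict[str, object] = {"Motif length": "total"}
        pct_row: dict[str, object] = {"Motif length": "%"}
        for b in REPEAT_NUMBER_BINS:
            total_row[b] = self.repeat_bin_totals[b]
            pct_row[b] = self.repeat_bin_pct[b]
        total_row["total"] = self.total_loci
        total_row["%"] = ""
        pct_row["total"] = ""
        pct_row["%"] = ""
        rows.extend([total_row, pct_row])
        # object dtype keeps count cells integral next to the % row
        return pd.DataFrame(rows, dtype=object)

    def class_frame(self) -> pd.DataFrame:
        rows = [
            {"Repeat motif": cls, "count": count, "%": pct}
            for cls, (count, pct) in sorted(
                self.class_table.items(), key=lambda kv: (-kv[1][0], kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["Repeat motif", "count", "%"])

    def _min_observed_bin(self, k: int) -> int:
        # smallest populated exact bin for this unit length; used only to
        # render sub-threshold cells as '-'
        populated = [int(b) for b in REPEAT_NUMBER_BINS[:-1]
                     if self.repeat_table[k][b] > 0]
        return min(populated) if populated else 4

    def to_json(self) -> str:
        payload = {
            "total_loci": self.total_loci,
            "loci_by_unit_length": {str(k): v for k, v in self.loci_by_unit_length.items()},
            "unit_length_pct": {str(k): v for k, v in self.unit_length_pct.items()},
            "repeat_table": {str(k): v for k, v in self.repeat_table.items()},
            "repeat_bin_totals": self.repeat_bin_totals,
            "repeat_bin_pct": self.repeat_bin_pct,
            "class_table": {
                cls: {"count": c, "pct": p} for cls, (c, p) in self.class_table.items()
            },
            "n_sequences_scanned": self.n_sequences_scanned,
            "n_sequences_with_ssr": self.n_sequences_with_ssr,
            "n_sequences_with_2plus": self.n_sequences_with_2plus,
            "total_length_bp": self.total_length_bp,
            "frequency_pct_loci": self.frequency_pct_loci,
            "frequency_pct_sequences": self.frequency_pct_sequences,
            "density_per_mb": self.density_per_mb,
        }
        return json.dumps(payload, indent=2)

    def to_markdown(self) -> str:
        return (
            "## Repeat type by repeat number\n\n"
            + _frame_to_markdown(self.repeat_frame())
            + "\n## Repeat motif classes\n\n"
            + _frame_to_markdown(self.class_frame())
        )


def _frame_to_markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    body = [[str(v) for v in row] for row in df.itertuples(index=False)]
    widths = [max(len(c), *(len(r[i]) for r in body)) if body else len(c)
              for i, c in enumerate(cols)]
    def fmt(cells: list[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(cols), "|" + "|".join("-" * (w + 2) for w in widths) + "|"]
    lines += [fmt(r) for r in body]
    return "\n".join(lines) + "\n"


def summarize(loci: Sequence[SSRLocus], records: Sequence[SeqRecord]) -> SSRSummary:
    """Build the survey summary from detector output and the scanned set.

    Density uses the total length of ALL scanned records, SSR-bearing or
    not.  An empty record list is an error; an empty locus list gives
    zero tables with density 0.
    """
    if not records:
        raise ValueError("cannot summarize against an empty record set")
    record_ids = {r.id for r in records}
    unknown = {l.seq_id for l in loci} - record_ids
    if unknown:
        raise ValueError(f"loci reference sequences not in the record set: {sorted(unknown)[:5]}")

    total = len(loci)
    by_k: dict[int, int] = {k: 0 for k in range(2, 7)}
    repeat_table: dict[int, dict[str, int]] = {
        k: {b: 0 for b in REPEAT_NUMBER_BINS} for k in range(2, 7)
    }
    class_counts: dict[str, int] = {}
    per_seq: dict[str, int] = {}
    for l in loci:
        k = l.unit_length
        by_k[k] += 1
        repeat_table[k][repeat_number_bin(l.repeat_count)] += 1
        class_counts[l.canonical_class] = class_counts.get(l.canonical_class, 0) + 1
        per_seq[l.seq_id] = per_seq.get(l.seq_id, 0) + 1

    bin_totals = {
        b: sum(repeat_table[k][b] for k in repeat_table) for b in REPEAT_NUMBER_BINS
    }
    total_len = sum(len(r) for r in records)
    n_with = len(per_seq)
    n_two_plus = sum(1 for c in per_seq.values() if c >= 2)
    return SSRSummary(
        total_loci=total,
        loci_by_unit_length=by_k,
        unit_length_pct={
            k: (percentage(c, total) if total else 0.0) for k, c in by_k.items()
        },
        repeat_table=repeat_table,
        repeat_bin_totals=bin_totals,
        repeat_bin_pct={
            b: (percentage(c, total) if total else 0.0) for b, c in bin_totals.items()
        },
        class_table={
            cls: (c, percentage(c, total)) for cls, c in class_counts.items()
        },
        n_sequences_scanned=len(records),
        n_sequences_with_ssr=n_with,
        n_sequences_with_2plus=n_two_plus,
        total_length_bp=total_len,
        frequency_pct_loci=percentage(total, len(records), 2),
        frequency_pct_sequences=percentage(n_with, len(records), 2),
        density_per_mb=density_per_mb(total, total_len) if total else 0.0,
    )
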