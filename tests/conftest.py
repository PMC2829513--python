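"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import re

import numpy as np
import pytest

from ssrmine.sequence_io import SeqRecord
from ssrmine.ssr_detection import SSRThresholds


# ---------------------------------------------------------------------------
# independent brute-force SSR oracle (regex maximal-run scanner)


def oracle_is_primitive(unit: str) -> bool:
    """Divisor-period check, written independently of the package."""
    n = len(unit)
    for period in range(1, n):
        if n % period:
            continue
        if all(unit[i] == unit[i % period] for i in range(n)):
            return False
    return True


def oracle_find_ssrs(record: SeqRecord, thresholds: SSRThresholds | None = None):
    """Regex-based maximal perfect-repeat scan.

    For each unit length k the pattern ([ACGT]{k})\\1{m-1,} finds, leftmost
    and greedy, every maximal stretch of whole-unit copies; non-primitive
    units are discarded afterwards.  Returns (seq_id, start, end, unit,
    count) tuples, 1-based inclusive, sorted like the detector output.
    """
    if thresholds is None:
        thresholds = SSRThresholds()
    found = []
    for k in range(2, 7):
        m = thresholds[k]
        pattern = re.compile(r"([ACGT]{%d})\1{%d,}" % (k, m - 1))
        for match in pattern.finditer(record.sequence):
            unit = match.group(1)
            if not oracle_is_primitive(unit):
                continue
            count = len(match.group(0)) // k
            start = match.start() + 1
            found.append((record.id, start, start + count * k - 1, unit, count))
    found.sort(key=lambda t: (t[1], len(t[3])))
    return found


def loci_as_tuples(loci):
    return [(l.seq_id, l.start, l.end, l.unit, l.repeat_count) for l in loci]


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_records(rng):
    """1,000 random 300-bp ACGT sequences (fixed seed)."""
    bases = np.array(list("ACGT"))
    return [
        SeqRecord(
            id=f"r{i}",
            description=f"r{i}",
            sequence="".join(rng.choice(bases, size=300)),
        )
        for i in range(1000)
    ]


@pytest.fixture
def toy_genotypes():
    from ssrmine.marker_diversity import GenotypeTable

    calls = {
        "i1": {"L1": (100, 102), "L2": (200, 200)},
        "i2": {"L1": (100, 100), "L2": (200, 204)},
        "i3": {"L1": (102, 102), "L2": None},
    }
    return GenotypeTable(("i1", "i2", "i3"), ("L1", "L2"), calls)
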