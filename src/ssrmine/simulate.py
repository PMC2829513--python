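"""Seeded synthetic inputs with known ground truth.

Two generators make every other module testable without external data:

* EST-like sequence sets with planted perfect repeats and an exact truth
  table of loci.  Background sequence is drawn i.i.d. from a base
  composition and re-rolled until it contains no accidental
  above-threshold SSR, so the truth table is complete by construction.
* Diploid genotype tables drawn under Hardy-Weinberg equilibrium from
  per-locus allele-frequency vectors, with optional missing-data
  masking.

All randomness flows from a single integer seed through one NumPy
generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ssrmine.marker_diversity import GenotypeTable
from ssrmine.sequence_io import SeqRecord
from ssrmine.ssr_detection import (
    SSRLocus,
    SSRThresholds,
    canonical_class,
    find_ssrs,
    is_primitive,
)

__all__ = [
    "PlantedSSR",
    "PlantSpec",
    "GenoSimSpec",
    "generate_est_set",
    "generate_genotypes",
    "random_templates_with_ssr",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSSR:
    """One repeat to plant: primitive unit, whole-copy count, and the
    1-based start offset within its record."""

    unit: str
    repeat_count: int
    offset: int

    def __post_init__(self) -> None:
        if not is_primitive(self.unit) or not 2 <= len(self.unit) <= 6:
            raise ValueError(f"unit {self.unit!r} must be a primitive 2-6 mer")
        if self.repeat_count < 2:
            raise ValueError("repeat_count must be >= 2")
        if self.offset < 1:
            raise ValueError("offset is 1-based and must be >= 1")

    @property
    def length(self) -> int:
        return len(self.unit) * self.repeat_count

    @property
    def end(self) -> int:
        return self.offset + self.length - 1


@dataclass(frozen=True)
class PlantSpec:
    """Placement plan for one EST set: one list of plants per record."""

    placements: tuple[tuple[PlantedSSR, ...], ...]
    record_length: int = 300
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    id_prefix: str = "synth"

    def __post_init__(self) -> None:
        if self.record_length < 1:
            raise ValueError("record_length must be positive")
        comp = np.asarray(self.base_composition, float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0) or (comp < 0).any():
            raise ValueError("base_composition must be 4 non-negative fractions summing to 1")
        for plants in self.placements:
            ordered = sorted(plants, key=lambda p: p.offset)
            for p in ordered:
                if p.end > self.record_length:
                    raise ValueError(f"plant {p} exceeds record length {self.record_length}")
            for a, b in zip(ordered, ordered[1:]):
                if b.offset <= a.end + 1:
                    raise ValueError(
                        f"plants {a} and {b} need >= 1 separating background base"
                    )


def _background_ok(record: SeqRecord, truth: list[SSRLocus],
                   thresholds: SSRThresholds) -> bool:
    return find_ssrs(record, thresholds) == sorted(
        truth, key=lambda l: (l.start, l.unit_length)
    )


def generate_est_set(
    spec: PlantSpec,
    thresholds: SSRThresholds | None = None,
    max_rejections: int = 1000,
) -> tuple[list[SeqRecord], list[SSRLocus]]:
    """Build the records of ``spec`` and the exact truth table.

    The truth table holds every planted repeat meeting ``thresholds``
    (below-threshold plants are placed but not listed).  Each record's
    background is re-rolled until the detector reports exactly the truth
    rows, so recovery tests are exact rather than probabilistic.
    """
    if thresholds is None:
        thresholds = SSRThresholds()
    rng = np.random.default_rng(spec.seed)
    records: list[SeqRecord] = []
    truth: list[SSRLocus] = []
    for idx, plants in enumerate(spec.placements):
        rec_id = f"{spec.id_prefix}_{idx + 1}"
        expected = [
            SSRLocus(
                seq_id=rec_id,
                start=p.offset,
                end=p.end,
                unit=p.unit,
                repeat_count=p.repeat_count,
                canonical_class=canonical_class(p.unit),
            )
            for p in sorted(plants, key=lambda p: p.offset)
            if p.repeat_count >= thresholds[len(p.unit)]
        ]
        for attempt in range(max_rejections):
            bases = rng.choice(_BASES, size=spec.record_length,
                               p=spec.base_composition)
            for p in plants:
                run = (p.unit * p.repeat_count)
                bases[p.offset - 1:p.end] = list(run)
            rec = SeqRecord(id=rec_id, description=rec_id,
                            sequence="".join(bases))
            if _background_ok(rec, expected, thresholds):
                break
        else:
            raise RuntimeError(
                f"could not generate SSR-free background for record {rec_id} "
                f"after {max_rejections} attempts"
            )
        records.append(rec)
        truth.extend(expected)
    return records, truth


def random_templates_with_ssr(
    n_templates: int,
    seed: int,
    length: int = 400,
    unit_pool: Sequence[str] = ("AC", "AG", "AT", "AAG", "ACC", "AAC", "AAAG"),
    repeat_range: tuple[int, int] = (6, 10),
) -> tuple[list[SeqRecord], list[SSRLocus]]:
    """Convenience wrapper: n templates, one random centered plant each.

    Useful for primer-design exercises where the repeat must sit far
    enough from both ends for 100-300 bp products.
    """
    rng = np.random.default_rng(seed)
    placements = []
    for _ in range(n_templates):
        unit = str(rng.choice(list(unit_pool)))
        lo, hi = repeat_range
        count = int(rng.integers(lo, hi + 1))
        span = len(unit) * count
        center = length // 2
        offset = center - span // 2
        placements.append((PlantedSSR(unit=unit, repeat_count=count,
                                      offset=offset),))
    spec = PlantSpec(
        placements=tuple(placements),
        record_length=length,
        seed=int(rng.integers(0, 2**31 - 1)),
        id_prefix="tmpl",
    )
    return generate_est_set(spec)


@dataclass(frozen=True)
class GenoSimSpec:
    """Hardy-Weinberg genotype simulation plan.

    ``locus_alleles`` maps locus label -> {allele size (bp): frequency};
    frequencies must sum to 1 within each locus.
    """

    n_individuals: int
    locus_alleles: Mapping[str, Mapping[int, float]]
    missing_rate: float = 0.0
    seed: int = 0
    individual_prefix: str = "ind"

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if not self.locus_alleles:
            raise ValueError("need at least 1 locus")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        for loc, freqs in self.locus_alleles.items():
            if not freqs:
                raise ValueError(f"locus {loc!r}: empty allele set")
            sizes = list(freqs)
            if len(set(sizes)) != len(sizes) or any(s <= 0 for s in sizes):
                raise ValueError(f"locus {loc!r}: allele sizes must be distinct positive")
            total = sum(freqs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"locus {loc!r}: frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"locus {loc!r}: negative frequency")


def generate_genotypes(spec: GenoSimSpec) -> GenotypeTable:
    """Draw a diploid table: two independent gene copies per individual
    and locus from the locus's frequency vector (HWE), then mask calls
    to missing at ``missing_rate``."""
    rng = np.random.default_rng(spec.seed)
    individuals = tuple(
        f"{spec.individual_prefix}{i + 1:03d}" for i in range(spec.n_individuals)
    )
    loci = tuple(spec.locus_alleles)
    calls: dict[str, dict[str, tuple[int, int] | None]] = {
        ind: {} for ind in individuals
    }
    for loc in loci:
        freqs = spec.locus_alleles[loc]
        sizes = np.array(list(freqs), dtype=int)
        p = np.array([freqs[int(s)] for s in sizes], dtype=float)
        draws = rng.choice(sizes, size=(spec.n_individuals, 2), p=p)
        missing = rng.random(spec.n_individuals) < spec.missing_rate
        for i, ind in enumerate(individuals):
            if missing[i]:
                calls[ind][loc] = None
            else:
                a, b = int(draws[i, 0]), int(draws[i, 1])
                calls[ind][loc] = (min(a, b), max(a, b))
    return GenotypeTable(individuals, loci, calls)
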