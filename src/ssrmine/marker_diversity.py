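"""Diversity statistics and distance trees from diploid SSR genotypes.

Works on individuals x loci tables of allele fragment sizes (bp).  Per
locus it computes the allele count Na, observed heterozygosity Ho,
unbiased expected heterozygosity

    He = n/(n-1) * (1 - sum_i p_i^2),    n = typed gene copies,

and the polymorphism information content

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2 .

Between individuals it computes the log-transformed proportion of shared
alleles, Dps = -ln(ps), with ps averaged over loci typed in both
individuals, and builds neighbor-joining dendrograms (Saitou-Nei
agglomeration with the Studier-Keppler Q-criterion) with optional
bootstrap supports from resampling loci with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypeTable",
    "LocusStats",
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "locus_stats",
    "dps_distance",
    "dps_matrix",
    "neighbor_joining",
    "bootstrap_nj",
    "write_newick",
    "write_phylip",
    "read_genotype_tsv",
    "write_genotype_tsv",
]

Call = tuple[int, int] | None  # unordered diploid allele sizes, or missing


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid allele-size calls for individuals x loci.

    ``calls[individual][locus]`` is an unordered (a1, a2) pair of
    fragment sizes in bp, or None for missing.  Sizes are stored sorted
    so (102, 100) and (100, 102) are one genotype.
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    calls: Mapping[str, Mapping[str, Call]]

    def __post_init__(self) -> None:
        if len(self.individuals) < 2:
            raise ValueError("need at least 2 individuals")
        if not self.loci:
            raise ValueError("need at least 1 locus")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual labels")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus labels")
        for ind in self.individuals:
            for loc in self.loci:
                call = self.calls[ind][loc]
                if call is None:
                    continue
                a, b = call
                if a <= 0 or b <= 0:
                    raise ValueError(
                        f"{ind}/{loc}: allele sizes must be positive, got {call}"
                    )

    def call(self, individual: str, locus: str) -> Call:
        return self.calls[individual][locus]

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        """Restrict (or resample, duplicates allowed via renaming) loci."""
        new_names = []
        counts: dict[str, int] = {}
        mapping = []
        for loc in loci:
            counts[loc] = counts.get(loc, 0) + 1
            name = loc if counts[loc] == 1 else f"{loc}.{counts[loc]}"
            new_names.append(name)
            mapping.append(loc)
        calls = {
            ind: {
                name: self.calls[ind][orig]
                for name, orig in zip(new_names, mapping)
            }
            for ind in self.individuals
        }
        return GenotypeTable(self.individuals, tuple(new_names), calls)


@dataclass(frozen=True)
class LocusStats:
    locus: str
    n_typed: int
    na: int
    ho: float
    he: float
    pic: float


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


# ---------------------------------------------------------------------------
# per-locus statistics


def _typed_calls(table: GenotypeTable, locus: str) -> list[tuple[int, int]]:
    if locus not in table.loci:
        raise KeyError(f"unknown locus {locus!r}")
    calls = [table.calls[ind][locus] for ind in table.individuals]
    typed = [c for c in calls if c is not None]
    if not typed:
        raise ValueError(f"locus {locus!r} has no typed individuals")
    return typed


def allele_frequencies(table: GenotypeTable, locus: str) -> dict[int, float]:
    """Allele relative frequencies over the 2 x n_typed gene copies."""
    typed = _typed_calls(table, locus)
    counts: dict[int, int] = {}
    for a, b in typed:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    n = 2 * len(typed)
    return {allele: c / n for allele, c in sorted(counts.items())}


def observed_heterozygosity(table: GenotypeTable, locus: str) -> float:
    """Fraction of typed individuals carrying two distinct alleles."""
    typed = _typed_calls(table, locus)
    return sum(1 for a, b in typed if a != b) / len(typed)


def expected_heterozygosity(table: GenotypeTable, locus: str) -> float:
    """Unbiased gene diversity n/(n-1)(1 - sum p^2), n = typed gene copies."""
    typed = _typed_calls(table, locus)
    n = 2 * len(typed)
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    freqs = allele_frequencies(table, locus)
    sum_p2 = sum(p * p for p in freqs.values())
    return n / (n - 1) * (1.0 - sum_p2)


def pic(table: GenotypeTable, locus: str) -> float:
    """Botstein-type polymorphism information content."""
    freqs = list(allele_frequencies(table, locus).values())
    sum_p2 = sum(p * p for p in freqs)
    cross = 0.0
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            cross += 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return 1.0 - sum_p2 - cross


def locus_stats(table: GenotypeTable, locus: str) -> LocusStats:
    typed = _typed_calls(table, locus)
    return LocusStats(
        locus=locus,
        n_typed=len(typed),
        na=len(allele_frequencies(table, locus)),
        ho=observed_heterozygosity(table, locus),
        he=expected_heterozygosity(table, locus),
        pic=pic(table, locus),
    )


# ---------------------------------------------------------------------------
# shared-allele distance


def _shared_copies(call_a: tuple[int, int], call_b: tuple[int, int]) -> int:
    copies_a: dict[int, int] = {}
    copies_b: dict[int, int] = {}
    for x in call_a:
        copies_a[x] = copies_a.get(x, 0) + 1
    for x in call_b:
        copies_b[x] = copies_b.get(x, 0) + 1
    return sum(min(c, copies_b.get(al, 0)) for al, c in copies_a.items())


def dps_distance(table: GenotypeTable, ind_a: str, ind_b: str) -> float:
    """-ln of the proportion of shared alleles between two individuals.

    ps sums, over loci typed in both individuals, the per-locus count of
    shared allele copies (min of the copy numbers of each allele, 0..2)
    and divides by 2 x the number of shared-typed loci.  When nothing is
    shared, ps is floored at half a copy over the comparable loci so the
    distance stays finite.
    """
    if ind_a == ind_b:
        return 0.0
    shared = 0
    n_loci = 0
    for loc in table.loci:
        ca = table.calls[ind_a][loc]
        cb = table.calls[ind_b][loc]
        if ca is None or cb is None:
            continue
        n_loci += 1
        shared += _shared_copies(ca, cb)
    if n_loci == 0:
        raise ValueError(f"{ind_a!r} and {ind_b!r} share no typed locus")
    ps = shared / (2.0 * n_loci)
    if ps == 0.0:
        ps = 0.5 / (2.0 * n_loci)  # half-count pseudo-share floor
    return -math.log(ps)


def dps_matrix(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise Dps over all individuals."""
    labels = table.individuals
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dps_distance(table, labels[i], labels[j])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, values=m)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the edge to the parent,
    ``raw_length`` keeps the pre-clamp NJ estimate when they differ."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None
    raw_length: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored rooted at the final NJ join (the root carries
    no edge and, for >= 3 taxa, three children)."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge splits, each canonicalized as the side not
        containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and len(below) >= 2 and len(all_leaves - below) >= 2:
                side = all_leaves - below if anchor in below else below
                splits.add(side)
            return below

        walk(self.root)
        return splits

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf distances along tree edges."""
        labels = tuple(self.leaf_names())
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        m = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf():
                depths = {index[node.name]: 0.0}
            else:
                depths = {}
                child_sets = []
                for c in node.children:
                    d = {k: v + (c.length or 0.0) for k, v in walk(c).items()}
                    child_sets.append(d)
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        for i, di in child_sets[a].items():
                            for j, dj in child_sets[b].items():
                                m[i, j] = m[j, i] = di + dj
                for d in child_sets:
                    depths.update(d)
            return depths

        walk(self.root)
        return DistanceMatrix(labels=labels, values=m)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Deterministic: among ties for the minimal Q the pair whose canonical
    labels (the alphabetically first leaf below each node) sort smallest
    is joined.  Negative branch-length estimates are clamped to zero
    with the deficit moved to the sibling edge; the raw estimate is kept
    on the node.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        d = float(dm.values[0, 1])
        a = TreeNode(name=dm.labels[0], length=d / 2, raw_length=d / 2)
        b = TreeNode(name=dm.labels[1], length=d / 2, raw_length=d / 2)
        return Tree(root=TreeNode(children=[a, b]))

    # active nodes keyed by canonical label = first leaf alphabetically
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(name=lab) for lab in dm.labels
    }
    dist: dict[frozenset[str], float] = {}
    labels = list(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((labels[i], labels[j]))] = float(dm.values[i, j])

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    active = sorted(nodes)
    while len(active) > 3:
        r = len(active)
        row_sums = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best_pair = None
        best_q = None
        for ia in range(r):
            for ib in range(ia + 1, r):
                a, b = active[ia], active[ib]
                q = (r - 2) * d(a, b) - row_sums[a] - row_sums[b]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best_pair = q, (a, b)
                # ties: active is sorted, so the first pair found already
                # has the lexicographically smallest (a, b)
        a, b = best_pair
        dab = d(a, b)
        la = dab / 2 + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lb = dab - la
        la_c, lb_c = la, lb
        if la < 0:
            la_c, lb_c = 0.0, lb + la
        if lb < 0:
            la_c, lb_c = la + lb, 0.0
        la_c, lb_c = max(la_c, 0.0), max(lb_c, 0.0)
        child_a = nodes.pop(a)
        child_b = nodes.pop(b)
        child_a.length, child_a.raw_length = la_c, la
        child_b.length, child_b.raw_length = lb_c, lb
        new_label = min(a, b)
        parent = TreeNode(children=[child_a, child_b])
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = 0.5 * (d(a, c) + d(b, c) - dab)
        active = sorted(nodes)

    # terminal trifurcation
    x, y, z = active
    lx = (d(x, y) + d(x, z) - d(y, z)) / 2
    ly = (d(x, y) + d(y, z) - d(x, z)) / 2
    lz = (d(x, z) + d(y, z) - d(x, y)) / 2
    root = TreeNode()
    for lab, raw in ((x, lx), (y, ly), (z, lz)):
        node = nodes.pop(lab)
        node.length, node.raw_length = max(raw, 0.0), raw
        root.children.append(node)
    return Tree(root=root)


def bootstrap_nj(
    table: GenotypeTable,
    n_replicates: int,
    seed: int,
    pool_by: Mapping[str, str] | None = None,
) -> Tree:
    """NJ tree on the full Dps matrix, with bootstrap supports.

    Each replicate resamples loci with replacement, rebuilds the Dps
    matrix and its NJ tree; the support of an internal edge of the
    full-data tree is the percentage of replicates whose tree contains
    the same bipartition.  ``n_replicates == 0`` returns the full-data
    tree without supports.
    """
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    if len(table.loci) < 2 and n_replicates > 0:
        raise ValueError("bootstrap needs at least 2 loci")
    if pool_by is not None:
        table = pool_individuals(table, pool_by)
    full = neighbor_joining(dps_matrix(table))
    if n_replicates == 0:
        return full
    target = {split: 0 for split in full.bipartitions()}
    rng = np.random.default_rng(seed)
    loci = list(table.loci)
    for _ in range(n_replicates):
        sample = [loci[i] for i in rng.integers(0, len(loci), size=len(loci))]
        rep_tree = neighbor_joining(dps_matrix(table.subset_loci(sample)))
        for split in rep_tree.bipartitions():
            if split in target:
                target[split] += 1

    all_leaves = frozenset(full.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: TreeNode, below_root: bool) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, False) for c in node.children))
        if not below_root and len(below) >= 2 and len(all_leaves - below) >= 2:
            side = all_leaves - below if anchor in below else below
            node.support = 100.0 * target[side] / n_replicates
        return below

    annotate(full.root, True)
    return full


def pool_individuals(
    table: GenotypeTable, groups: Mapping[str, str]
) -> GenotypeTable:
    """Pool individuals into labelled groups (e.g. species): each group
    keeps one representative row whose call at a locus is the first
    non-missing call among its members."""
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for ind in table.individuals:
        g = groups.get(ind, ind)
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(ind)
    calls = {}
    for g in order:
        row: dict[str, Call] = {}
        for loc in table.loci:
            row[loc] = next(
                (table.calls[m][loc] for m in members[g]
                 if table.calls[m][loc] is not None),
                None,
            )
        calls[g] = row
    return GenotypeTable(tuple(order), table.loci, calls)


# ---------------------------------------------------------------------------
# serialization


def write_newick(
    tree: Tree,
    min_support: float | None = None,
    decimals: int = 5,
) -> str:
    """Newick string with branch lengths and bootstrap supports as
    internal-node labels; supports below ``min_support`` are suppressed
    when a threshold is given."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            body = node.name
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None and (
                min_support is None or node.support >= min_support
            ):
                label = f"{node.support:.0f}"
            body = f"({inner}){label}"
        if node.length is not None:
            body += f":{node.length:.{decimals}f}"
        return body

    return fmt(tree.root) + ";"


def write_phylip(dm: DistanceMatrix) -> str:
    """Square PHYLIP distance-matrix format (names padded to 10)."""
    lines = [f"{len(dm.labels):5d}"]
    for i, lab in enumerate(dm.labels):
        name = (lab[:10]).ljust(10)
        row = " ".join(f"{v:.6f}" for v in dm.values[i])
        lines.append(f"{name}{row}")
    return "\n".join(lines) + "\n"


def write_stats_tsv(stats: Iterable[LocusStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tn\tNa\tHo\tHe\tPIC\n")
        for s in stats:
            fh.write(
                f"{s.locus}\t{s.n_typed}\t{s.na}\t{s.ho:.4f}\t{s.he:.4f}\t{s.pic:.4f}\n"
            )


MISSING = "?"


def read_genotype_tsv(path: str | Path) -> GenotypeTable:
    """Read the genotype layout: header ``individual<TAB>locus...``,
    cells ``a1/a2`` (bp, unordered) or ``?`` for missing."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty genotype table")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "individual":
        raise ValueError(
            f"{path}: header must start with 'individual' followed by loci"
        )
    loci = tuple(header[1:])
    individuals: list[str] = []
    calls: dict[str, dict[str, Call]] = {}
    for line_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}: line {line_no}: expected {len(header)} columns")
        ind = parts[0]
        individuals.append(ind)
        row: dict[str, Call] = {}
        for loc, cell in zip(loci, parts[1:]):
            if cell == MISSING:
                row[loc] = None
                continue
            try:
                a, b = cell.split("/")
                pair = tuple(sorted((int(a), int(b))))
            except ValueError:
                raise ValueError(
                    f"{path}: line {line_no}: bad genotype cell {cell!r} "
                    "(expected 'a1/a2' or '?')"
                ) from None
            row[loc] = pair
        calls[ind] = row
    return GenotypeTable(tuple(individuals), loci, calls)


def write_genotype_tsv(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(table.loci) + "\n")
        for ind in table.individuals:
            cells = []
            for loc in table.loci:
                call = table.calls[ind][loc]
                cells.append(MISSING if call is None else f"{call[0]}/{call[1]}")
            fh.write(ind + "\t" + "\t".join(cells) + "\n")
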