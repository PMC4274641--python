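"""Gene family-free gene cluster discovery for pairwise genome comparison.

Instead of partitioning genes into families, genomes are compared directly
under a symmetric pairwise gene similarity measure σ ≥ 0 (e.g. relative
reciprocal BLAST scores).  Each chromosome is a string of unique gene
identifiers; the similarity table induces an index mapping ``B_A`` whose
position ``y`` lists the positions of genome ``A`` with positive similarity
to gene ``y`` of ``B`` (or the INF placeholder).  Gene clusters are then the
mutually-closed (approximate) weak common intervals of ``(I_A, B_A)``.

Candidate clusters are ranked by a best-hit score: for every gene of one
interval, the fraction of its globally best similarity that is attained
inside the partner interval (μ ∈ [0, 1]), summed over both intervals.
Spurious similarities can be pruned beforehand with a stringency threshold
relative to each gene's best hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .acsi import acsi_mapping
from .awcii import awcii_mapping
from .core import IndexMapping, Interval, IntervalPair
from .oracle import ResultSet
from .wcii import wcii_mapping

__all__ = [
    "GeneOrder",
    "SimilarityTable",
    "ClusterReport",
    "similarity_index_mapping",
    "mu",
    "pair_score",
    "stringency_filter",
    "discover_clusters",
    "compare_genomes",
    "ALGORITHMS",
]

ALGORITHMS = ("wcii", "awcii", "acsi")


@dataclass(frozen=True)
class GeneOrder:
    """Ordered gene identifiers of one chromosome; position = chromosomal order."""

    genes: tuple[str, ...]
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene identifiers in gene order {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def at(self, p: int) -> str:
        """Gene identifier at 1-based position ``p``."""
        if not 1 <= p <= len(self.genes):
            raise IndexError(f"position {p} out of range")
        return self.genes[p - 1]

    def index(self) -> dict[str, int]:
        """Gene identifier → 1-based position."""
        return {g: p for p, g in enumerate(self.genes, start=1)}


class SimilarityTable:
    """Sparse symmetric gene similarity map ``(a, b) → σ ≥ 0``.

    Absent entries mean 0.  Entries supplied in both orientations (or
    repeatedly) are averaged, keeping the table symmetric by construction.
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]] = ()):
        acc: dict[tuple[str, str], list[float]] = {}
        for a, b, s in entries:
            s = float(s)
            if s < 0:
                raise ValueError(f"negative similarity for ({a!r}, {b!r})")
            key = (a, b) if a <= b else (b, a)
            acc.setdefault(key, []).append(s)
        self._scores: dict[tuple[str, str], float] = {
            k: sum(v) / len(v) for k, v in acc.items()
        }
        self._adj: dict[str, dict[str, float]] = {}
        for (a, b), s in self._scores.items():
            if s > 0:
                self._adj.setdefault(a, {})[b] = s
                self._adj.setdefault(b, {})[a] = s

    def get(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        return self._scores.get(key, 0.0)

    def partners(self, g: str) -> Mapping[str, float]:
        """Positive-similarity partners of gene ``g``."""
        return self._adj.get(g, {})

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self._scores:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def items(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), s in sorted(self._scores.items()):
            yield a, b, s

    def __len__(self) -> int:
        return len(self._scores)

    def scaled(self, c: float) -> "SimilarityTable":
        """All similarities multiplied by ``c > 0`` (for invariance checks)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return SimilarityTable((a, b, s * c) for (a, b), s in self._scores.items())


def similarity_index_mapping(
    a: GeneOrder, b: GeneOrder, sigma: SimilarityTable, *, strict: bool = True
) -> IndexMapping:
    """Index mapping ``B_A``: positions of ``a`` with positive similarity to each gene of ``b``.

    With ``strict`` (the default), a similarity entry whose genes occur in
    neither gene order raises a ValueError.
    """
    idx_a = a.index()
    if strict:
        known = set(a.genes) | set(b.genes)
        for ga, gb, _ in sigma.items():
            if ga not in known or gb not in known:
                missing = ga if ga not in known else gb
                raise ValueError(f"similarity entry references unknown gene {missing!r}")
    sets = []
    for g in b.genes:
        sets.append({idx_a[p] for p in sigma.partners(g) if p in idx_a})
    return IndexMapping(sets, source_len=len(a), provenance=b.genes)


def _best(sigma: SimilarityTable, g: str, other: Sequence[str]) -> float:
    partners = sigma.partners(g)
    other_set = set(other)
    vals = [s for p, s in partners.items() if p in other_set]
    return max(vals) if vals else 0.0


def mu(
    x: int,
    interval: tuple[int, int] | Interval,
    x_order: GeneOrder,
    y_order: GeneOrder,
    sigma: SimilarityTable,
) -> float:
    """Best-hit fraction of gene at position ``x`` of ``x_order`` into an interval of ``y_order``.

    ``max_{y ∈ [a,b]} σ(x, y) / max_{z ∈ Y} σ(x, z)``; 1 exactly when a
    globally best hit of ``x`` lies inside the interval, 0 when ``x`` has no
    positive similarity into ``Y``.
    """
    a, b = (interval.lo, interval.hi) if isinstance(interval, Interval) else interval
    if not (1 <= a <= b <= len(y_order)):
        raise IndexError(f"interval [{a}, {b}] out of range on partner gene order")
    gx = x_order.at(x)
    denom = _best(sigma, gx, y_order.genes)
    if denom == 0:
        return 0.0
    num = max(sigma.get(gx, y_order.at(y)) for y in range(a, b + 1))
    return num / denom


def pair_score(
    pair: IntervalPair,
    a: GeneOrder,
    b: GeneOrder,
    sigma: SimilarityTable,
) -> float:
    """Cluster score: summed μ of every gene of each interval into the partner interval."""
    if pair.left.hi > len(a) or pair.right.hi > len(b):
        raise IndexError("interval pair out of range on gene orders")
    s = sum(
        mu(x, (pair.right.lo, pair.right.hi), a, b, sigma) for x in pair.left.positions()
    )
    s += sum(
        mu(y, (pair.left.lo, pair.left.hi), b, a, sigma) for y in pair.right.positions()
    )
    return s


def stringency_filter(
    sigma: SimilarityTable, f: float, *, rule: str = "min"
) -> SimilarityTable:
    """Drop similarity edges below a fraction ``f`` of the endpoint best hits.

    An edge ``(a, b)`` is kept iff ``σ(a,b) ≥ f · agg(best(a), best(b))``
    where ``best(g)`` is the gene's maximum similarity and ``agg`` is ``min``
    (default) or ``max``.  ``f = 0`` keeps every positive edge; larger ``f``
    keeps a subset of what smaller ``f`` keeps.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"stringency f must be in [0, 1], got {f}")
    if rule not in ("min", "max"):
        raise ValueError(f"unknown stringency rule {rule!r}")
    agg = min if rule == "min" else max
    best: dict[str, float] = {}
    for a, b, s in sigma.items():
        if s > 0:
            best[a] = max(best.get(a, 0.0), s)
            best[b] = max(best.get(b, 0.0), s)
    kept = [
        (a, b, s)
        for a, b, s in sigma.items()
        if s > 0 and s >= f * agg(best[a], best[b])
    ]
    return SimilarityTable(kept)


@dataclass(frozen=True)
class ClusterReport:
    """A scored candidate gene cluster from one chromosome-pair comparison."""

    pair: IntervalPair
    score: float
    genes_left: tuple[str, ...]
    genes_right: tuple[str, ...]
    chrom_left: str = ""
    chrom_right: str = ""

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be non-negative")


_MAPPING_SOLVERS = {
    "wcii": lambda ts, delta, min_size: wcii_mapping(ts, min_size=min_size),
    "awcii": awcii_mapping,
    "acsi": acsi_mapping,
}


def discover_clusters(
    a: GeneOrder,
    b: GeneOrder,
    sigma: SimilarityTable,
    delta: int = 0,
    min_size: int = 3,
    f: float = 0.0,
    algorithm: str = "acsi",
) -> list[ClusterReport]:
    """Discover and score gene clusters between two gene orders.

    Applies the stringency filter, builds ``B_A``, runs the chosen discovery
    algorithm on ``(I_A, B_A)``, and returns scored reports sorted by
    descending score, then canonical coordinates.  ``wcii`` only supports
    ``delta = 0``.
    """
    if algorithm not in _MAPPING_SOLVERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if algorithm == "wcii" and delta != 0:
        raise ValueError("wcii solves the delta = 0 problem only")
    filtered = stringency_filter(sigma, f)
    ba = similarity_index_mapping(a, b, filtered, strict=False)
    pairs: ResultSet = _MAPPING_SOLVERS[algorithm](ba, delta, min_size)
    reports = []
    for p in pairs:
        score = pair_score(p, a, b, filtered)
        reports.append(
            ClusterReport(
                pair=IntervalPair(
                    left=p.left,
                    right=p.right,
                    common_set=p.common_set,
                    indels=p.indels,
                    score=score,
                ),
                score=score,
                genes_left=tuple(a.at(x) for x in p.left.positions()),
                genes_right=tuple(b.at(y) for y in p.right.positions()),
                chrom_left=a.name,
                chrom_right=b.name,
            )
        )
    reports.sort(key=lambda r: (-r.score, r.pair.coords()))
    return reports


def compare_genomes(
    genome_a: Mapping[str, GeneOrder],
    genome_b: Mapping[str, GeneOrder],
    sigma: SimilarityTable,
    delta: int = 0,
    min_size: int = 3,
    f: float = 0.0,
    algorithm: str = "acsi",
) -> list[ClusterReport]:
    """Pairwise genome comparison, chromosome pair by chromosome pair.

    Clusters never span chromosomes.  Similarity entries must reference genes
    of the two genomes.
    """
    known = set()
    for go in list(genome_a.values()) + list(genome_b.values()):
        known.update(go.genes)
    for ga, gb, _ in sigma.items():
        if ga not in known or gb not in known:
            missing = ga if ga not in known else gb
            raise ValueError(f"similarity entry references unknown gene {missing!r}")
    reports: list[ClusterReport] = []
    for ca in sorted(genome_a):
        for cb in sorted(genome_b):
            reports.extend(
                discover_clusters(
                    genome_a[ca], genome_b[cb], sigma, delta, min_size, f, algorithm
                )
            )
    reports.sort(key=lambda r: (-r.score, r.chrom_left, r.chrom_right, r.pair.coords()))
    return reports
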