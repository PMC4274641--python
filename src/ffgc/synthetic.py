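"""Reproducible synthetic fixtures: random string pairs and planted gene clusters.

The family-free generator emulates the discovery use case: two genomes that
share a handful of conserved gene clusters.  Each planted cluster is a block
of genes whose pairwise similarities are mutual global best hits, optionally
interrupted by up to δ inserted genes on one side (indels); the remaining
similarity graph is sparse low-score noise.  By construction every planted
block (without noise interference) is a mutually-closed weak common interval
pair of ``(I_A, B_A)`` at the matching indel threshold.

Noise is parameterized as spurious edges per gene: ``noise_rate = 0.05``
adds about one spurious low-score edge per 20 genes.  Noise scores are drawn
strictly below cluster scores, so best hits inside planted blocks are never
displaced; noise can still break closedness when it touches a block's
immediate neighbourhood, which is exactly the failure mode real spurious
similarities cause.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .core import IndeterminateString, Interval, IntervalPair
from .familyfree import GeneOrder, SimilarityTable

__all__ = [
    "GenConfig",
    "random_indeterminate_pair",
    "planted_cluster_dataset",
    "random_family_genomes",
]


@dataclass
class GenConfig:
    """Configuration of the synthetic generators; one seed drives all randomness."""

    seed: int = 0
    # random indeterminate string pairs
    alphabet_size: int = 8
    n: int = 12
    m: int = 12
    set_size_min: int = 1
    set_size_max: int = 3
    disjoint_alphabets: bool = False
    # family-free planted-cluster datasets
    genome_size_a: int = 40
    genome_size_b: int = 40
    n_clusters: int = 3
    cluster_size: int = 4
    cluster_indels: int = 0
    noise_rate: float = 0.05
    cluster_score_range: tuple[float, float] = (0.5, 1.0)
    noise_score_range: tuple[float, float] = (0.05, 0.2)
    # random family-annotated genomes
    n_families: int = 8

    def __post_init__(self):
        for name in (
            "alphabet_size",
            "n",
            "m",
            "set_size_min",
            "set_size_max",
            "genome_size_a",
            "genome_size_b",
            "cluster_size",
            "n_families",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters < 0 or self.cluster_indels < 0:
            raise ValueError("cluster counts must be non-negative")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.set_size_min > self.set_size_max:
            raise ValueError("set_size_min must not exceed set_size_max")


def random_indeterminate_pair(
    cfg: GenConfig,
) -> tuple[IndeterminateString, IndeterminateString]:
    """A reproducible random pair of indeterminate strings over a shared alphabet.

    Position sets are uniform samples of the configured size range; with
    ``disjoint_alphabets`` the second string uses its own alphabet, so the
    pair shares no characters at all.
    """
    rng = random.Random(cfg.seed)
    alpha_s = [f"c{i}" for i in range(1, cfg.alphabet_size + 1)]
    alpha_t = (
        [f"d{i}" for i in range(1, cfg.alphabet_size + 1)]
        if cfg.disjoint_alphabets
        else alpha_s
    )

    def draw(length: int, alphabet: list[str]) -> IndeterminateString:
        sets = []
        for _ in range(length):
            size = rng.randint(cfg.set_size_min, min(cfg.set_size_max, len(alphabet)))
            sets.append(rng.sample(alphabet, size))
        return IndeterminateString(sets)

    return draw(cfg.n, alpha_s), draw(cfg.m, alpha_t)


def _place_blocks(
    rng: random.Random, genome_len: int, block_sizes: list[int]
) -> list[int]:
    """Random non-overlapping block starts (1-based) with ≥ 1 gene between blocks."""
    k = len(block_sizes)
    if k == 0:
        return []
    needed = sum(block_sizes) + (k - 1)
    if needed > genome_len:
        raise ValueError(
            f"infeasible packing: {k} clusters need {needed} positions, genome has {genome_len}"
        )
    slack = genome_len - needed
    # distribute slack over k+1 gaps (ends may be empty, inner gaps get +1 below)
    cuts = sorted(rng.randint(0, slack) for _ in range(k))
    gaps = [cuts[0]] + [cuts[t] - cuts[t - 1] for t in range(1, k)] + [slack - cuts[-1]]
    starts = []
    pos = 1
    for t, size in enumerate(block_sizes):
        pos += gaps[t] + (1 if t > 0 else 0)
        starts.append(pos)
        pos += size
    return starts


def planted_cluster_dataset(
    cfg: GenConfig,
) -> tuple[GeneOrder, GeneOrder, SimilarityTable, list[IntervalPair]]:
    """Two gene orders with planted conserved clusters and their ground truth.

    Each planted cluster occupies ``cluster_size`` positions in genome A and
    ``cluster_size + cluster_indels`` in genome B (the inserted genes sit in
    the interior of the B block and have no similarity to anything).  Ground
    truth interval pairs are returned in output coordinates with their indel
    counts.
    """
    if cfg.cluster_indels > 0 and cfg.cluster_size < 2:
        raise ValueError("clusters with indels need size at least 2")
    rng = random.Random(cfg.seed)
    size_b_block = cfg.cluster_size + cfg.cluster_indels
    genes_a = [f"a{i}" for i in range(1, cfg.genome_size_a + 1)]
    len_b = cfg.genome_size_b + cfg.n_clusters * cfg.cluster_indels
    genes_b = [f"b{i}" for i in range(1, len_b + 1)]
    starts_a = _place_blocks(rng, cfg.genome_size_a, [cfg.cluster_size] * cfg.n_clusters)
    starts_b = _place_blocks(rng, len_b, [size_b_block] * cfg.n_clusters)
    # keep block ordering independent between the genomes
    rng.shuffle(starts_b)

    entries: list[tuple[str, str, float]] = []
    truth: list[IntervalPair] = []
    paired: set[tuple[str, str]] = set()
    for sa, sb in zip(starts_a, starts_b):
        # inserted (indel) slots lie strictly inside the B block
        interior = list(range(1, size_b_block - 1))
        indel_offsets = set(rng.sample(interior, cfg.cluster_indels))
        match_offsets = [o for o in range(size_b_block) if o not in indel_offsets]
        for t, o in enumerate(match_offsets):
            ga, gb = genes_a[sa - 1 + t], genes_b[sb - 1 + o]
            entries.append((ga, gb, rng.uniform(*cfg.cluster_score_range)))
            paired.add((ga, gb))
        truth.append(
            IntervalPair(
                left=Interval(sa, sa + cfg.cluster_size - 1),
                right=Interval(sb, sb + size_b_block - 1),
                indels=cfg.cluster_indels,
            )
        )

    n_noise = round(cfg.noise_rate * (len(genes_a) + len(genes_b)) / 2)
    attempts = 0
    added = 0
    while added < n_noise and attempts < 100 * (n_noise + 1):
        attempts += 1
        ga = rng.choice(genes_a)
        gb = rng.choice(genes_b)
        if (ga, gb) in paired:
            continue
        paired.add((ga, gb))
        entries.append((ga, gb, rng.uniform(*cfg.noise_score_range)))
        added += 1

    return (
        GeneOrder(tuple(genes_a), name="A"),
        GeneOrder(tuple(genes_b), name="B"),
        SimilarityTable(entries),
        truth,
    )


def random_family_genomes(
    cfg: GenConfig,
) -> tuple[GeneOrder, GeneOrder, SimilarityTable, list[str], list[str]]:
    """Two gene orders with random family labels and the family-based similarity.

    σ = 1 between genes of the same family, 0 otherwise — the degenerate case
    in which family-free discovery must coincide with classic common-interval
    detection on the family strings.  Returns the two gene orders, the
    similarity table, and the per-position family labels.
    """
    rng = random.Random(cfg.seed)
    fams = [f"F{i}" for i in range(1, cfg.n_families + 1)]
    fam_a = [rng.choice(fams) for _ in range(cfg.genome_size_a)]
    fam_b = [rng.choice(fams) for _ in range(cfg.genome_size_b)]
    genes_a = [f"a{i}" for i in range(1, cfg.genome_size_a + 1)]
    genes_b = [f"b{i}" for i in range(1, cfg.genome_size_b + 1)]
    entries = [
        (ga, gb, 1.0)
        for ga, la in zip(genes_a, fam_a)
        for gb, lb in zip(genes_b, fam_b)
        if la == lb
    ]
    return (
        GeneOrder(tuple(genes_a), name="A"),
        GeneOrder(tuple(genes_b), name="B"),
        SimilarityTable(entries),
        fam_a,
        fam_b,
    )
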