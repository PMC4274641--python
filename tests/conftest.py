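"""Shared fixtures: compact string construction and the randomized oracle battery."""

from __future__ import annotations

import random
from types import SimpleNamespace

import pytest

from ffgc.core import IndeterminateString
from ffgc.familyfree import discover_clusters
from ffgc.oracle import classify_all, enumerate_bruteforce
from ffgc.synthetic import GenConfig, planted_cluster_dataset, random_indeterminate_pair


def istr(text: str) -> IndeterminateString:
    """Compact notation: positions separated by spaces, characters by commas.

    ``istr("a,d,g c a,d e,f b c,g")`` is the 6-position worked-example string.
    """
    return IndeterminateString([tok.split(",") for tok in text.split()])


#: the worked example: |S| = 6, ‖S‖ = 11 over {a,...,g}
EXAMPLE_TEXT = "a,d,g c a,d e,f b c,g"


def battery_instances(
    count: int = 210, max_len: int = 25, seed: int = 20240
) -> list[tuple[IndeterminateString, IndeterminateString]]:
    """Randomized instances plus adversarial fixtures for equivalence testing."""
    rng = random.Random(seed)
    out = []
    for k in range(count):
        cfg = GenConfig(
            seed=rng.randint(0, 2**30),
            n=rng.randint(2, max_len),
            m=rng.randint(2, max_len),
            alphabet_size=rng.randint(2, 10),
            set_size_min=1,
            set_size_max=3,
            disjoint_alphabets=(k % 29 == 7),  # yields all-INF index mappings
        )
        out.append(random_indeterminate_pair(cfg))
    # adversarial: long runs of identical sets and near-disjoint alphabets
    out.append((istr("a,b a,b a,b a,b a,b a,b"), istr("a b a b a b")))
    out.append((istr("a a a a a a"), istr("a a a a")))
    out.append((istr("a b c d e"), istr("e d c b a")))
    out.append((istr("a x a x a"), istr("a a y a")))  # INF-rich mapping at i > 1
    out.append((istr("a,b c a,b c"), istr("c a,b z z c a,b")))
    return out


@pytest.fixture(scope="session")
def battery():
    """Instances with precomputed oracle result sets for δ = 0..3 (min_size = 1)."""
    items = []
    for s, t in battery_instances():
        cls = classify_all(s, t)
        oracles = {
            d: enumerate_bruteforce(s, t, d, 1, classification=cls) for d in range(4)
        }
        items.append(SimpleNamespace(s=s, t=t, oracle=oracles))
    return items


def planted_recall(
    n_replicates: int,
    noise_rate: float,
    cluster_indels: int = 0,
    delta: int = 0,
    seed0: int = 500,
) -> float:
    """Fraction of planted clusters recovered by discovery over seeded replicates."""
    found = total = 0
    for r in range(n_replicates):
        cfg = GenConfig(
            seed=seed0 + r,
            genome_size_a=40,
            genome_size_b=40,
            n_clusters=3,
            cluster_size=4,
            cluster_indels=cluster_indels,
            noise_rate=noise_rate,
        )
        a, b, sigma, truth = planted_cluster_dataset(cfg)
        reports = discover_clusters(a, b, sigma, delta=delta, min_size=3, f=0.0)
        coords = {r_.pair.coords() for r_ in reports}
        total += len(truth)
        found += sum(1 for p in truth if p.coords() in coords)
    return found / total


@pytest.fixture(scope="session")
def noisy_recall():
    """Recall of planted clusters under 5% spurious similarity edges, 50 replicates."""
    return planted_recall(n_replicates=50, noise_rate=0.05)
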