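"""Plain-text parsers and writers for all package formats (TSV everywhere).

Formats
-------
Indeterminate string
    One position per line, characters comma-separated; blank lines and lines
    starting with ``#`` are ignored; the token ``INF`` is reserved for the
    index-mapping placeholder.
Gene order
    TSV with header ``chromosome  position_rank  gene_id``; ranks order the
    genes within each chromosome.
Similarity
    TSV with header ``gene_id_a  gene_id_b  score``; undirected, duplicate
    orientations averaged.
Results
    Interval-pair TSV (``lo1 hi1 lo2 hi2 common_size indels``) and the richer
    cluster-report TSV.  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .core import INF, IndeterminateString
from .familyfree import ClusterReport, GeneOrder, SimilarityTable
from .oracle import ResultSet

__all__ = [
    "FormatError",
    "parse_indeterminate",
    "write_indeterminate",
    "read_gene_orders",
    "write_gene_orders",
    "read_similarity",
    "write_similarity",
    "write_resultset",
    "write_cluster_reports",
]

INF_TOKEN = "INF"


class FormatError(ValueError):
    """Malformed input file content."""


def parse_indeterminate(path: str | os.PathLike) -> IndeterminateString:
    """Read an indeterminate string from its one-position-per-line text format."""
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t.strip() for t in line.split(",")]
            if any(not t for t in tokens):
                raise FormatError(f"{path}:{lineno}: empty character in position set")
            chars = [INF if t == INF_TOKEN else t for t in tokens]
            if INF in chars and len(set(chars)) > 1:
                raise FormatError(
                    f"{path}:{lineno}: {INF_TOKEN} must be the sole character of a position"
                )
            sets.append(chars)
    try:
        return IndeterminateString(sets)
    except ValueError as exc:  # pragma: no cover - guarded above
        raise FormatError(f"{path}: {exc}") from exc


def write_indeterminate(s: IndeterminateString, path: str | os.PathLike) -> None:
    """Write the one-position-per-line text format (round-trips with the parser)."""
    with open(path, "w", encoding="utf-8") as fh:
        for cs in s:
            tokens = sorted(INF_TOKEN if c == INF else str(c) for c in cs)
            fh.write(",".join(tokens) + "\n")


_ORDER_COLS = ["chromosome", "position_rank", "gene_id"]


def read_gene_orders(path: str | os.PathLike) -> dict[str, GeneOrder]:
    """Read a gene-order TSV into per-chromosome gene orders."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene_id": str})
    if list(df.columns) != _ORDER_COLS:
        raise FormatError(
            f"{path}: expected columns {_ORDER_COLS}, found {list(df.columns)}"
        )
    out: dict[str, GeneOrder] = {}
    for chrom, grp in df.groupby("chromosome", sort=True):
        grp = grp.sort_values("position_rank")
        try:
            out[str(chrom)] = GeneOrder(tuple(grp["gene_id"]), name=str(chrom))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no gene orders found")
    return out


def write_gene_orders(orders: Mapping[str, GeneOrder], path: str | os.PathLike) -> None:
    rows = [
        (chrom, rank, gene)
        for chrom in sorted(orders)
        for rank, gene in enumerate(orders[chrom].genes, start=1)
    ]
    pd.DataFrame(rows, columns=_ORDER_COLS).to_csv(path, sep="\t", index=False)


_SIM_COLS = ["gene_id_a", "gene_id_b", "score"]


def read_similarity(path: str | os.PathLike) -> SimilarityTable:
    """Read an undirected gene similarity TSV (duplicate orientations averaged)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id_a": str, "gene_id_b": str})
    if list(df.columns) != _SIM_COLS:
        raise FormatError(
            f"{path}: expected columns {_SIM_COLS}, found {list(df.columns)}"
        )
    try:
        return SimilarityTable(
            (a, b, float(s)) for a, b, s in df.itertuples(index=False)
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_similarity(sigma: SimilarityTable, path: str | os.PathLike) -> None:
    pd.DataFrame(list(sigma.items()), columns=_SIM_COLS).to_csv(
        path, sep="\t", index=False
    )


def write_resultset(rs: ResultSet, path: str | os.PathLike) -> None:
    """Interval-pair TSV in canonical order: lo1 hi1 lo2 hi2 common_size indels."""
    rows = [
        (p.left.lo, p.left.hi, p.right.lo, p.right.hi, len(p.common_set), p.indels)
        for p in rs
    ]
    pd.DataFrame(
        rows, columns=["lo1", "hi1", "lo2", "hi2", "common_size", "indels"]
    ).to_csv(path, sep="\t", index=False)


def write_cluster_reports(
    reports: Iterable[ClusterReport], path: str | os.PathLike
) -> None:
    """Scored cluster TSV, one row per reported interval pair."""
    rows = []
    for r in reports:
        rows.append(
            (
                r.chrom_left,
                r.pair.left.lo,
                r.pair.left.hi,
                r.chrom_right,
                r.pair.right.lo,
                r.pair.right.hi,
                len(r.pair.left),
                len(r.pair.right),
                r.pair.indels,
                f"{r.score:.4f}",
                ",".join(r.genes_left),
                ",".join(r.genes_right),
            )
        )
    cols = [
        "chrA",
        "loA",
        "hiA",
        "chrB",
        "loB",
        "hiB",
        "size_A",
        "size_B",
        "indels",
        "score",
        "genesA",
        "genesB",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
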