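"""Simplified Phylogenetic Intersect Analysis for endogenous-content checks.

Ultrashort, conserved small-RNA sequences often hit many taxa; the
intersect approach assigns a read to the lowest common ancestor (LCA) of
its top two database hits, after discarding reads whose top two hit scores
tie (no discriminating signal) and reads whose intersect is unresolvable
("unknowable": a hit taxon missing from the taxonomy, or an intersect at
the root).  A read is then counted exogenous only if it neither maps to
the target genome nor intersects anywhere on the lineage leading to the
target taxon; redundancy frequencies weight each unique sequence by its
read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .damage_match import ReferenceIndex
from .references import ReferenceSet


@dataclass
class Taxonomy:
    """A rooted taxonomy as a child -> parent map, with a focal taxon.

    The target lineage is the path from the root down to ``target``; reads
    whose intersect lies on that path are consistent with a putative
    target-taxon assignment.
    """

    parent: dict[str, str | None]
    target: str

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        if self.target not in self.parent:
            raise ValueError(f"target taxon {self.target!r} not in taxonomy")
        for node in self.parent:
            if node not in set(self.lineage(node)):
                raise ValueError(f"node {node!r} not reachable from root")
        self.target_lineage = set(self.lineage(self.target))

    def lineage(self, node: str) -> list[str]:
        """Path from ``node`` up to the root, inclusive."""
        path = [node]
        seen = {node}
        while self.parent[path[-1]] is not None:
            nxt = self.parent[path[-1]]
            if nxt in seen:
                raise ValueError(f"cycle in taxonomy at {nxt!r}")
            path.append(nxt)
            seen.add(nxt)
        return path

    def lca(self, a: str, b: str) -> str | None:
        """Lowest common ancestor, or None when either taxon is unknown."""
        if a not in self.parent or b not in self.parent:
            return None
        ancestors_a = self.lineage(a)
        set_b = set(self.lineage(b))
        for node in ancestors_a:
            if node in set_b:
                return node
        return None

    @classmethod
    def from_parent_table(cls, path: str | Path, target: str) -> "Taxonomy":
        """Load from a two-column TSV (node, parent; empty parent = root)."""
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        parent = {
            row.node: (row.parent or None) for row in table.itertuples(index=False)
        }
        return cls(parent=parent, target=target)

    def to_parent_table(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"node": list(self.parent), "parent": [p or "" for p in self.parent.values()]}
        ).to_csv(path, sep="\t", index=False)
        return path


@dataclass
class HitList:
    """Ordered database hits for one query (non-increasing score)."""

    query_id: str
    hits: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        scores = [s for _, s in self.hits]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError(f"hits for {self.query_id!r} not sorted by score")


UNKNOWABLE = "unknowable"


def filter_ties(hits: HitList) -> bool:
    """Keep a read unless its top two hit scores are identical.

    Single-hit lists are kept; an empty hit list carries no evidence and
    is discarded.
    """
    if not hits.hits:
        return False
    if len(hits.hits) >= 2 and hits.hits[0][1] == hits.hits[1][1]:
        return False
    return True


def intersect_node(hits: HitList, taxonomy: Taxonomy) -> str:
    """Classification intersect: LCA of the top two hits' taxa.

    Returns :data:`UNKNOWABLE` when a hit taxon is absent from the
    taxonomy or the LCA is the root (basal, unresolvable).  A single-hit
    list intersects at that hit's own taxon.
    """
    if not hits.hits:
        return UNKNOWABLE
    if len(hits.hits) == 1:
        taxon = hits.hits[0][0]
        if taxon not in taxonomy.parent or taxon == taxonomy.root:
            return UNKNOWABLE
        return taxon
    node = taxonomy.lca(hits.hits[0][0], hits.hits[1][0])
    if node is None or node == taxonomy.root:
        return UNKNOWABLE
    return node


@dataclass
class EndogenousReport:
    """Outcome of the endogenous-content estimate."""

    endogenous_proportion: float
    accuracy: float | None
    total_weight: float
    exogenous_weight: float
    n_sequences: int
    n_genome_mapping: int


def endogenous_content(
    hitlists: Sequence[HitList],
    taxonomy: Taxonomy,
    genome: ReferenceSet,
    redundancy: Mapping[str, float],
    sequences: Mapping[str, str],
    mode: str = "ancient",
) -> EndogenousReport:
    """Frequency-weighted lower bound on the endogenous read fraction.

    A sequence counts as exogenous only when it (a) does not map to the
    target genome (damage-aware in ancient mode) and (b) has no intersect
    on the target lineage.  Reads discarded by the tie filter or with an
    unknowable intersect fail criterion (b) but can still be rescued by a
    genome mapping; the result is therefore a lower bound.  ``accuracy``
    is the fraction of genome-mapping, intersect-bearing reads whose
    intersect lies on the target lineage.

    Parameters
    ----------
    hitlists: one per unique sequence (``query_id`` keys the other maps).
    redundancy: query_id -> read frequency (weight).
    sequences: query_id -> nucleotide sequence, for genome mapping.
    """
    if not hitlists:
        raise ValueError("endogenous_content requires at least one hit list")
    index = ReferenceIndex([genome])
    total = 0.0
    exogenous = 0.0
    on_lineage_mapped = 0.0
    intersecting_mapped = 0.0
    n_genome = 0
    for hl in hitlists:
        weight = float(redundancy.get(hl.query_id, 1.0))
        total += weight
        maps_genome = bool(index.match(sequences[hl.query_id], mode=mode))
        if maps_genome:
            n_genome += 1
        consistent = False
        node = None
        if filter_ties(hl):
            node = intersect_node(hl, taxonomy)
            if node != UNKNOWABLE:
                consistent = node in taxonomy.target_lineage
        if not maps_genome and not consistent:
            exogenous += weight
        if maps_genome and node is not None and node != UNKNOWABLE:
            intersecting_mapped += weight
            if consistent:
                on_lineage_mapped += weight
    accuracy = (
        on_lineage_mapped / intersecting_mapped if intersecting_mapped > 0 else None
    )
    return EndogenousReport(
        endogenous_proportion=1.0 - exogenous / total,
        accuracy=accuracy,
        total_weight=total,
        exogenous_weight=exogenous,
        n_sequences=len(hitlists),
        n_genome_mapping=n_genome,
    )


def read_hitlists(path: str | Path) -> list[HitList]:
    """Read hit lists from TSV with columns (query, taxon, score)."""
    table = pd.read_csv(path, sep="\t", dtype={"query": str, "taxon": str})
    out = []
    for query_id, group in table.groupby("query", sort=True):
        hits = sorted(
            zip(group["taxon"], group["score"].astype(float)),
            key=lambda ts: -ts[1],
        )
        out.append(HitList(query_id=str(query_id), hits=hits))
    return out


def write_hitlists(hitlists: Sequence[HitList], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"query": hl.query_id, "taxon": taxon, "score": score}
        for hl in hitlists
        for taxon, score in hl.hits
    ]
    pd.DataFrame(rows, columns=["query", "taxon", "score"]).to_csv(
        path, sep="\t", index=False
    )
    return path
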