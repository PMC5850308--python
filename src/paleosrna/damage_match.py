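"""Deamination-aware matching of small-RNA sequences to references.

Postmortem cytosine deamination reads out as C->T on the strand a fragment
derives from.  When that fragment aligns to the reference forward strand
(+) the damage appears as reference C vs read T; when it derives from the
reverse strand (-) it appears, in forward-reference coordinates, as
reference G vs an implied A.  Ancient-mode matching therefore accepts at
most one mismatch and only of that kind; modern-mode matching is exact.

Coordinates are 0-based, half-open, on the reference forward strand.  A
k-mer index over the references makes the scan fast, but the contract is
defined by exhaustive enumeration over every offset, strand and mismatch
pattern (the test suite compares the two directly).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .references import CLASS_PRIORITY, ReferenceSet, reverse_complement

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class MatchResult:
    """One placement of a query on a reference.

    ``strand`` is '+' when the query matches the forward strand, '-' when
    its reverse complement does.  ``damage_consistent`` is vacuously true
    for exact matches; for single-mismatch matches it records that the
    mismatch is C->T in the frame of the strand the read derives from.
    """

    query_sequence: str
    reference_name: str
    reference_class: str
    strand: str
    position: int
    n_mismatches: int
    damage_consistent: bool

    def sort_key(self) -> tuple:
        return (self.reference_name, self.position, self.strand)


def _mismatches(query: str, ref_window: str) -> list[int]:
    """Positions where query and window disagree; N never matches."""
    return [
        i
        for i, (q, r) in enumerate(zip(query, ref_window))
        if q != r or q not in _ACGT or r not in _ACGT
    ]


def _damage_ok(strand: str, ref_base: str, fwd_query_base: str) -> bool:
    # '+' strand: reference C sequenced as T.  '-' strand: the read's C->T
    # appears on the forward reference as G vs A.
    if strand == "+":
        return ref_base == "C" and fwd_query_base == "T"
    return ref_base == "G" and fwd_query_base == "A"


class ReferenceIndex:
    """K-mer seed index over one or more reference sets.

    With at most one mismatch allowed, a query of length L >= 2k always
    contains an exact seed of length k in either its first or last k bases
    (pigeonhole), so two seed lookups per strand enumerate every candidate
    placement; each candidate is then verified base by base.
    """

    def __init__(self, reference_sets: Iterable[ReferenceSet], k: int = 9):
        self.k = k
        self.references: dict[str, tuple[str, str]] = {}  # name -> (seq, class)
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for refset in reference_sets:
            for name, seq in refset:
                if name in self.references:
                    raise ValueError(f"duplicate reference name {name!r}")
                self.references[name] = (seq, refset.class_label)
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if _ACGT.issuperset(kmer):
                        self._index[kmer].append((name, i))

    def _candidates(self, oriented: str) -> set[tuple[str, int]]:
        """Candidate (reference, start) placements for one orientation."""
        k = self.k
        n = len(oriented)
        cands: set[tuple[str, int]] = set()
        for offset in (0, n - k):
            seed = oriented[offset : offset + k]
            for name, pos in self._index.get(seed, ()):
                start = pos - offset
                if start >= 0:
                    cands.add((name, start))
        return cands

    def match(
        self, query: str, mode: str = "modern", max_len: int = 25, min_len: int = 18
    ) -> list[MatchResult]:
        """All accepted placements of ``query``, deterministically sorted.

        modern mode: exact occurrences of the query or its reverse
        complement.  ancient mode: additionally single-mismatch occurrences
        whose mismatch is deamination-consistent.  Queries containing
        characters outside A/C/G/T (including N) yield no matches.
        """
        if mode not in ("ancient", "modern"):
            raise ValueError(f"mode must be 'ancient' or 'modern', got {mode!r}")
        if not (min_len <= len(query) <= max_len):
            raise ValueError(
                f"query length {len(query)} outside [{min_len}, {max_len}]"
            )
        query = query.upper()
        if not _ACGT.issuperset(query):
            return []
        results: list[MatchResult] = []
        L = len(query)
        for strand in ("+", "-"):
            oriented = query if strand == "+" else reverse_complement(query)
            for name, start in self._candidates(oriented):
                seq, _cls = self.references[name]
                if start + L > len(seq):
                    continue
                window = seq[start : start + L]
                mm = _mismatches(oriented, window)
                if not mm:
                    results.append(self._result(query, name, strand, start, 0, True))
                elif mode == "ancient" and len(mm) == 1:
                    i = mm[0]
                    if _damage_ok(strand, window[i], oriented[i]):
                        results.append(
                            self._result(query, name, strand, start, 1, True)
                        )
        results.sort(key=MatchResult.sort_key)
        return results

    def _result(
        self, query: str, name: str, strand: str, pos: int, n_mm: int, damage: bool
    ) -> MatchResult:
        return MatchResult(
            query_sequence=query,
            reference_name=name,
            reference_class=self.references[name][1],
            strand=strand,
            position=pos,
            n_mismatches=n_mm,
            damage_consistent=damage,
        )


def match(
    query: str,
    references: ReferenceSet | Iterable[ReferenceSet],
    mode: str = "modern",
) -> list[MatchResult]:
    """One-shot convenience wrapper around :class:`ReferenceIndex`."""
    if isinstance(references, ReferenceSet):
        references = [references]
    return ReferenceIndex(references).match(query, mode=mode)


def assign_best(
    query: str,
    results: Sequence[MatchResult],
    class_priority: Sequence[str] = CLASS_PRIORITY,
) -> MatchResult | None:
    """Resolve a multi-class hit list to one assignment, or None.

    Exact (0-mismatch) hits beat single-mismatch hits; among equals the
    earliest class in ``class_priority`` wins; remaining ties break by the
    deterministic (reference, position, strand) sort order.
    """
    if not results:
        return None
    rank = {cls: i for i, cls in enumerate(class_priority)}

    def key(r: MatchResult) -> tuple:
        return (r.n_mismatches, rank.get(r.reference_class, len(rank)), r.sort_key())

    return min(results, key=key)


def assign_table(
    queries: pd.DataFrame,
    index: ReferenceIndex,
    mode: str,
    class_priority: Sequence[str] = CLASS_PRIORITY,
) -> pd.DataFrame:
    """Assign every unique sequence in a dereplicated table.

    Input columns: sequence, frequency (and optionally sample_id).
    Output adds: assigned_class ('unassigned' when no hit), reference,
    strand, position, n_mismatches.
    """
    rows = []
    for rec in queries.itertuples(index=False):
        hits = index.match(rec.sequence, mode=mode)
        best = assign_best(rec.sequence, hits, class_priority)
        rows.append(
            {
                "sequence": rec.sequence,
                "frequency": rec.frequency,
                "assigned_class": best.reference_class if best else "unassigned",
                "reference": best.reference_name if best else "",
                "strand": best.strand if best else "",
                "position": best.position if best else -1,
                "n_mismatches": best.n_mismatches if best else -1,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "frequency",
            "assigned_class",
            "reference",
            "strand",
            "position",
            "n_mismatches",
        ],
    )
    if "sample_id" in queries.columns and len(queries):
        out["sample_id"] = queries["sample_id"].to_numpy()
    return out
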