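"""The matcher's contract is defined by exhaustive enumeration: every
offset, strand and single-mismatch pattern, with the deamination rule
applied in the frame of the originating strand."""

import numpy as np
import pytest

from paleosrna.damage_match import (
    MatchResult,
    ReferenceIndex,
    assign_best,
    match,
)
from paleosrna.references import ReferenceSet, reverse_complement

_ACGT = set("ACGT")


def brute_force_match(query, refsets, mode):
    """Independent oracle: direct scan over every placement."""
    query = query.upper()
    if not _ACGT.issuperset(query):
        return []
    results = []
    for refset in refsets:
        for name, seq in refset:
            L = len(query)
            for strand in "+-":
                oriented = query if strand == "+" else reverse_complement(query)
                for start in range(len(seq) - L + 1):
                    window = seq[start : start + L]
                    mm = [
                        i
                        for i in range(L)
                        if oriented[i] != window[i]
                        or oriented[i] not in _ACGT
                        or window[i] not in _ACGT
                    ]
                    if not mm:
                        results.append(
                            MatchResult(query, name, refset.class_label, strand,
                                        start, 0, True)
                        )
                    elif mode == "ancient" and len(mm) == 1:
                        i = mm[0]
                        ok = (
                            (strand == "+" and window[i] == "C" and oriented[i] == "T")
                            or (strand == "-" and window[i] == "G" and oriented[i] == "A")
                        )
                        if ok:
                            results.append(
                                MatchResult(query, name, refset.class_label, strand,
                                            start, 1, True)
                            )
    results.sort(key=MatchResult.sort_key)
    return results


@pytest.fixture
def simple_refs():
    return ReferenceSet("mrna", {"ref1": "AAACGTCCGTACGTACGGTTACCGGAATTCCA"})


@pytest.mark.parametrize("mode", ["ancient", "modern"])
def test_exact_substring_matches_in_both_modes(simple_refs, mode):
    query = simple_refs.sequences["ref1"][3:23]
    hits = match(query, simple_refs, mode=mode)
    assert any(h.position == 3 and h.n_mismatches == 0 for h in hits)


def test_c_to_t_accepted_only_in_ancient_mode(simple_refs):
    ref = simple_refs.sequences["ref1"]
    window = ref[0:20]
    assert "C" in window
    i = window.index("C")
    damaged = window[:i] + "T" + window[i + 1 :]
    ancient = match(damaged, simple_refs, mode="ancient")
    modern = match(damaged, simple_refs, mode="modern")
    assert any(h.n_mismatches == 1 and h.damage_consistent for h in ancient)
    assert all(h.n_mismatches == 0 for h in modern)


def test_non_deamination_mismatch_rejected_everywhere(simple_refs):
    ref = simple_refs.sequences["ref1"]
    window = ref[0:20]
    i = window.index("A")
    mutated = window[:i] + "G" + window[i + 1 :]
    for mode in ("ancient", "modern"):
        hits = [h for h in match(mutated, simple_refs, mode=mode) if h.strand == "+"]
        assert not any(h.position == 0 for h in hits)


def test_minus_strand_damage_is_g_to_a_on_forward_reference():
    # fragment from the reverse strand: its C->T damage shows as G->A in
    # forward coordinates
    ref = "TTTACGGATCGGATCCGGATTACG" + "GTCA" * 3
    refs = ReferenceSet("mrna", {"r": ref})
    window = ref[2:22]
    i = window.index("G")
    read_rc = reverse_complement(window)  # the sequenced (reverse) strand
    j = len(window) - 1 - i  # position of the complementary C in the read
    assert read_rc[j] == "C"
    damaged_read = read_rc[:j] + "T" + read_rc[j + 1 :]
    hits = match(damaged_read, refs, mode="ancient")
    minus = [h for h in hits if h.strand == "-" and h.position == 2]
    assert len(minus) == 1
    assert minus[0].n_mismatches == 1 and minus[0].damage_consistent
    assert match(damaged_read, refs, mode="modern") == []


def test_query_with_n_never_matches(simple_refs):
    query = simple_refs.sequences["ref1"][0:20]
    query = "N" + query[1:]
    assert match(query, simple_refs, mode="ancient") == []


def _random_refsets(rng, n_refs, ref_len):
    bases = np.array(list("ACGT"))
    sets = []
    for cls, count in (("mirna", n_refs // 2), ("rrna", n_refs - n_refs // 2)):
        seqs = {
            f"{cls}{i}": "".join(rng.choice(bases, ref_len)) for i in range(count)
        }
        sets.append(ReferenceSet(cls, seqs))
    return sets


@pytest.mark.parametrize("mode", ["ancient", "modern"])
def test_matches_brute_force_oracle_on_random_instances(mode):
    rng = np.random.default_rng(42)
    refsets = _random_refsets(rng, 12, 60)
    index = ReferenceIndex(refsets)
    bases = np.array(list("ACGT"))
    n_checked = 0
    for _ in range(120):
        if rng.random() < 0.5:
            # planted query: a (possibly damaged) fragment of a reference
            refset = refsets[int(rng.integers(len(refsets)))]
            name = list(refset.sequences)[int(rng.integers(len(refset)))]
            seq = refset.sequences[name]
            L = int(rng.integers(18, 26))
            start = int(rng.integers(0, len(seq) - L + 1))
            q = seq[start : start + L]
            if rng.random() < 0.5:
                q = reverse_complement(q)
            if rng.random() < 0.5:
                i = int(rng.integers(L))
                q = q[:i] + str(rng.choice(bases)) + q[i + 1 :]
        else:
            q = "".join(rng.choice(bases, int(rng.integers(18, 26))))
        assert index.match(q, mode=mode) == brute_force_match(q, refsets, mode)
        n_checked += 1
    assert n_checked == 120


def test_strand_symmetry():
    rng = np.random.default_rng(3)
    refsets = _random_refsets(rng, 6, 80)
    index = ReferenceIndex(refsets)
    bases = np.array(list("ACGT"))
    for _ in range(40):
        q = "".join(rng.choice(bases, 20))
        direct = index.match(q, mode="modern")
        flipped = index.match(reverse_complement(q), mode="modern")
        # matching the reverse complement mirrors every hit's strand
        assert {(h.reference_name, h.position, h.strand) for h in direct} == {
            (h.reference_name, h.position, "+" if h.strand == "-" else "-")
            for h in flipped
        }


def test_modern_results_subset_of_ancient(simple_refs):
    rng = np.random.default_rng(5)
    index = ReferenceIndex([simple_refs])
    bases = np.array(list("ACGT"))
    for _ in range(50):
        q = "".join(rng.choice(bases, 19))
        modern = set(map(repr, index.match(q, mode="modern")))
        ancient = set(map(repr, index.match(q, mode="ancient")))
        assert modern <= ancient


def _mk(cls, mm, name="r", pos=0):
    return MatchResult("A" * 20, name, cls, "+", pos, mm, True)


def test_assign_best_prefers_fewer_mismatches():
    best = assign_best("q", [_mk("rrna", 0), _mk("mirna", 1)])
    assert best.reference_class == "rrna"


def test_assign_best_uses_class_priority_among_equals():
    best = assign_best(
        "q", [_mk("mrna", 0), _mk("rrna", 0)],
        class_priority=("mirna", "rrna", "mrna", "retro"),
    )
    assert best.reference_class == "rrna"


def test_assign_best_empty_is_unassigned():
    assert assign_best("q", []) is None
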