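"""Per-sample composition profiles, miRNA family counts, target fragments.

Counts aggregate read *frequencies* (a dereplicated sequence observed 40
times contributes 40), matching read-level reporting; unique-sequence
counts are carried alongside as a secondary column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .references import CLASS_PRIORITY

#: classes reported in a composition profile, in display order
COMPOSITION_CLASSES: tuple[str, ...] = tuple(CLASS_PRIORITY) + ("unassigned",)


@dataclass
class CompositionProfile:
    """Per-class read counts for one sample's small-RNA fraction."""

    sample_id: str
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    def fractions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {cls: 0.0 for cls in self.class_counts}
        return {cls: n / total for cls, n in self.class_counts.items()}


@dataclass
class ExpressionProfile:
    """miRNA family counts for one sample.

    ``normalized`` stays empty until the statistics stage fills it in.
    ``total_reads`` is the library's total read count (pre size filter),
    the denominator of the per-sample miRNA-to-reads ratio.
    """

    sample_id: str
    raw: dict[str, float] = field(default_factory=dict)
    normalized: dict[str, float] = field(default_factory=dict)
    total_reads: int = 0

    @property
    def total_mirna(self) -> float:
        return sum(self.raw.values())


def build_profiles(
    assignments: Mapping[str, pd.DataFrame],
    family_map: Mapping[str, str],
    total_reads: Mapping[str, int] | None = None,
) -> tuple[dict[str, CompositionProfile], dict[str, ExpressionProfile]]:
    """Aggregate per-sample assignment tables into profiles.

    Parameters
    ----------
    assignments:
        sample_id -> table with columns (sequence, frequency,
        assigned_class, reference), as produced by
        :func:`paleosrna.damage_match.assign_table`.
    family_map:
        miRNA reference name -> family name; every reference a read was
        assigned to in class ``mirna`` must be present.
    total_reads:
        optional sample_id -> total library reads, stored on the
        expression profiles for normalization.
    """
    compositions: dict[str, CompositionProfile] = {}
    expressions: dict[str, ExpressionProfile] = {}
    for sample_id, table in assignments.items():
        counts = {cls: 0 for cls in COMPOSITION_CLASSES}
        families: dict[str, float] = {}
        for rec in table.itertuples(index=False):
            cls = rec.assigned_class
            counts[cls] = counts.get(cls, 0) + int(rec.frequency)
            if cls == "mirna":
                if rec.reference not in family_map:
                    raise KeyError(
                        f"miRNA reference {rec.reference!r} has no family mapping"
                    )
                fam = family_map[rec.reference]
                families[fam] = families.get(fam, 0) + int(rec.frequency)
        compositions[sample_id] = CompositionProfile(sample_id, counts)
        expressions[sample_id] = ExpressionProfile(
            sample_id,
            raw=dict(sorted(families.items())),
            total_reads=(total_reads or {}).get(sample_id, 0),
        )
    return compositions, expressions


def retro_proportions(
    profile: CompositionProfile,
) -> tuple[float | None, float | None]:
    """Retroelement read share vs all sRNA and vs messenger RNA only.

    The second proportion excludes rRNA and tRNA from the denominator
    (retro / (mRNA + retro)); an empty denominator yields None.
    """
    retro = profile.class_counts.get("retro", 0)
    total = profile.total
    mrna = profile.class_counts.get("mrna", 0)
    vs_all = retro / total if total > 0 else None
    denom = mrna + retro
    vs_mrna = retro / denom if denom > 0 else None
    return vs_all, vs_mrna


def mean_frequency(
    counts: Sequence[float], ddof: int = 0
) -> tuple[float, float]:
    """Arithmetic mean and standard deviation of per-sample counts.

    ``ddof=0`` (population convention) by default; pass ``ddof=1`` for the
    sample convention.
    """
    if len(counts) == 0:
        raise ValueError("mean_frequency requires a non-empty list")
    n = len(counts)
    mean = sum(counts) / n
    if n - ddof <= 0:
        return mean, float("nan")
    var = sum((c - mean) ** 2 for c in counts) / (n - ddof)
    return mean, math.sqrt(var)


def target_fragment_counts(
    assignments: Mapping[str, pd.DataFrame],
    targets: Iterable[str],
    control_ids: Sequence[str],
    ancient_id: str,
    depth_correction: float = 1.0,
    known_references: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-sample fragment counts for named target transcripts.

    Targets (e.g. the GAMYB and PCF transcription-factor messengers
    silenced by miR159/miR319) are mRNA references matched by name.  The
    control-side correction is the arithmetic mean of matching fragments
    across all controls; the modern/ancient sequencing-depth correction
    factor multiplies the ancient counts and is an explicit input.

    Returns a table indexed by target with per-sample columns plus
    ``control_mean`` and ``ancient_corrected``.
    """
    targets = list(targets)
    sample_ids = list(control_ids) + [ancient_id]
    if known_references is not None:
        known = set(known_references)
        missing = [t for t in targets if t not in known]
        if missing:
            raise KeyError(f"target reference(s) absent from reference set: {missing}")
    data = {}
    for sid in sample_ids:
        table = assignments[sid]
        per_target = (
            table[table["reference"].isin(targets)]
            .groupby("reference")["frequency"]
            .sum()
        )
        data[sid] = [int(per_target.get(t, 0)) for t in targets]
    out = pd.DataFrame(data, index=pd.Index(targets, name="target"))
    out["control_mean"] = out[list(control_ids)].mean(axis=1)
    out["ancient_corrected"] = out[ancient_id] * depth_correction
    return out
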