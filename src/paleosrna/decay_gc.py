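"""RNA half-life estimation and GC-content survival analysis.

Half-life follows first-order decay estimated from per-seed nucleic-acid
mass: T½ = T·log2 / log(V1/V2), with T the elapsed time in years, V1 the
modern and V2 the ancient mass per seed (µg).  The ratio of a reference
DNA half-life to the RNA half-life expresses how much faster RNA decays.

GC analysis bins sequence GC% into 0.1-point bins; each miRNA's "GC
location" is the bin holding the plurality of its observed sequence
frequency (ties break toward the lower bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import profile_regression

BIN_WIDTH = 0.1


@dataclass(frozen=True)
class DecayInput:
    """Elapsed time (years) and modern/ancient per-seed mass (µg)."""

    elapsed_years: float
    modern_mass: float
    ancient_mass: float

    def __post_init__(self) -> None:
        if self.elapsed_years <= 0:
            raise ValueError("elapsed time must be positive")
        if self.ancient_mass <= 0 or self.modern_mass <= 0:
            raise ValueError("masses must be positive")
        if self.modern_mass <= self.ancient_mass:
            raise ValueError(
                "modern mass must exceed ancient mass (no decay signal otherwise)"
            )


def half_life(decay: DecayInput) -> float:
    """T½ = T·log(2) / log(V1/V2), base-independent."""
    return (
        decay.elapsed_years
        * math.log(2.0)
        / math.log(decay.modern_mass / decay.ancient_mass)
    )


def degradation_fold(dna_half_life: float, rna_half_life: float) -> float:
    """How many times faster RNA decays than DNA (= T½_DNA / T½_RNA)."""
    if dna_half_life <= 0 or rna_half_life <= 0:
        raise ValueError("half-lives must be positive")
    return dna_half_life / rna_half_life


def gc_content(sequence: str) -> float:
    """GC percentage; U counts with A/T, N bases are excluded entirely."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    counted = [b for b in seq if b in "ACGT"]
    if not counted:
        raise ValueError("sequence contains no unambiguous bases")
    gc = sum(b in "GC" for b in counted)
    return 100.0 * gc / len(counted)


def gc_bin(gc_percent: float) -> float:
    """Lower edge of the half-open 0.1-point bin containing ``gc_percent``.

    Bins are [k·0.1, (k+1)·0.1); 100.0 exactly is assigned to the top bin
    [99.9, 100.0].
    """
    if not 0.0 <= gc_percent <= 100.0:
        raise ValueError("GC percentage must lie in [0, 100]")
    # 1e-7 guard absorbs float representation error at bin edges
    k = min(int(math.floor(gc_percent * 10.0 + 1e-7)), 999)
    return round(k * BIN_WIDTH, 1)


@dataclass
class GCBinTable:
    """Binned GC distribution with per-miRNA GC locations."""

    bins: pd.DataFrame  # columns: bin, frequency
    locations: dict[str, float]  # miRNA family -> GC-location bin edge
    total_frequency: int


def gc_binning(
    sequences: pd.DataFrame, family_column: str | None = "family"
) -> GCBinTable:
    """Bin sequences (columns: sequence, frequency[, family]) by GC%.

    Per-family "GC location" = the bin containing the plurality of that
    family's sequence frequency, ties toward the lower bin.  Omitted when
    no family column is present.
    """
    work = sequences.copy()
    work["gc"] = work["sequence"].map(gc_content)
    work["bin"] = work["gc"].map(gc_bin)
    bins = (
        work.groupby("bin")["frequency"].sum().reset_index().sort_values("bin")
    ).reset_index(drop=True)
    locations: dict[str, float] = {}
    if family_column and family_column in work.columns:
        for fam, group in work.groupby(family_column):
            per_bin = group.groupby("bin")["frequency"].sum()
            top = per_bin.max()
            locations[str(fam)] = float(min(per_bin[per_bin == top].index))
    return GCBinTable(
        bins=bins,
        locations=locations,
        total_frequency=int(work["frequency"].sum()),
    )


def gc_expression_correlation(
    gc_values: Sequence[float], expression: Sequence[float]
) -> float | None:
    """Squared Pearson correlation of GC% vs relative expression.

    Returns None (flagged undefined) when either vector has zero
    variance.
    """
    fit = profile_regression(np.asarray(gc_values), np.asarray(expression))
    return None if fit.degenerate else fit.r_squared


def mean_gc(
    sequences: pd.DataFrame,
) -> float:
    """Frequency-weighted mean GC% of a dereplicated sequence table."""
    gc = sequences["sequence"].map(gc_content)
    w = sequences["frequency"].astype(float)
    return float((gc * w).sum() / w.sum())


def half_life_range(
    elapsed_bounds: tuple[float, float],
    modern_mass: float,
    ancient_mass: float,
    dna_half_life: float | None = None,
) -> dict:
    """Half-life (and optional degradation fold) at two dating bounds."""
    t_lo, t_hi = sorted(elapsed_bounds)
    hl_lo = half_life(DecayInput(t_lo, modern_mass, ancient_mass))
    hl_hi = half_life(DecayInput(t_hi, modern_mass, ancient_mass))
    out = {"half_life_years": (hl_lo, hl_hi)}
    if dna_half_life is not None:
        out["degradation_fold"] = (
            degradation_fold(dna_half_life, hl_hi),
            degradation_fold(dna_half_life, hl_lo),
        )
    return out
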