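"""Count normalization and extended-Poisson differential assessment.

Libraries of very different depth are made comparable in two steps.
Control samples are first scaled by their miRNA-to-total-reads ratio:

    normalized_f = f / (total_miRNA_s / total_reads_s) * mean_ratio

where ``mean_ratio`` is the arithmetic mean of the per-sample ratios; this
leaves the cross-sample mean of per-sample miRNA totals unchanged.  The
deeply sequenced ancient library is then brought onto the control scale by
an adjustment ratio: mean adjusted control total / ancient miRNA total.

Differential assessment treats each (adjusted) count x as an observation
from a count process with mean λ and variance r·λ, r >= 1 absorbing
overdispersion.  For low counts (x < 50) the likelihood of λ is the exact
Poisson form λ^x e^{-λ}/Γ(x+1); for larger counts a Normal approximation
with variance r·λ is used.  Curves are normalized over a λ grid (flat
prior), and two counts are called up/down when their central 95% λ
intervals are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, special, stats as sps

from .classify import ExpressionProfile

#: counts below this use the exact Poisson likelihood; at or above it the
#: Normal approximation of the extended process (variance r·λ) is used
POISSON_CUTOFF = 50.0

#: coverage of the central λ interval used for up/down calls
INTERVAL_LEVEL = 0.95


@dataclass
class NormalizationConstants:
    """Scaling constants tying control and ancient libraries together."""

    per_sample_ratio: dict[str, float]
    mean_ratio: float
    mean_adjusted_control_total: float
    adjustment_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "per_sample_ratio": dict(self.per_sample_ratio),
            "mean_ratio": self.mean_ratio,
            "mean_adjusted_control_total": self.mean_adjusted_control_total,
            "adjustment_ratio": self.adjustment_ratio,
        }


def normalize_controls(
    profiles: Sequence[ExpressionProfile],
) -> tuple[list[ExpressionProfile], NormalizationConstants]:
    """Depth-normalize control profiles; fills their ``normalized`` maps."""
    if len(profiles) < 2:
        raise ValueError("need at least two control profiles")
    ratios: dict[str, float] = {}
    for prof in profiles:
        if prof.total_reads <= 0:
            raise ValueError(f"sample {prof.sample_id!r} has zero total reads")
        if prof.total_mirna <= 0:
            raise ValueError(f"sample {prof.sample_id!r} has zero miRNA total")
        ratios[prof.sample_id] = prof.total_mirna / prof.total_reads
    mean_ratio = sum(ratios.values()) / len(ratios)
    adjusted_totals = []
    for prof in profiles:
        scale = mean_ratio / ratios[prof.sample_id]
        prof.normalized = {fam: f * scale for fam, f in prof.raw.items()}
        adjusted_totals.append(sum(prof.normalized.values()))
    constants = NormalizationConstants(
        per_sample_ratio=ratios,
        mean_ratio=mean_ratio,
        mean_adjusted_control_total=sum(adjusted_totals) / len(adjusted_totals),
    )
    return list(profiles), constants


def adjust_ancient(
    ancient: ExpressionProfile, constants: NormalizationConstants
) -> ExpressionProfile:
    """Scale the ancient profile onto the control scale.

    adjustment_ratio = mean adjusted control total / ancient miRNA total;
    after scaling, the ancient totals sum exactly to the mean adjusted
    control total.
    """
    total = ancient.total_mirna
    if total <= 0:
        raise ValueError(f"ancient sample {ancient.sample_id!r} has zero miRNA total")
    ratio = constants.mean_adjusted_control_total / total
    constants.adjustment_ratio = ratio
    ancient.normalized = {fam: f * ratio for fam, f in ancient.raw.items()}
    return ancient


@dataclass
class RegressionResult:
    r_squared: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    degenerate: bool = False


def profile_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """OLS of y on x; R² is the squared Pearson correlation.

    Two-sided p from the t distribution on n-2 degrees of freedom.  Zero
    variance in either vector flags the result degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RegressionResult(None, None, None, None, degenerate=True)
    fit = sps.linregress(x, y)
    return RegressionResult(
        r_squared=fit.rvalue**2,
        p_value=fit.pvalue,
        slope=fit.slope,
        intercept=fit.intercept,
    )


def estimate_r(
    normalized_counts: Mapping[str, Sequence[float]], ddof: int = 1
) -> float:
    """Average variance-to-mean ratio across miRNA families.

    Each family contributes variance_f / mean_f computed over control
    samples; families with zero mean are excluded.  Sample variance
    (ddof=1) by default.
    """
    ratios = []
    for fam, counts in normalized_counts.items():
        arr = np.asarray(list(counts), dtype=float)
        if len(arr) < 2:
            raise ValueError(f"family {fam!r} needs counts from >= 2 samples")
        mean = arr.mean()
        if mean == 0:
            continue
        ratios.append(arr.var(ddof=ddof) / mean)
    if not ratios:
        raise ValueError("all families have zero mean; r undefined")
    return float(np.mean(ratios))


@dataclass
class LikelihoodCurve:
    """Gridded relative likelihood of the mean count λ given a count x."""

    grid: np.ndarray
    values: np.ndarray
    observed: float
    r: float
    kind: str  # 'poisson' | 'extended'

    def interval(self, level: float = INTERVAL_LEVEL) -> tuple[float, float]:
        """Central ``level`` interval of λ under the normalized curve."""
        cdf = integrate.cumulative_trapezoid(self.values, self.grid, initial=0.0)
        cdf /= cdf[-1]
        lo = (1.0 - level) / 2.0
        hi = 1.0 - lo
        return (
            float(np.interp(lo, cdf, self.grid)),
            float(np.interp(hi, cdf, self.grid)),
        )

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])


def default_grid(x: float, n_points: int = 2001) -> np.ndarray:
    """λ grid spanning [max(1e-3, x/10), 10·max(x, 1)]."""
    lo = max(1e-3, x / 10.0)
    hi = 10.0 * max(x, 1.0)
    return np.linspace(lo, hi, n_points)


def likelihood_kernel(
    x: float,
    r: float = 1.0,
    grid: np.ndarray | None = None,
) -> LikelihoodCurve:
    """Relative likelihood of λ for an observed (normalized) count x.

    x < 50: exact Poisson form, generalized to non-integer counts via the
    gamma function.  x >= 50: Normal approximation with variance r·λ.
    The returned curve is normalized to integrate to 1 over the grid
    (trapezoid rule).
    """
    if x < 0:
        raise ValueError("observed count must be non-negative")
    if r <= 0:
        raise ValueError("variance-to-mean ratio r must be positive")
    if grid is None:
        grid = default_grid(x)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("λ grid must be strictly positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("λ grid must be strictly increasing")
    if x < POISSON_CUTOFF:
        kind = "poisson"
        log_values = x * np.log(grid) - grid - special.gammaln(x + 1.0)
    else:
        kind = "extended"
        var = r * grid
        log_values = -0.5 * np.log(2.0 * np.pi * var) - (x - grid) ** 2 / (2.0 * var)
    log_values -= log_values.max()
    values = np.exp(log_values)
    area = np.trapezoid(values, grid)
    values /= area
    return LikelihoodCurve(grid=grid, values=values, observed=x, r=r, kind=kind)


@dataclass
class ComparisonCall:
    """Outcome of comparing an ancient count with the control mean."""

    family: str | None
    call: str  # 'up' | 'down' | 'indistinguishable'
    ancient_interval: tuple[float, float]
    control_interval: tuple[float, float]
    ancient_count: float
    control_mean: float


def compare_counts(
    x_ancient: float,
    x_controls: Sequence[float],
    r: float,
    family: str | None = None,
    level: float = INTERVAL_LEVEL,
) -> ComparisonCall:
    """Call up/down/indistinguishable from central λ intervals.

    Kernels are built for the ancient count and for the control mean
    count; "up"/"down" when the two central ``level`` intervals are
    disjoint, "indistinguishable" otherwise.
    """
    control_mean = float(np.mean(x_controls))
    a_curve = likelihood_kernel(x_ancient, r)
    c_curve = likelihood_kernel(control_mean, r)
    a_lo, a_hi = a_curve.interval(level)
    c_lo, c_hi = c_curve.interval(level)
    if a_lo > c_hi:
        call = "up"
    elif a_hi < c_lo:
        call = "down"
    else:
        call = "indistinguishable"
    return ComparisonCall(
        family=family,
        call=call,
        ancient_interval=(a_lo, a_hi),
        control_interval=(c_lo, c_hi),
        ancient_count=x_ancient,
        control_mean=control_mean,
    )


def differential_calls(
    ancient: ExpressionProfile,
    controls: Sequence[ExpressionProfile],
    r: float,
    level: float = INTERVAL_LEVEL,
) -> list[ComparisonCall]:
    """Compare every family present in ancient or controls.

    Uses the ``normalized`` maps (fill them first); families absent from
    a sample count as 0.
    """
    families = sorted(
        set(ancient.normalized) | {f for c in controls for f in c.normalized}
    )
    calls = []
    for fam in families:
        x_a = ancient.normalized.get(fam, 0.0)
        x_c = [c.normalized.get(fam, 0.0) for c in controls]
        calls.append(compare_counts(x_a, x_c, r, family=fam, level=level))
    return calls
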