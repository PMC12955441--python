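"""Assay validation statistics: linearity, precision, yield and purity checks.

These are the bench-validation computations run on estimate tables:
dilution-series log-log linearity (Pearson), per-level coefficients of
variation between technical replicates, DNase percent-reduction of
genomic DNA carryover, RNA-yield slope consistency across pool sizes,
A260/A280 purity improvement, and positive/negative amplitude separation
used to rank annealing temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .droplets import DropletReaction
from .normalize import RNASample
from .quantify import ChannelThresholds, classify_droplets


@dataclass
class DilutionSeriesResult:
    """Linearity and precision summary of one serial dilution series.

    The Pearson statistic is computed on log10(copies) versus
    log10(nominal fraction): a 1:5 series spans several orders of
    magnitude, and on the raw scale the correlation would be dominated by
    the top level.  The raw-scale least-squares slope (copies per unit
    nominal fraction) is reported alongside for transparency.
    """

    target_name: str
    base_factor: int
    levels: List[Tuple[int, List[float]]]
    pearson_r2_log: float
    pearson_p_log: float
    slope_raw: float
    cv_by_level: Dict[int, Optional[float]]
    excluded_levels: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if not (0.0 <= self.pearson_r2_log <= 1.0 + 1e-12):
            raise ValueError("r^2 must lie in [0, 1]")


def percent_reduction(pre_copies: float, post_copies: float) -> float:
    """Percent reduction 100·(pre − post)/pre, to two decimals.

    Used to audit DNase digestion of genomic DNA carryover (pre = copies
    without treatment, post = copies after treatment).
    """
    if pre_copies <= 0:
        raise ValueError("pre_copies must be positive")
    if post_copies < 0:
        raise ValueError("post_copies must be non-negative")
    return round(100.0 * (pre_copies - post_copies) / pre_copies, 2)


def replicate_cv(estimates: Sequence[float]) -> Optional[float]:
    """Coefficient of variation between technical replicates, in percent.

    Sample SD (n−1 denominator) over the mean, × 100.  Returns ``None``
    (undefined) when the mean is zero.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two replicate estimates")
    arr = np.asarray(estimates, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return float(100.0 * arr.std(ddof=1) / mean)


def dilution_linearity(
    levels: Sequence[Tuple[int, Sequence[float]]],
    base_factor: int,
    target_name: str = "target",
) -> DilutionSeriesResult:
    """Linearity of measured copies against the nominal dilution fraction.

    ``levels`` is a list of ``(exponent, replicate estimates)``.  Levels
    containing any zero estimate are excluded from the log-log fit (a log
    of zero is undefined) and reported in ``excluded_levels``.  Per-level
    CVs are computed for every level with ≥ 2 replicates.
    """
    if base_factor < 2:
        raise ValueError("base_factor must be >= 2")
    levels = [(int(k), list(map(float, reps))) for k, reps in levels]
    usable = [(k, reps) for k, reps in levels if reps and all(v > 0 for v in reps)]
    excluded = [k for k, reps in levels if not reps or any(v <= 0 for v in reps)]
    if len(usable) < 3:
        raise ValueError("need at least 3 dilution levels with all-positive estimates")

    x = np.concatenate([[k * math.log10(base_factor)] * len(reps) for k, reps in usable])
    y = np.log10(np.concatenate([reps for _, reps in usable]))
    r, p = stats.pearsonr(x, y)

    frac = np.concatenate([[float(base_factor) ** k] * len(reps) for k, reps in levels])
    copies = np.concatenate([reps for _, reps in levels])
    slope_raw = float(np.polyfit(frac, copies, 1)[0]) if len(levels) > 1 else math.nan

    cv_by_level = {
        k: (replicate_cv(reps) if len(reps) >= 2 else None) for k, reps in levels
    }
    return DilutionSeriesResult(
        target_name=target_name,
        base_factor=base_factor,
        levels=levels,
        pearson_r2_log=float(r**2),
        pearson_p_log=float(p),
        slope_raw=slope_raw,
        cv_by_level=cv_by_level,
        excluded_levels=excluded,
    )


@dataclass
class YieldSlopeResult:
    """RNA-yield slope versus the expected per-pair yield."""

    fitted_slope: float
    expected_slope: float
    p_value: float
    zero_variance: bool = False


def yield_slope_test(samples: Sequence[RNASample]) -> YieldSlopeResult:
    """Is total RNA concentration proportional to the number of testis pairs?

    Fits the least-squares slope of concentration on pair count, takes the
    mean per-pair yield as the expected slope, and runs a one-sample
    t-test of the per-sample contributions (conc_i / pairs_i) against the
    fitted slope.  Identical per-pair yields give zero variance; the test
    is then flagged and p reported as 1.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    pairs = np.array([s.n_testis_pairs for s in samples], dtype=float)
    conc = np.array([s.conc_ng_per_ul for s in samples], dtype=float)
    if np.unique(pairs).size < 2:
        raise ValueError("samples must span at least two distinct pair counts")
    fitted_slope = float(np.polyfit(pairs, conc, 1)[0])
    per_pair = conc / pairs
    expected = float(per_pair.mean())
    if per_pair.std(ddof=1) == 0:
        return YieldSlopeResult(fitted_slope, expected, p_value=1.0, zero_variance=True)
    t = stats.ttest_1samp(per_pair, fitted_slope)
    return YieldSlopeResult(fitted_slope, expected, p_value=float(t.pvalue))


@dataclass
class PairedShiftResult:
    """Paired comparison of a purity ratio before/after a protocol step."""

    mean_before: float
    mean_after: float
    p_value: float
    improved: bool
    zero_variance: bool = False


def purity_improvement(
    before_after_pairs: Sequence[Tuple[float, float]]
) -> PairedShiftResult:
    """Paired t-test of purity ratios (e.g. A260/A280) before vs after.

    Means are reported to two decimals.  Identical pairs give zero
    variance of the differences; p is then flagged as 1.
    """
    if len(before_after_pairs) < 2:
        raise ValueError("need at least two pairs")
    before = np.array([b for b, _ in before_after_pairs], dtype=float)
    after = np.array([a for _, a in before_after_pairs], dtype=float)
    if before.size != after.size:
        raise ValueError("mismatched lengths")
    diff = after - before
    mean_b, mean_a = round(float(before.mean()), 2), round(float(after.mean()), 2)
    if diff.std(ddof=1) == 0:
        return PairedShiftResult(mean_b, mean_a, p_value=1.0, improved=bool(diff.mean() > 0), zero_variance=True)
    t = stats.ttest_rel(after, before)
    return PairedShiftResult(mean_b, mean_a, p_value=float(t.pvalue), improved=bool(diff.mean() > 0))


def amplitude_separation(
    reaction: DropletReaction, thresholds: ChannelThresholds
) -> Dict[str, Optional[float]]:
    """Positive-minus-negative mean amplitude per channel.

    The criterion for ranking annealing temperatures: larger separation
    means more robust droplet discrimination.  A channel with an empty
    positive or negative class yields ``None`` (undefined).
    """
    classified = classify_droplets(reaction, thresholds)
    fam_pos = np.isin(classified.labels, (1, 3))
    hex_pos = np.isin(classified.labels, (2, 3))
    out: Dict[str, Optional[float]] = {}
    for name, amp, pos in (
        ("FAM", reaction.fam_amplitudes, fam_pos),
        ("HEX", reaction.hex_amplitudes, hex_pos),
    ):
        if pos.any() and (~pos).any():
            out[name] = float(amp[pos].mean() - amp[~pos].mean())
        else:
            out[name] = None
    return out
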