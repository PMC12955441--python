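"""Spike-in and reference-gene normalization of raw ddPCR copy counts.

Two complementary strategies:

* **Spike-in (technical) normalization** — a fixed amount of synthetic RNA
  is added to every sample before extraction.  Its measured recovery
  estimates the sample-processing efficiency; dividing raw target counts
  by that efficiency compensates proportional losses incurred during
  purification, DNase treatment and reverse transcription.
* **Reference-gene (biological) normalization** — target counts are
  expressed as a ratio to a stably expressed endogenous gene
  (β-Spectrin), controlling for input material and transcriptional
  activity.

Per-input-unit bookkeeping (RNA yield per testis pair, nominal tissue
equivalents of a dilution level) lives here too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

from .quantify import ConcentrationEstimate


@dataclass
class RNASample:
    """Metadata for one RNA extraction."""

    sample_id: str
    n_testis_pairs: int
    conc_ng_per_ul: float
    elution_volume_ul: float = 25.0
    a260_280: Optional[float] = None
    a260_230: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_testis_pairs < 1:
            raise ValueError("n_testis_pairs must be >= 1")
        if self.conc_ng_per_ul < 0 or self.elution_volume_ul < 0:
            raise ValueError("concentration and volume must be non-negative")


@dataclass
class NormalizedResult:
    """Raw and normalized copy counts for one target in one sample."""

    target_name: str
    raw_copies_per_reaction: float
    efficiency: Optional[float] = None
    corrected_copies_per_reaction: Optional[float] = None
    corrected_ci_low: Optional[float] = None
    corrected_ci_high: Optional[float] = None
    reference_ratio: Optional[float] = None
    copies_per_testis_pair: Optional[float] = None


def spike_recovery(measured_spike: float, expected_spike: float) -> float:
    """Processing efficiency = measured / expected spike-in copies.

    Values above 1 are possible when the expected-input calibration is
    off; they are allowed but produce a warning.
    """
    if expected_spike <= 0:
        raise ValueError("expected_spike must be positive")
    if measured_spike < 0:
        raise ValueError("measured_spike must be non-negative")
    efficiency = measured_spike / expected_spike
    if efficiency > 1:
        warnings.warn(
            f"spike recovery {efficiency:.3f} exceeds 1; expected-input calibration suspect",
            stacklevel=2,
        )
    return efficiency


def correct_by_efficiency(raw_copies: float, efficiency: float) -> float:
    """Compensate processing loss: corrected = raw / efficiency.

    An efficiency of 0.5 means half the molecules survived processing, so
    the pre-loss count is twice the measured one.
    """
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    return raw_copies / efficiency


def _se_from_ci(est: ConcentrationEstimate) -> float:
    return (est.ci95_high - est.ci95_low) / (2 * 1.96)


def efficiency_corrected_estimate(
    target: ConcentrationEstimate,
    spike: ConcentrationEstimate,
    expected_spike_copies_per_reaction: float,
) -> NormalizedResult:
    """Spike-corrected target count with a delta-method 95% CI.

    corrected = target × expected_spike / measured_spike.  The relative
    variances of the two independent estimates add:
    SE(corrected)² ≈ corrected² × (cv_target² + cv_spike²).
    """
    eff = spike_recovery(spike.copies_per_reaction, expected_spike_copies_per_reaction)
    if eff == 0:
        raise ValueError("measured spike is zero; processing efficiency undefined")
    corrected = correct_by_efficiency(target.copies_per_reaction, eff)
    cv2 = 0.0
    if target.copies_per_reaction > 0:
        cv2 += (_se_from_ci(target) / target.copies_per_reaction) ** 2
    if spike.copies_per_reaction > 0:
        cv2 += (_se_from_ci(spike) / spike.copies_per_reaction) ** 2
    se = corrected * math.sqrt(cv2)
    return NormalizedResult(
        target_name=target.target_name,
        raw_copies_per_reaction=target.copies_per_reaction,
        efficiency=eff,
        corrected_copies_per_reaction=corrected,
        corrected_ci_low=max(0.0, corrected - 1.96 * se),
        corrected_ci_high=corrected + 1.96 * se,
    )


@dataclass
class RatioResult:
    """Target/reference ratio with a delta-method 95% CI."""

    ratio: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    undefined: bool = False


def normalize_to_reference(
    target_copies: float,
    reference_copies: float,
    target_se: Optional[float] = None,
    reference_se: Optional[float] = None,
) -> RatioResult:
    """Ratio of target to reference-gene copies.

    A zero reference yields an undefined-result flag rather than a silent
    infinity.  When standard errors for both independent estimates are
    given, a delta-method CI is propagated:
    Var(ratio) ≈ ratio² (SE_t²/t² + SE_r²/r²).
    """
    if reference_copies < 0:
        raise ValueError("reference_copies must be non-negative")
    if reference_copies == 0:
        return RatioResult(ratio=None, undefined=True)
    ratio = target_copies / reference_copies
    if target_se is None or reference_se is None or target_copies == 0:
        return RatioResult(ratio=ratio)
    se = ratio * math.sqrt(
        (target_se / target_copies) ** 2 + (reference_se / reference_copies) ** 2
    )
    return RatioResult(ratio=ratio, ci_low=max(0.0, ratio - 1.96 * se), ci_high=ratio + 1.96 * se)


def per_unit_yield(sample: RNASample) -> Tuple[float, float]:
    """RNA yield bookkeeping: (ng/µL per testis pair, total ng eluted)."""
    per_pair = sample.conc_ng_per_ul / sample.n_testis_pairs
    total_ng = sample.conc_ng_per_ul * sample.elution_volume_ul
    return per_pair, total_ng


def equivalent_input(
    n_pairs_at_full_strength: int, dilution_base: int, exponent: int
) -> float:
    """Nominal tissue input of a dilution level, in testis-pair equivalents.

    A series built from material of ``n`` pairs diluted ``base**exponent``
    represents ``n × base**exponent`` pairs.
    """
    if dilution_base < 2:
        raise ValueError("dilution_base must be >= 2")
    if exponent > 0:
        raise ValueError("exponent must be non-positive")
    return n_pairs_at_full_strength * float(dilution_base) ** exponent
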