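"""Droplet classification, Poisson quantification, QC, and limits of detection.

The estimator is the standard digital PCR Poisson correction: with
``n_positive`` of ``n_total`` droplets positive for a target, the fraction
``p̂ = n_positive/n_total`` estimates ``1 − exp(−λ)`` where λ is the mean
number of template molecules per droplet, so

    λ̂ = −ln(1 − p̂),
    copies/µL = λ̂ / V_droplet(µL),
    copies/reaction = copies/µL × V_reaction(µL).

The correction accounts for droplets holding more than one molecule.  A
delta-method 95% CI on λ (SE = sqrt(p̂ / (n (1 − p̂)))) is used in the
bulk of the count range; at extreme counts (≤ 5 positives or ≤ 5
negatives) exact Clopper–Pearson binomial bounds on p̂ are transformed
through −ln(1 − p) instead.

The limit of detection is taken from no-template controls (NTCs): the
upper limit of the 95% confidence interval of the NTC concentration,
rounded up to a whole copy count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .droplets import DropletReaction

LABELS = ("negative", "fam_only", "hex_only", "double")

#: minimum droplet yield for a well to enter downstream analysis
DEFAULT_MIN_DROPLETS = 10_000


# ---------------------------------------------------------------------------
# thresholds and classification
# ---------------------------------------------------------------------------

@dataclass
class ChannelThresholds:
    """Per-channel amplitude cutoffs for positive/negative classification.

    ``crosstalk_alpha_hat`` is the estimated linear bleed of FAM signal
    into the HEX channel; HEX amplitudes are compensated by
    ``hex − alpha_hat × max(0, fam − fam_low_mean)`` before thresholding.

    ``hex_cutoff_fam_positive`` handles amplitude competition: when the
    two targets compete for reagents in double-positive droplets the
    HEX-positive cluster sits lower among FAM-positive droplets than among
    FAM-negative ones, so the HEX split is fitted separately within the
    two FAM populations.  ``None`` falls back to ``hex_cutoff``.
    """

    fam_cutoff: float
    hex_cutoff: float
    crosstalk_alpha_hat: float = 0.0
    fam_low_mean: float = 0.0
    hex_cutoff_fam_positive: Optional[float] = None


@dataclass
class ClassifiedDroplets:
    """Per-droplet cluster labels and the four class counts for one well."""

    labels: np.ndarray  # integer codes indexing LABELS
    n_total: int
    n_negative: int
    n_fam_only: int
    n_hex_only: int
    n_double: int
    thresholds: ChannelThresholds

    def __post_init__(self) -> None:
        if self.n_negative + self.n_fam_only + self.n_hex_only + self.n_double != self.n_total:
            raise ValueError("class counts must sum to n_total")

    @property
    def n_fam_positive(self) -> int:
        return self.n_fam_only + self.n_double

    @property
    def n_hex_positive(self) -> int:
        return self.n_hex_only + self.n_double

    def label_names(self) -> np.ndarray:
        return np.asarray(LABELS)[self.labels]


def _two_means(x: np.ndarray, max_iter: int = 100) -> Tuple[float, float, np.ndarray]:
    """Deterministic 1-D 2-means split.

    Centers are initialized at the 5th and 95th amplitude percentiles and
    refined by Lloyd iterations.  Returns (low_mean, high_mean, high_mask).
    """
    lo, hi = np.percentile(x, [5.0, 95.0])
    if hi <= lo:  # essentially constant data
        return float(lo), float(hi), np.zeros(x.size, dtype=bool)
    for _ in range(max_iter):
        boundary = 0.5 * (lo + hi)
        high = x > boundary
        if not high.any() or high.all():
            break
        new_lo, new_hi = float(x[~high].mean()), float(x[high].mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    high = x > 0.5 * (lo + hi)
    return lo, hi, high


def _split_channel(x: np.ndarray, min_separation_sd: float = 4.0) -> Tuple[float, float, bool]:
    """Two-cluster cutoff for one amplitude vector.

    Returns ``(cutoff, low_mean, is_single_cluster)``.  If the two cluster
    means differ by less than ``min_separation_sd`` pooled within-cluster
    SDs the channel is declared single-cluster (an all-negative well) and
    the cutoff is placed at mean + 5·SD so that no droplet is positive.
    """
    lo, hi, high = _two_means(x)
    n_high = int(high.sum())
    if 0 < n_high < x.size:
        var_lo = float(x[~high].var(ddof=1)) if (~high).sum() > 1 else 0.0
        var_hi = float(x[high].var(ddof=1)) if n_high > 1 else 0.0
        w_lo, w_hi = (~high).sum(), n_high
        pooled_sd = math.sqrt((w_lo * var_lo + w_hi * var_hi) / (w_lo + w_hi))
        if pooled_sd == 0 or (hi - lo) >= min_separation_sd * pooled_sd:
            return 0.5 * (lo + hi), lo, False
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    return mean + 5.0 * sd, mean, True


def fit_thresholds(reaction: DropletReaction) -> ChannelThresholds:
    """Fit per-channel cutoffs from the amplitude distributions of one well.

    FAM is split first (its clusters are unaffected by duplex artefacts).
    The FAM→HEX crosstalk coefficient is then estimated as the regression
    slope of HEX on FAM among FAM-positive/HEX-negative droplets (≥ 50
    droplets required, else 0), HEX amplitudes are compensated, and the
    HEX split is fitted separately within the FAM-negative and
    FAM-positive populations (see :class:`ChannelThresholds`).
    """
    if reaction.n_droplets < 100:
        raise ValueError("need at least 100 droplets to fit thresholds")
    fam = reaction.fam_amplitudes
    hex_amp = reaction.hex_amplitudes

    fam_cutoff, fam_low_mean, fam_single = _split_channel(fam)
    fam_pos = fam > fam_cutoff

    # crosstalk: slope of HEX on FAM among FAM-positive / HEX-negative droplets
    alpha_hat = 0.0
    if fam_pos.sum() >= 50:
        _, _, hex_high_prelim = _two_means(hex_amp[fam_pos])
        sub_fam = fam[fam_pos][~hex_high_prelim]
        sub_hex = hex_amp[fam_pos][~hex_high_prelim]
        if sub_fam.size >= 50 and sub_fam.std() > 0:
            slope = stats.linregress(sub_fam, sub_hex).slope
            alpha_hat = max(0.0, float(slope))

    hex_comp = hex_amp - alpha_hat * np.maximum(0.0, fam - fam_low_mean)

    fam_neg = ~fam_pos
    if fam_neg.sum() >= 100:
        hex_cutoff, _, _ = _split_channel(hex_comp[fam_neg])
    else:
        hex_cutoff, _, _ = _split_channel(hex_comp)

    hex_cutoff_fam_pos: Optional[float] = None
    if fam_pos.sum() >= 100:
        hex_cutoff_fam_pos, _, single = _split_channel(hex_comp[fam_pos])
        if single:
            # no HEX-positive cluster among FAM positives; keep the high
            # cutoff so those droplets classify as fam_only
            pass

    return ChannelThresholds(
        fam_cutoff=float(fam_cutoff),
        hex_cutoff=float(hex_cutoff),
        crosstalk_alpha_hat=alpha_hat,
        fam_low_mean=float(fam_low_mean),
        hex_cutoff_fam_positive=hex_cutoff_fam_pos,
    )


def classify_droplets(reaction: DropletReaction, thresholds: ChannelThresholds) -> ClassifiedDroplets:
    """Assign each droplet to {negative, fam_only, hex_only, double}.

    HEX amplitudes are crosstalk-compensated before the HEX cutoff is
    applied; FAM classification uses the raw amplitude and never depends
    on the HEX state.
    """
    fam = reaction.fam_amplitudes
    hex_amp = reaction.hex_amplitudes
    for cutoff, channel in ((thresholds.fam_cutoff, fam), (thresholds.hex_cutoff, hex_amp)):
        if not math.isfinite(cutoff):
            raise ValueError("threshold cutoffs must be finite")
        if channel.size and cutoff < channel.min():
            raise ValueError(
                "cutoff below the observed amplitude range would mark every droplet positive"
            )

    fam_pos = fam > thresholds.fam_cutoff
    hex_comp = hex_amp - thresholds.crosstalk_alpha_hat * np.maximum(0.0, fam - thresholds.fam_low_mean)
    hex_cut = np.where(
        fam_pos,
        thresholds.hex_cutoff_fam_positive
        if thresholds.hex_cutoff_fam_positive is not None
        else thresholds.hex_cutoff,
        thresholds.hex_cutoff,
    )
    hex_pos = hex_comp > hex_cut

    labels = np.zeros(reaction.n_droplets, dtype=np.int8)
    labels[fam_pos & ~hex_pos] = 1
    labels[~fam_pos & hex_pos] = 2
    labels[fam_pos & hex_pos] = 3
    counts = np.bincount(labels, minlength=4)
    return ClassifiedDroplets(
        labels=labels,
        n_total=reaction.n_droplets,
        n_negative=int(counts[0]),
        n_fam_only=int(counts[1]),
        n_hex_only=int(counts[2]),
        n_double=int(counts[3]),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Poisson quantification
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationEstimate:
    """Poisson-corrected concentration for one target in one well."""

    target_name: str
    n_droplets: int
    n_positive: int
    lambda_hat: float
    copies_per_ul: float
    copies_per_reaction: float
    ci95_low: float
    ci95_high: float
    qc_pass: bool = True
    saturated: bool = False
    reaction_volume_ul: float = 20.0
    droplet_volume_nl: float = 0.85
    well_id: Optional[str] = None
    assay_name: Optional[str] = None
    dilution_exponent: Optional[int] = None
    replicate_id: Optional[int] = None
    is_ntc: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_droplets):
            raise ValueError("n_positive must lie in [0, n_droplets]")
        if (self.lambda_hat == 0) != (self.n_positive == 0):
            raise ValueError("lambda_hat must be zero iff n_positive is zero")


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact binomial CI on a proportion (beta quantiles)."""
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def estimate_concentration(
    classified: ClassifiedDroplets,
    channel: str,
    reaction_volume_ul: float = 20.0,
    droplet_volume_nl: float = 0.85,
    *,
    target_name: Optional[str] = None,
    **metadata,
) -> ConcentrationEstimate:
    """Poisson-corrected concentration of one channel's target.

    Positives on FAM are ``fam_only + double``; on HEX, ``hex_only +
    double`` — double-positive droplets count toward both targets.  A
    fully positive well is flagged ``saturated`` (λ has no finite
    estimate); the lower CI bound is still reported from the exact
    binomial bound.
    """
    channel = channel.upper()
    if channel not in ("FAM", "HEX"):
        raise ValueError("channel must be 'FAM' or 'HEX'")
    n = classified.n_total
    if n == 0:
        raise ValueError("cannot estimate a concentration from zero droplets")
    k = classified.n_fam_positive if channel == "FAM" else classified.n_hex_positive

    vd_ul = droplet_volume_nl * 1e-3
    scale = reaction_volume_ul / vd_ul  # λ → copies/reaction

    def lam_of(p: float) -> float:
        return math.inf if p >= 1.0 else -math.log1p(-p)

    p_hat = k / n
    saturated = k == n

    if k <= 5 or (n - k) <= 5:
        p_lo, p_hi = _clopper_pearson(k, n)
        lam_lo, lam_hi = lam_of(p_lo), lam_of(p_hi)
    else:
        lam = lam_of(p_hat)
        se = math.sqrt(p_hat / (n * (1.0 - p_hat)))
        lam_lo, lam_hi = max(0.0, lam - 1.96 * se), lam + 1.96 * se

    lam_hat = lam_of(p_hat)
    copies_per_ul = lam_hat / vd_ul
    return ConcentrationEstimate(
        target_name=target_name or channel,
        n_droplets=n,
        n_positive=k,
        lambda_hat=lam_hat,
        copies_per_ul=copies_per_ul,
        copies_per_reaction=copies_per_ul * reaction_volume_ul,
        ci95_low=lam_lo * scale,
        ci95_high=lam_hi * scale,
        saturated=saturated,
        reaction_volume_ul=reaction_volume_ul,
        droplet_volume_nl=droplet_volume_nl,
        **metadata,
    )


def qc_reaction(reaction: DropletReaction, min_droplets: int = DEFAULT_MIN_DROPLETS) -> bool:
    """Well-level QC: pass iff the droplet yield is at least ``min_droplets``."""
    return reaction.n_droplets >= min_droplets


def quantify_reaction(
    reaction: DropletReaction,
    thresholds: Optional[ChannelThresholds] = None,
    *,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    fam_target: str = "FAM",
    hex_target: str = "HEX",
) -> List[ConcentrationEstimate]:
    """Threshold, classify and estimate both targets of one well.

    Convenience pipeline; wells failing the droplet-yield QC get
    ``qc_pass=False`` on both estimates (they are still computed).
    """
    if thresholds is None:
        thresholds = fit_thresholds(reaction)
    classified = classify_droplets(reaction, thresholds)
    passed = qc_reaction(reaction, min_droplets)
    meta = dict(
        well_id=reaction.well_id,
        assay_name=reaction.assay_name,
        dilution_exponent=reaction.dilution_exponent,
        replicate_id=reaction.replicate_id,
        is_ntc=reaction.is_ntc,
    )
    out = []
    for channel, name in (("FAM", fam_target), ("HEX", hex_target)):
        est = estimate_concentration(
            classified,
            channel,
            reaction.reaction_volume_ul,
            reaction.droplet_volume_nl,
            target_name=name,
            **meta,
        )
        est.qc_pass = passed
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# limit of detection
# ---------------------------------------------------------------------------

@dataclass
class LODResult:
    """Limit of detection derived from no-template controls.

    ``lod_copies_per_reaction`` is the upper 95% confidence limit of the
    NTC background concentration; ``lod_rounded_up`` is its ceiling, the
    whole-copy threshold below which a signal is indistinguishable from
    background.
    """

    target_name: str
    lod_copies_per_reaction: float
    lod_rounded_up: int
    n_ntc_reactions: int
    method_note: str

    def __post_init__(self) -> None:
        if self.lod_copies_per_reaction < 0:
            raise ValueError("LOD must be non-negative")
        if self.lod_rounded_up != math.ceil(self.lod_copies_per_reaction):
            raise ValueError("lod_rounded_up must be the ceiling of the continuous LOD")


def round_up_lod(lod_copies_per_reaction: float) -> int:
    """Round a continuous LOD up to whole copies per reaction."""
    if lod_copies_per_reaction < 0:
        raise ValueError("LOD must be non-negative")
    return math.ceil(lod_copies_per_reaction)


def _pooled_upper_bound(estimates: Sequence[ConcentrationEstimate]) -> float:
    """Clopper–Pearson upper bound on the pooled NTC droplet counts,
    converted to copies/reaction; strictly positive even at zero counts."""
    total_k = sum(e.n_positive for e in estimates)
    total_n = sum(e.n_droplets for e in estimates)
    _, p_hi = _clopper_pearson(total_k, total_n)
    lam_hi = -math.log1p(-p_hi)
    vd_ul = float(np.mean([e.droplet_volume_nl for e in estimates])) * 1e-3
    vr = float(np.mean([e.reaction_volume_ul for e in estimates]))
    return lam_hi / vd_ul * vr


def compute_lod(ntc_estimates: Sequence[ConcentrationEstimate]) -> LODResult:
    """Limit of detection from NTC concentration estimates.

    With ≥ 2 NTC wells the LOD is the upper limit of the two-sided 95%
    t-interval of copies/reaction across wells; with exactly one, that
    well's own CI upper bound.  When the across-well variance is zero
    (e.g. every NTC had zero positive droplets) the t-interval
    degenerates and the pooled exact binomial upper bound is used, which
    is never exactly zero.
    """
    if not ntc_estimates:
        raise ValueError("at least one NTC estimate is required")
    names = {e.target_name for e in ntc_estimates}
    if len(names) > 1:
        raise ValueError(f"mixed target names in NTC estimates: {sorted(names)}")
    if not all(e.qc_pass for e in ntc_estimates):
        raise ValueError("all NTC estimates must pass reaction QC")
    target = ntc_estimates[0].target_name
    n = len(ntc_estimates)

    if n == 1:
        lod = ntc_estimates[0].ci95_high
        note = "single NTC: upper 95% CI bound of the well's own estimate"
    else:
        values = np.array([e.copies_per_reaction for e in ntc_estimates])
        sd = float(values.std(ddof=1))
        if sd > 0:
            t = float(stats.t.ppf(0.975, n - 1))
            lod = float(values.mean()) + t * sd / math.sqrt(n)
            note = f"mean + t(0.975, {n - 1})*SD/sqrt(n) across {n} NTC wells"
        else:
            lod = _pooled_upper_bound(ntc_estimates)
            note = "degenerate across-well variance: pooled Clopper-Pearson upper bound"
    return LODResult(
        target_name=target,
        lod_copies_per_reaction=float(lod),
        lod_rounded_up=round_up_lod(float(lod)),
        n_ntc_reactions=n,
        method_note=note,
    )
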