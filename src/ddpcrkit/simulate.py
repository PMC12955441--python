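"""Droplet-level simulator for duplex digital PCR with known ground truth.

The generative model mirrors how a QX200-style instrument produces data:

1. The reaction mix at concentration ``c`` copies/µL is partitioned into
   ``n_droplets`` droplets of ``droplet_volume_nl`` nL each, so the number
   of template molecules per droplet is Poisson with mean
   ``λ = c × droplet_volume_nl × 1e-3``.  Occupancies of the two targets
   are independent.
2. Endpoint PCR saturates, so any droplet with occupancy ≥ 1 joins the
   positive amplitude cluster of its channel; amplitude does not depend on
   copy number within a droplet.
3. Amplitudes are Gaussian around cluster means.  Two duplex artefacts
   seen in real cif/spike assays are modelled:

   * *amplitude competition*: in double-positive droplets the two targets
     compete for reagents, depressing the HEX-positive amplitude; modelled
     by multiplying the HEX positive mean by ``competition_kappa`` ≤ 1.
   * *spectral crosstalk*: FAM fluorescence bleeds into the HEX detector;
     modelled by adding ``crosstalk_alpha × max(0, fam − fam_neg_mean)``
     to every droplet's HEX amplitude.

Both effects produce the intermediate HEX clusters observed in real
two-dimensional droplet plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .droplets import DropletReaction

#: fluorescence defaults follow the amplitude scales observed in cif/spike
#: duplex assays: FAM negatives ~700, FAM positives ~9,600, HEX negatives
#: ~1,030, HEX positives ~4,280 arbitrary units.  SDs default to 3% of the
#: respective mean.
_FAM_NEG = 702.0
_FAM_POS = 9603.0
_HEX_NEG = 1032.0
_HEX_POS = 4284.0


@dataclass(frozen=True)
class SimulationParams:
    """Tunable parameters of the droplet simulator.

    ``ntc_contamination_rate`` (copies/µL) models the trace environmental
    template that makes real no-template controls occasionally positive.
    ``rain_fraction`` replaces that fraction of droplets with uniform
    amplitudes between the cluster means ("rain") for threshold robustness
    testing; it defaults to 0 and is not part of the standard conditions.
    """

    n_droplets: int = 15_000
    droplet_volume_nl: float = 0.85
    fam_neg_mean: float = _FAM_NEG
    fam_neg_sd: float = 0.03 * _FAM_NEG
    fam_pos_mean: float = _FAM_POS
    fam_pos_sd: float = 0.03 * _FAM_POS
    hex_neg_mean: float = _HEX_NEG
    hex_neg_sd: float = 0.03 * _HEX_NEG
    hex_pos_mean: float = _HEX_POS
    hex_pos_sd: float = 0.03 * _HEX_POS
    crosstalk_alpha: float = 0.05
    competition_kappa: float = 0.5
    ntc_contamination_rate: float = 0.005
    rain_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")
        for name in ("fam_neg_sd", "fam_pos_sd", "hex_neg_sd", "hex_pos_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fam_pos_mean <= self.fam_neg_mean:
            raise ValueError("fam_pos_mean must exceed fam_neg_mean (cluster separability)")
        if self.hex_pos_mean <= self.hex_neg_mean:
            raise ValueError("hex_pos_mean must exceed hex_neg_mean (cluster separability)")
        if not (0.0 < self.competition_kappa <= 1.0):
            raise ValueError("competition_kappa must be in (0, 1]")
        if not (0.0 <= self.crosstalk_alpha < 1.0):
            raise ValueError("crosstalk_alpha must be in [0, 1)")
        if self.ntc_contamination_rate < 0:
            raise ValueError("ntc_contamination_rate must be non-negative")
        if not (0.0 <= self.rain_fraction < 1.0):
            raise ValueError("rain_fraction must be in [0, 1)")

    @property
    def droplet_volume_ul(self) -> float:
        return self.droplet_volume_nl * 1e-3


@dataclass(frozen=True)
class TrueConcentrations:
    """Ground-truth target concentrations (copies/µL) in the reaction mix."""

    fam_target_copies_per_ul: float
    hex_target_copies_per_ul: float

    def __post_init__(self) -> None:
        for v in (self.fam_target_copies_per_ul, self.hex_target_copies_per_ul):
            if not math.isfinite(v):
                raise ValueError("concentrations must be finite")
            if v < 0:
                raise ValueError("concentrations must be non-negative")

    def scaled(self, factor: float) -> "TrueConcentrations":
        return TrueConcentrations(
            self.fam_target_copies_per_ul * factor,
            self.hex_target_copies_per_ul * factor,
        )


def simulate_reaction(
    params: SimulationParams,
    truth: TrueConcentrations,
    *,
    well_id: str = "A01",
    assay_name: str = "duplex",
    reaction_volume_ul: float = 20.0,
    dilution_exponent: Optional[int] = None,
    replicate_id: Optional[int] = None,
    is_ntc: bool = False,
    annealing_temp_c: Optional[float] = None,
    seed: Optional[int] = None,
    return_occupancy: bool = False,
):
    """Simulate one well.

    Returns a :class:`DropletReaction`; with ``return_occupancy=True``
    additionally returns the per-droplet true occupancy counts
    ``(fam_occupancy, hex_occupancy)`` for oracle tests.
    Deterministic given ``(params, truth, seed)``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_droplets
    vd = params.droplet_volume_ul

    lam_fam = truth.fam_target_copies_per_ul * vd
    lam_hex = truth.hex_target_copies_per_ul * vd
    occ_fam = rng.poisson(lam_fam, size=n)
    occ_hex = rng.poisson(lam_hex, size=n)
    pos_fam = occ_fam >= 1
    pos_hex = occ_hex >= 1
    double = pos_fam & pos_hex

    fam = np.where(
        pos_fam,
        rng.normal(params.fam_pos_mean, params.fam_pos_sd, size=n),
        rng.normal(params.fam_neg_mean, params.fam_neg_sd, size=n),
    )
    hex_mean = np.where(
        pos_hex,
        np.where(double, params.hex_pos_mean * params.competition_kappa, params.hex_pos_mean),
        params.hex_neg_mean,
    )
    hex_sd = np.where(pos_hex, params.hex_pos_sd, params.hex_neg_sd)
    hex_amp = rng.normal(hex_mean, hex_sd)

    if params.rain_fraction > 0:
        rain = rng.random(n) < params.rain_fraction
        fam = np.where(rain, rng.uniform(params.fam_neg_mean, params.fam_pos_mean, size=n), fam)
        hex_amp = np.where(rain, rng.uniform(params.hex_neg_mean, params.hex_pos_mean, size=n), hex_amp)

    # spectral bleed of FAM into the HEX detector, applied to every droplet
    hex_amp = hex_amp + params.crosstalk_alpha * np.maximum(0.0, fam - params.fam_neg_mean)

    reaction = DropletReaction(
        well_id=well_id,
        assay_name=assay_name,
        fam_amplitudes=fam,
        hex_amplitudes=hex_amp,
        reaction_volume_ul=reaction_volume_ul,
        droplet_volume_nl=params.droplet_volume_nl,
        dilution_exponent=dilution_exponent,
        replicate_id=replicate_id,
        is_ntc=is_ntc,
        annealing_temp_c=annealing_temp_c,
    )
    if return_occupancy:
        return reaction, occ_fam, occ_hex
    return reaction


def simulate_dilution_series(
    params: SimulationParams,
    base_truth: TrueConcentrations,
    dilution_base: int,
    exponents: Sequence[int],
    replicates_per_level: int,
    seed: int,
    *,
    hold_hex_constant: bool = False,
    assay_name: str = "duplex",
) -> List[DropletReaction]:
    """Simulate a serial dilution series with technical replicates.

    At exponent ``k`` both target concentrations are scaled by
    ``dilution_base**k``.  With ``hold_hex_constant=True`` the HEX target
    (spike-in added fresh to every reaction) stays at its base value.
    Replicate ``r`` of level index ``i`` uses sub-seed
    ``seed + 1000*i + r`` so individual wells are reproducible.
    """
    if dilution_base < 2:
        raise ValueError("dilution_base must be >= 2")
    if replicates_per_level < 1:
        raise ValueError("replicates_per_level must be >= 1")
    if any(k > 0 for k in exponents):
        raise ValueError("dilution exponents must be non-positive")

    reactions = []
    for i, k in enumerate(exponents):
        factor = float(dilution_base) ** k
        truth_k = TrueConcentrations(
            base_truth.fam_target_copies_per_ul * factor,
            base_truth.hex_target_copies_per_ul
            if hold_hex_constant
            else base_truth.hex_target_copies_per_ul * factor,
        )
        for r in range(replicates_per_level):
            reactions.append(
                simulate_reaction(
                    params,
                    truth_k,
                    well_id=f"L{i}R{r}",
                    assay_name=assay_name,
                    dilution_exponent=k,
                    replicate_id=r,
                    seed=seed + 1000 * i + r,
                )
            )
    return reactions


def simulate_ntc(params: SimulationParams, seed: Optional[int] = None, *, well_id: str = "NTC") -> DropletReaction:
    """Simulate a no-template control well.

    The only template present is trace contamination at
    ``params.ntc_contamination_rate`` copies/µL on both channels.
    """
    truth = TrueConcentrations(params.ntc_contamination_rate, params.ntc_contamination_rate)
    return simulate_reaction(params, truth, well_id=well_id, assay_name="NTC", is_ntc=True, seed=seed)


def simulate_processing(
    truth: TrueConcentrations,
    spike_input: float,
    efficiency: float,
) -> Tuple[TrueConcentrations, float]:
    """Apply sample-processing loss to target and spike-in alike.

    The spike-in is added before extraction, so purification, DNase
    treatment and reverse transcription remove the same fraction of spike
    and endogenous target molecules.  Returns the post-processing
    concentrations that drive :func:`simulate_reaction` (target on FAM,
    realized spike on HEX) and the realized spike concentration.
    Proportional loss is deterministic; droplet-level noise enters
    downstream in the simulated reaction.
    """
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("efficiency must be in (0, 1]")
    if spike_input <= 0:
        raise ValueError("spike_input must be positive")
    realized_spike = spike_input * efficiency
    post = TrueConcentrations(
        truth.fam_target_copies_per_ul * efficiency,
        realized_spike,
    )
    return post, realized_spike


def expected_positive_fraction(concentration_per_ul: float, droplet_volume_nl: float) -> float:
    """Closed-form P(droplet positive) = 1 − exp(−c·V_d) under Poisson loading."""
    lam = concentration_per_ul * droplet_volume_nl * 1e-3
    return 1.0 - math.exp(-lam)
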