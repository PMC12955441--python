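"""Per-droplet observables: the two-channel amplitude table for one well."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class DropletReaction:
    """Two-channel fluorescence amplitudes for every droplet of one well.

    This is the atomic observable of a droplet digital PCR experiment: after
    endpoint amplification each droplet is read once on the FAM channel
    (target 1) and once on the HEX channel (target 2).  Amplitudes are in
    the reader's arbitrary fluorescence units.

    Parameters
    ----------
    well_id : str
        Plate-well identifier, e.g. ``"A01"``.
    assay_name : str
        Duplex assay the well was run with, e.g. ``"cifA/spike"``.
    fam_amplitudes, hex_amplitudes : ndarray
        Equal-length per-droplet amplitude vectors.
    reaction_volume_ul : float
        Assembled reaction volume in µL (default 20).  Copies/reaction
        scales linearly with this value.
    droplet_volume_nl : float
        Partition volume in nL (default 0.85).  Copies/µL scales inversely
        with this value.
    dilution_exponent : int, optional
        Exponent ``k`` of the nominal dilution ``base**k`` (non-positive).
    replicate_id : int, optional
        Technical replicate index within a dilution level.
    is_ntc : bool
        True for no-template control wells.
    annealing_temp_c : float, optional
        Annealing temperature; carried as metadata only.
    """

    well_id: str
    assay_name: str
    fam_amplitudes: np.ndarray
    hex_amplitudes: np.ndarray
    reaction_volume_ul: float = 20.0
    droplet_volume_nl: float = 0.85
    dilution_exponent: Optional[int] = None
    replicate_id: Optional[int] = None
    is_ntc: bool = False
    annealing_temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        self.fam_amplitudes = np.asarray(self.fam_amplitudes, dtype=float)
        self.hex_amplitudes = np.asarray(self.hex_amplitudes, dtype=float)
        if self.fam_amplitudes.shape != self.hex_amplitudes.shape:
            raise ValueError(
                "FAM and HEX amplitude vectors must have the same length "
                f"({self.fam_amplitudes.size} != {self.hex_amplitudes.size})"
            )
        if self.fam_amplitudes.ndim != 1:
            raise ValueError("amplitude vectors must be one-dimensional")
        if not (np.all(np.isfinite(self.fam_amplitudes)) and np.all(np.isfinite(self.hex_amplitudes))):
            raise ValueError("amplitudes must be finite")
        if self.reaction_volume_ul <= 0:
            raise ValueError("reaction_volume_ul must be positive")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")

    @property
    def n_droplets(self) -> int:
        return int(self.fam_amplitudes.size)
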