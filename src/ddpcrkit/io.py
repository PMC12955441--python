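"""CSV/JSON I/O for droplet tables, estimate tables, and run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .droplets import DropletReaction
from .quantify import ConcentrationEstimate

logger = logging.getLogger("ddpcrkit")

DROPLET_COLUMNS = ["well", "assay", "droplet_index", "fam_amplitude", "hex_amplitude"]

META_COLUMNS = [
    "reaction_volume_ul",
    "droplet_volume_nl",
    "dilution_exponent",
    "replicate_id",
    "is_ntc",
    "annealing_temp_c",
]

ESTIMATE_COLUMNS = [
    "well",
    "assay",
    "target",
    "n_droplets",
    "n_positive",
    "lambda",
    "copies_per_ul",
    "copies_per_reaction",
    "ci_low",
    "ci_high",
    "qc_pass",
    "saturated",
    "dilution_exponent",
    "replicate_id",
    "is_ntc",
]


def _config_hash(payload: Dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# droplet tables
# ---------------------------------------------------------------------------

def write_droplet_csv(
    reactions: Sequence[DropletReaction],
    path,
    *,
    params: Optional[Dict] = None,
    truth: Optional[Dict] = None,
) -> None:
    """Write wells as one long CSV; params/truth go to a JSON sidecar."""
    if not reactions:
        raise ValueError("no reactions to write")
    frames = []
    for rx in reactions:
        frames.append(
            pd.DataFrame(
                {
                    "well": rx.well_id,
                    "assay": rx.assay_name,
                    "droplet_index": np.arange(rx.n_droplets),
                    "fam_amplitude": rx.fam_amplitudes,
                    "hex_amplitude": rx.hex_amplitudes,
                    "reaction_volume_ul": rx.reaction_volume_ul,
                    "droplet_volume_nl": rx.droplet_volume_nl,
                    "dilution_exponent": rx.dilution_exponent,
                    "replicate_id": rx.replicate_id,
                    "is_ntc": rx.is_ntc,
                    "annealing_temp_c": rx.annealing_temp_c,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    path = Path(path)
    sidecar = {"package_version": _pkg_version, "params": params, "truth": truth}
    header = f"# ddpcrkit {_pkg_version} config_hash={_config_hash(sidecar)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        table.to_csv(fh, index=False)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_droplet_csv(path, column_map: Optional[Dict[str, str]] = None) -> List[DropletReaction]:
    """Read a droplet amplitude CSV into one :class:`DropletReaction` per well.

    ``column_map`` renames foreign headers onto the canonical ones, e.g.
    ``{"Ch1 Amplitude": "fam_amplitude", "Ch2 Amplitude": "hex_amplitude"}``
    for two-column instrument exports (a single unnamed well is assumed
    when no ``well`` column exists).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, comment="#")
    if column_map:
        table = table.rename(columns=column_map)
    required = {"fam_amplitude", "hex_amplitude"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "well" not in table.columns:
        table["well"] = "A01"
    if "assay" not in table.columns:
        table["assay"] = "unknown"

    # locate non-numeric amplitude cells and report the first offending line
    for col in ("fam_amplitude", "hex_amplitude"):
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"non-numeric value in column {col!r} at line {line}")
        table[col] = values

    n_malformed = int(table[["fam_amplitude", "hex_amplitude"]].isna().any(axis=1).sum())
    if n_malformed:
        logger.warning("dropping %d malformed droplet rows", n_malformed)
        table = table.dropna(subset=["fam_amplitude", "hex_amplitude"])

    reactions = []
    for (well, assay), group in table.groupby(["well", "assay"], sort=True):
        if group.empty:
            continue

        def _meta(name, default, cast):
            if name in group.columns and group[name].notna().any():
                return cast(group[name].iloc[0])
            return default

        reactions.append(
            DropletReaction(
                well_id=str(well),
                assay_name=str(assay),
                fam_amplitudes=group["fam_amplitude"].to_numpy(float),
                hex_amplitudes=group["hex_amplitude"].to_numpy(float),
                reaction_volume_ul=_meta("reaction_volume_ul", 20.0, float),
                droplet_volume_nl=_meta("droplet_volume_nl", 0.85, float),
                dilution_exponent=_meta("dilution_exponent", None, lambda v: int(v)),
                replicate_id=_meta("replicate_id", None, lambda v: int(v)),
                is_ntc=_meta("is_ntc", False, lambda v: bool(v)),
                annealing_temp_c=_meta("annealing_temp_c", None, float),
            )
        )
    if not reactions:
        raise ValueError("no wells found in droplet table")
    return reactions


# ---------------------------------------------------------------------------
# estimate tables
# ---------------------------------------------------------------------------

def write_estimates_csv(estimates: Sequence[ConcentrationEstimate], path) -> None:
    """Write per-well estimates in a deterministic row/column order."""
    if not estimates:
        raise ValueError("no estimates to write")
    rows = [
        {
            "well": e.well_id,
            "assay": e.assay_name,
            "target": e.target_name,
            "n_droplets": e.n_droplets,
            "n_positive": e.n_positive,
            "lambda": e.lambda_hat,
            "copies_per_ul": e.copies_per_ul,
            "copies_per_reaction": e.copies_per_reaction,
            "ci_low": e.ci95_low,
            "ci_high": e.ci95_high,
            "qc_pass": e.qc_pass,
            "saturated": e.saturated,
            "dilution_exponent": e.dilution_exponent,
            "replicate_id": e.replicate_id,
            "is_ntc": e.is_ntc,
        }
        for e in estimates
    ]
    table = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    table = table.sort_values(["well", "target"], kind="stable").reset_index(drop=True)
    header = f"# ddpcrkit {_pkg_version} config_hash={_config_hash(rows[0])}\n"
    with open(path, "w") as fh:
        fh.write(header)
        table.to_csv(fh, index=False)


def read_estimates_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured configuration for the CLI pipeline.

    ``seed`` is mandatory for any stochastic command; unknown keys in the
    config file are rejected rather than silently ignored.
    """

    seed: int
    simulator: Dict = field(default_factory=dict)
    truth: Dict = field(default_factory=dict)
    dilution: Dict = field(default_factory=dict)
    thresholds: Dict = field(default_factory=dict)
    min_droplets: int = 10_000
    recipe: Optional[str] = None
    output_dir: Optional[str] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "seed" not in payload:
            raise ValueError("config must set a seed")
        return cls(**payload)

    def hash(self) -> str:
        return _config_hash(asdict(self))
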