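"""Exactly specified assay arithmetic.

Four small, auditable calculations that accompany the imaging pipeline:

* TEER normalisation: blank-corrected resistance times insert area,
  (raw - 100 ohm) * 0.33 cm2 by default, reported in ohm*cm2.  Readings
  below the blank yield a *negative, flagged* value — never a silent clip —
  so suspect wells stay visible in the audit trail.
* Mean-fluorescence-per-cell: field mean gray value / total cell count.
* Positive-cell fraction: marker-positive count / total count.
* Elastic modulus from shear storage modulus via rubber elasticity,
  E = 2 (1 + nu) G'; with nu = 0.5 (incompressible) this is E = 3 G',
  which is how a gel with G' = 1 kPa is reported as a "3 kPa" substrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TeerConfig",
    "TeerResult",
    "FluorescenceRecord",
    "RheologyInput",
    "normalize_teer",
    "normalize_teer_table",
    "fluorescence_per_cell",
    "positive_fraction",
    "modulus_from_storage",
]


@dataclass(frozen=True)
class TeerConfig:
    """Blank resistance (ohm) and insert area (cm2) of the TEER assay."""

    blank_resistance: float = 100.0
    well_area: float = 0.33

    def __post_init__(self) -> None:
        if self.blank_resistance < 0:
            raise ValueError("blank_resistance must be non-negative")
        if self.well_area <= 0:
            raise ValueError("well_area must be positive")


@dataclass(frozen=True)
class TeerResult:
    values: tuple[float, ...]
    flags: tuple[bool, ...]  # True where the raw reading fell below blank
    mean: float


@dataclass(frozen=True)
class FluorescenceRecord:
    """One field of view: mean gray value, total cells, optional positives."""

    mean_gray_value: float
    n_cells: int
    n_positive: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_positive is not None and not 0 <= self.n_positive <= self.n_cells:
            raise ValueError("n_positive must lie in [0, n_cells]")


@dataclass(frozen=True)
class RheologyInput:
    """Shear moduli (kPa) and Poisson ratio of one hydrogel sample."""

    g_prime: float
    g_double_prime: float = 0.0
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.g_prime <= 0:
            raise ValueError("g_prime must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


def normalize_teer(
    raw: float | Sequence[float], cfg: TeerConfig = TeerConfig()
) -> TeerResult:
    """Blank-corrected, area-scaled TEER in ohm*cm2 per replicate plus mean.

    value = (raw - blank_resistance) * well_area.  Negative results are
    returned as-is and flagged (physically suspect well), never clipped.
    """
    readings = np.atleast_1d(np.asarray(raw, dtype=float))
    if (readings < 0).any():
        raise ValueError("raw resistance readings must be non-negative")
    values = (readings - cfg.blank_resistance) * cfg.well_area
    flags = readings < cfg.blank_resistance
    return TeerResult(
        values=tuple(values.tolist()),
        flags=tuple(flags.tolist()),
        mean=float(values.mean()),
    )


def normalize_teer_table(
    table: pd.DataFrame, cfg: TeerConfig = TeerConfig()
) -> pd.DataFrame:
    """Normalise a (well_id, condition, raw_ohm) table; averages per condition
    are left to the caller's grouping of choice."""
    out = table.copy()
    res = normalize_teer(out["raw_ohm"].to_numpy(), cfg)
    out["teer_ohm_cm2"] = res.values
    out["flag"] = res.flags
    return out


def fluorescence_per_cell(rec: FluorescenceRecord) -> float:
    """Mean gray value of the field normalised by total cell count."""
    return rec.mean_gray_value / rec.n_cells


def positive_fraction(rec: FluorescenceRecord) -> float:
    """Fraction of cells expressing the marker of interest, in [0, 1]."""
    if rec.n_positive is None:
        raise ValueError("record has no positive-cell count")
    return rec.n_positive / rec.n_cells


def modulus_from_storage(rh: RheologyInput) -> float:
    """Elastic modulus from shear storage modulus, E = 2 (1 + nu) G' (kPa)."""
    return 2.0 * (1.0 + rh.poisson_ratio) * rh.g_prime
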