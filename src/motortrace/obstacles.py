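"""Linear obstacle density on microtubules.

Quantum-dot obstacle density per µm of MT is estimated two ways: by
counting resolvable fluorescent spots (reliable when spots are sparse) and
by the ratio of total MT fluorescence to the intensity of a single QD
(needed once spots overlap).  Counting saturates at high density, so the
intensity-ratio estimate is used above a crossover density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MTIntensityRecord",
    "density_by_counting",
    "density_by_intensity",
    "estimate_density",
    "read_intensity_records",
]

CROSSOVER_DENSITY_PER_UM = 2.0


@dataclass(frozen=True)
class MTIntensityRecord:
    """Per-microtubule fluorescence summary (inputs are background-corrected)."""

    mt_id: str
    mt_length_um: float
    spot_count: int | None = None
    total_intensity: float | None = None
    single_qd_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mt_length_um <= 0:
            raise ValueError("mt_length_um must be positive")
        if self.spot_count is None and self.total_intensity is None:
            raise ValueError("need spot_count and/or total_intensity")


def density_by_counting(record: MTIntensityRecord) -> float:
    """Spots per µm of MT."""
    if record.spot_count is None:
        raise ValueError(f"{record.mt_id}: spot_count missing")
    return record.spot_count / record.mt_length_um


def density_by_intensity(record: MTIntensityRecord) -> float:
    """(total / single-QD intensity) per µm of MT."""
    if record.total_intensity is None or record.single_qd_intensity is None:
        raise ValueError(f"{record.mt_id}: intensity fields missing")
    if record.single_qd_intensity <= 0:
        raise ValueError(f"{record.mt_id}: single_qd_intensity must be positive")
    return (record.total_intensity / record.single_qd_intensity) / record.mt_length_um


def estimate_density(
    record: MTIntensityRecord,
    crossover: float = CROSSOVER_DENSITY_PER_UM,
) -> float:
    """Best available density: counting below the crossover, intensity above.

    If only one method's inputs are present, that method is used.  When
    both are available, counting is used whenever its own estimate is at
    or below ``crossover`` µm⁻¹ (spots still resolvable), else the
    intensity ratio.
    """
    has_count = record.spot_count is not None
    has_intensity = (
        record.total_intensity is not None and record.single_qd_intensity is not None
    )
    if has_count and not has_intensity:
        return density_by_counting(record)
    if has_intensity and not has_count:
        return density_by_intensity(record)
    by_count = density_by_counting(record)
    return by_count if by_count <= crossover else density_by_intensity(record)


def read_intensity_records(path) -> list[MTIntensityRecord]:
    """Read a delimited table of per-MT intensity summaries.

    Expected columns: mt_id, mt_length_um and any of spot_count,
    total_intensity, single_qd_intensity (empty cells allowed).
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            MTIntensityRecord(
                mt_id=str(row["mt_id"]),
                mt_length_um=float(row["mt_length_um"]),
                spot_count=(
                    int(row["spot_count"])
                    if "spot_count" in df.columns and pd.notna(row["spot_count"])
                    else None
                ),
                total_intensity=(
                    float(row["total_intensity"])
                    if "total_intensity" in df.columns and pd.notna(row["total_intensity"])
                    else None
                ),
                single_qd_intensity=(
                    float(row["single_qd_intensity"])
                    if "single_qd_intensity" in df.columns
                    and pd.notna(row["single_qd_intensity"])
                    else None
                ),
            )
        )
    return records
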