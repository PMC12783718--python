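"""Specimen metadata records and CSV round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

CLADES = ("Northern", "Southern")
ORIENTATIONS = ("dorsal", "ventral")

METADATA_COLUMNS = [
    "specimen_id",
    "species",
    "clade",
    "location",
    "orientation",
    "image_path",
    "mask_path",
    "keyhole_mask_path",
    "major_axis_mm",
]


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen's labels, file paths and caliper size."""

    specimen_id: str
    species: str
    clade: str
    location: str
    orientation: str
    image_path: str
    mask_path: str
    keyhole_mask_path: str | None
    major_axis_mm: float

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"clade must be one of {CLADES}, got {self.clade!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if not self.major_axis_mm > 0:
            raise ValueError("major_axis_mm must be positive")


def records_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["keyhole_mask_path"] = d["keyhole_mask_path"] or ""
        rows.append(d)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def write_metadata(records: list[SpecimenRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    df["major_axis_mm"] = df["major_axis_mm"].map(lambda v: f"{v:.3f}")
    df.to_csv(path, index=False, lineterminator="\n")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, dtype={"keyhole_mask_path": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id),
                species=str(row.species),
                clade=str(row.clade),
                location=str(row.location),
                orientation=str(row.orientation),
                image_path=str(row.image_path),
                mask_path=str(row.mask_path),
                keyhole_mask_path=str(row.keyhole_mask_path) or None,
                major_axis_mm=float(row.major_axis_mm),
            )
        )
    return records
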