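"""The long-format volume measurement record and table helpers."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["VolumeRecord", "records_to_frame", "frame_to_records", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("subject_id", "scanner_id", "repetition", "structure", "volume_ml")


@dataclass(frozen=True)
class VolumeRecord:
    """One automated volumetry measurement.

    A record is keyed by (subject, scanner, repetition, structure); the
    volume is in mL and must be positive.
    """

    subject_id: str
    scanner_id: str
    repetition: int
    structure: str
    volume_ml: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError(
                f"volume must be positive, got {self.volume_ml} for "
                f"{self.subject_id}/{self.scanner_id}/{self.repetition}/{self.structure}"
            )


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.subject_id, r.scanner_id, int(r.repetition), r.structure, float(r.volume_ml))
            for r in records
        ],
        columns=list(REQUIRED_COLUMNS),
    )
    return df


def frame_to_records(df: pd.DataFrame) -> list[VolumeRecord]:
    return [
        VolumeRecord(
            subject_id=str(row.subject_id),
            scanner_id=str(row.scanner_id),
            repetition=int(row.repetition),
            structure=str(row.structure),
            volume_ml=float(row.volume_ml),
        )
        for row in df.itertuples(index=False)
    ]
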