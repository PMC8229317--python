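"""On-disk measurement records in the handheld device's layout.

Each saved measurement becomes a pair of files named by the imaging time
to one-second precision, ``YYYY-MM-DD-HH-MM-SS``:

    <root>/data/record/2019-12-01-08-17-50.txt
    <root>/data/images/2019-12-01-08-17-50.jpg

The text file carries one ``key=value`` per line (``dbh_mm``,
``distance_mm``, ``lon``, ``lat``) — the device documents only the
naming scheme, so this field layout is this package's own dialect.
Missing GPS fields are written empty.  A colliding timestamp gets a
``_1``, ``_2`` ... suffix instead of overwriting.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Tuple, Union

__all__ = ["MeasurementRecord", "write_record", "read_record", "TIMESTAMP_FORMAT"]

TIMESTAMP_FORMAT = "%Y-%m-%d-%H-%M-%S"


@dataclass(frozen=True)
class MeasurementRecord:
    """One completed DBH measurement."""

    timestamp: datetime
    dbh_mm: float
    distance_mm: float
    longitude: Optional[float] = None
    latitude: Optional[float] = None
    image_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.dbh_mm > 0:
            raise ValueError(f"dbh must be positive, got {self.dbh_mm}")
        if not self.distance_mm > 0:
            raise ValueError(f"distance must be positive, got {self.distance_mm}")

    @property
    def stem(self) -> str:
        return self.timestamp.strftime(TIMESTAMP_FORMAT)

    def to_text(self) -> str:
        def fmt(v: Optional[float]) -> str:
            return "" if v is None else f"{v:.6f}".rstrip("0").rstrip(".")

        return (
            f"dbh_mm={fmt(self.dbh_mm)}\n"
            f"distance_mm={fmt(self.distance_mm)}\n"
            f"lon={fmt(self.longitude)}\n"
            f"lat={fmt(self.latitude)}\n"
        )


def write_record(
    rec: MeasurementRecord, root: Union[str, Path]
) -> Tuple[Path, Optional[Path]]:
    """Write the record text (and copy its image, if any) under
    ``<root>/data/{record,images}``; returns the written paths."""
    root = Path(root)
    record_dir = root / "data" / "record"
    images_dir = root / "data" / "images"
    record_dir.mkdir(parents=True, exist_ok=True)
    images_dir.mkdir(parents=True, exist_ok=True)

    stem = rec.stem
    txt_path = record_dir / f"{stem}.txt"
    suffix = 0
    while txt_path.exists():
        suffix += 1
        txt_path = record_dir / f"{stem}_{suffix}.txt"
    txt_path.write_text(rec.to_text())

    img_path: Optional[Path] = None
    if rec.image_ref is not None:
        src = Path(rec.image_ref)
        ext = src.suffix.lower() or ".jpg"
        img_path = images_dir / (txt_path.stem + ext)
        shutil.copyfile(src, img_path)
    return txt_path, img_path


def read_record(txt_path: Union[str, Path]) -> MeasurementRecord:
    """Parse a record text file back into a :class:`MeasurementRecord`."""
    txt_path = Path(txt_path)
    fields: dict[str, Optional[float]] = {}
    for line in txt_path.read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = float(value) if value.strip() else None
    stem = txt_path.stem
    # strip a collision suffix like _1 before parsing the timestamp
    parts = stem.rsplit("_", 1)
    ts_part = parts[0] if len(parts) == 2 and parts[1].isdigit() else stem
    return MeasurementRecord(
        timestamp=datetime.strptime(ts_part, TIMESTAMP_FORMAT),
        dbh_mm=fields["dbh_mm"],
        distance_mm=fields["distance_mm"],
        longitude=fields.get("lon"),
        latitude=fields.get("lat"),
    )
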