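"""Per-injection peak records and their CSV schema.

An :class:`InjectionRecord` is the entry point of the pipeline: one analyte in
one injection, carrying the integrated areas of its quantifier and qualifier
MRM transitions, the internal-standard area, and the observed retention time.
Raw chromatograms are out of scope; peak areas are taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["InjectionRecord", "ROLES", "records_to_frame", "frame_to_records"]

#: Experimental role of an injection within a study.
ROLES = ("calib", "spike", "wash_before", "wash_after", "sample")

INJECTION_COLUMNS = [
    "analyte",
    "level_ug_kg",
    "replicate",
    "rt_min",
    "area_quant",
    "area_qual",
    "area_is",
    "role",
]


@dataclass(frozen=True)
class InjectionRecord:
    """One analyte observed in one injection.

    ``area_quant`` / ``area_qual`` are the quantifier and qualifier MRM
    transition areas, ``area_is`` the internal-standard area used to form the
    response ratio.  ``level_ug_kg`` is the nominal level of the injection
    (calibration level, spike level or contamination level), ``replicate`` a
    1-based replicate index, and ``role`` one of :data:`ROLES`.
    """

    analyte: str
    rt_min: float
    area_quant: float
    area_qual: float
    area_is: float
    role: str = "sample"
    level_ug_kg: float = float("nan")
    replicate: int = 1
    day: int = 1
    in_range: bool = True

    def __post_init__(self) -> None:
        if self.area_quant < 0 or self.area_qual < 0 or self.area_is < 0:
            raise ValueError(f"{self.analyte}: peak areas must be non-negative")
        if not self.rt_min > 0:
            raise ValueError(f"{self.analyte}: retention time must be positive")
        if self.role not in ROLES:
            raise ValueError(f"{self.analyte}: unknown role {self.role!r}")

    @property
    def response_ratio(self) -> float:
        """Quantifier area normalised by the internal-standard area."""
        if self.area_is <= 0:
            raise ZeroDivisionError(f"{self.analyte}: internal-standard area is zero")
        return self.area_quant / self.area_is


def records_to_frame(records: Iterable[InjectionRecord]) -> pd.DataFrame:
    """Long-format injection table with the fixed CSV header."""
    rows = [
        dict(
            analyte=r.analyte,
            level_ug_kg=r.level_ug_kg,
            replicate=r.replicate,
            rt_min=r.rt_min,
            area_quant=r.area_quant,
            area_qual=r.area_qual,
            area_is=r.area_is,
            role=r.role,
            day=r.day,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=INJECTION_COLUMNS + ["day"])


def frame_to_records(frame: pd.DataFrame) -> list[InjectionRecord]:
    missing = [c for c in INJECTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"injection table is missing columns: {missing}")
    return [
        InjectionRecord(
            analyte=row.analyte,
            rt_min=float(row.rt_min),
            area_quant=float(row.area_quant),
            area_qual=float(row.area_qual),
            area_is=float(row.area_is),
            role=row.role,
            level_ug_kg=float(row.level_ug_kg),
            replicate=int(row.replicate),
            day=int(getattr(row, "day", 1)),
        )
        for row in frame.itertuples(index=False)
    ]


def write_injections_csv(records: Sequence[InjectionRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_injections_csv(path) -> list[InjectionRecord]:
    return frame_to_records(pd.read_csv(path))
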