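"""Per-pesticide method registry.

Each analyte carries the constants of the validated multi-residue method:
limit of quantification (LOQ), linear calibration range, acquisition polarity
and assigned internal standard, plus (optionally) the reference retention time
and ion-ratio mean established from a matrix-matched calibration batch.

The bundled registry transcribes the validated 120-compound method table for
pesticide residues in rice (LOQs of 5, 10 or 50 μg/kg; linear ranges of
5–100, 10–100 or 50–100 μg/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = ["PesticideSpec", "PesticideRegistry", "default_registry"]

_POLARITIES = {"positive", "negative"}
_INTERNAL_STANDARDS = {"TPP", "DNC"}


@dataclass(frozen=True)
class PesticideSpec:
    """Method constants for one analyte.

    Parameters
    ----------
    name
        Analyte name as it appears in the method table.
    loq
        Limit of quantification in μg/kg; back-calculated concentrations
        below it are reported censored ("< LOQ").
    linear_range
        (low, high) of the calibration range in μg/L.  Sample-level
        concentrations in μg/kg are numerically identical to these labels
        for the 1:1 matrix-matched dilution used here; a single numeric
        scale is stored and the unit is metadata.
    polarity
        Electrospray polarity, ``"positive"`` or ``"negative"``.
    internal_standard
        ``"TPP"`` (positive mode) or ``"DNC"`` (negative mode).
    rt_mean_calibration
        Mean retention time (minutes) of the analyte over a calibration
        batch; reference for the retention-time identification criterion.
        ``None`` until established from a calibration batch.
    ir_mean_calibration
        Mean ion ratio (percent, in (0, 100]) over a calibration batch;
        reference for the ion-ratio identification criterion.
    """

    name: str
    loq: float
    linear_range: tuple[float, float]
    polarity: str = "positive"
    internal_standard: str = "TPP"
    rt_mean_calibration: float | None = None
    ir_mean_calibration: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("analyte name must be non-empty")
        if not self.loq > 0:
            raise ValueError(f"{self.name}: LOQ must be positive, got {self.loq}")
        low, high = self.linear_range
        if not low < high:
            raise ValueError(
                f"{self.name}: linear range low must be below high, got {self.linear_range}"
            )
        if self.polarity not in _POLARITIES:
            raise ValueError(f"{self.name}: polarity must be one of {sorted(_POLARITIES)}")
        if self.internal_standard not in _INTERNAL_STANDARDS:
            raise ValueError(
                f"{self.name}: internal standard must be one of {sorted(_INTERNAL_STANDARDS)}"
            )
        if self.ir_mean_calibration is not None and not 0 < self.ir_mean_calibration <= 100:
            raise ValueError(
                f"{self.name}: ion-ratio mean must lie in (0, 100], got {self.ir_mean_calibration}"
            )
        if self.rt_mean_calibration is not None and not self.rt_mean_calibration > 0:
            raise ValueError(f"{self.name}: retention-time mean must be positive")

    def with_calibration_reference(self, rt_mean: float, ir_mean: float) -> "PesticideSpec":
        """Return a copy with the calibration RT/ion-ratio references filled in."""
        return replace(self, rt_mean_calibration=rt_mean, ir_mean_calibration=ir_mean)


class UnknownAnalyteError(KeyError):
    """Raised when an analyte is not present in the registry."""


class PesticideRegistry(Mapping[str, PesticideSpec]):
    """Name-keyed collection of :class:`PesticideSpec` entries."""

    def __init__(self, specs: Iterable[PesticideSpec]):
        self._specs: dict[str, PesticideSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate registry entry: {spec.name}")
            self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> PesticideSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise UnknownAnalyteError(name) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def update(self, spec: PesticideSpec) -> None:
        """Insert or replace one entry."""
        self._specs[spec.name] = spec

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PesticideRegistry":
        """Build a registry from a table with columns
        ``pesticide, loq_ug_kg, linear_low_ug_L, linear_high_ug_L`` and
        optionally ``polarity, internal_standard, rt_min, ir_pct``."""
        specs = []
        for row in frame.itertuples(index=False):
            specs.append(
                PesticideSpec(
                    name=row.pesticide,
                    loq=float(row.loq_ug_kg),
                    linear_range=(float(row.linear_low_ug_L), float(row.linear_high_ug_L)),
                    polarity=getattr(row, "polarity", "positive"),
                    internal_standard=getattr(row, "internal_standard", "TPP"),
                    rt_mean_calibration=_opt(getattr(row, "rt_min", None)),
                    ir_mean_calibration=_opt(getattr(row, "ir_pct", None)),
                )
            )
        return cls(specs)

    @classmethod
    def from_csv(cls, path) -> "PesticideRegistry":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                pesticide=s.name,
                loq_ug_kg=s.loq,
                linear_low_ug_L=s.linear_range[0],
                linear_high_ug_L=s.linear_range[1],
                polarity=s.polarity,
                internal_standard=s.internal_standard,
                rt_min=s.rt_mean_calibration,
                ir_pct=s.ir_mean_calibration,
            )
            for s in self._specs.values()
        ]
        return pd.DataFrame(rows)


def _opt(value) -> float | None:
    if value is None or pd.isna(value):
        return None
    return float(value)


def default_registry() -> PesticideRegistry:
    """The bundled rice multi-residue registry (120 pesticides)."""
    from .datasets import load_registry_table

    return PesticideRegistry.from_frame(load_registry_table())
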