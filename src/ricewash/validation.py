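"""Method-validation metrics: recovery, precision, expanded uncertainty.

Per pesticide, blank matrix is spiked at three levels (n = 5 replicates) and
the experiment is repeated on three days by different operators.  From the
back-calculated concentrations this module computes

* recovery (measured mean / spiked × 100), acceptance window 70–120 %;
* RSDr — repeatability relative standard deviation (within one day);
* RSDR — within-lab reproducibility RSD, computed over the pooled values of
  all days (total-variability convention, not the ANOVA between-day
  component);
* expanded uncertainty, top-down: U = k·sqrt(RSDR² + bias²) with
  bias = recovery − 100 and coverage factor k = 2 (~95 % coverage).

Both precision RSDs are reported at the spike level equal to the analyte's
LOQ, matching how multi-residue validation tables are conventionally
reported; recoveries are reported per level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .quantification import CalibrationCurve, R2_FLAG_THRESHOLD
from .registry import PesticideSpec

__all__ = [
    "RECOVERY_WINDOW_PCT",
    "RSD_LIMIT_PCT",
    "ValidationReport",
    "recovery_pct",
    "rsd",
    "rsd_reproducibility",
    "expanded_uncertainty",
    "validate_pesticide",
]

#: SANTE acceptance window for mean recovery, percent.
RECOVERY_WINDOW_PCT = (70.0, 120.0)
#: SANTE acceptance ceiling for RSDr and RSDR, percent.
RSD_LIMIT_PCT = 20.0


def recovery_pct(measured_mean: float, spiked: float) -> float:
    """Recovery in percent: 100 × measured mean / spiked level."""
    if spiked <= 0:
        raise ValueError("spiked level must be positive")
    return 100.0 * measured_mean / spiked


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent (n−1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD requires at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * v.std(ddof=1) / abs(mean)


def rsd_reproducibility(day_batches: Sequence[Sequence[float]]) -> float:
    """Within-lab reproducibility RSD: RSD of the values pooled across days."""
    if len(day_batches) < 2 or any(len(b) < 2 for b in day_batches):
        raise ValueError("reproducibility requires ≥ 2 batches of ≥ 2 values")
    pooled = np.concatenate([np.asarray(b, dtype=float) for b in day_batches])
    return rsd(pooled)


def expanded_uncertainty(rsd_R: float, bias: float, k: float = 2.0) -> float:
    """Top-down expanded uncertainty U = k·sqrt(RSDR² + bias²), percent.

    ``bias`` may be signed (recovery − 100); ``k`` is the coverage factor.
    """
    if k <= 0:
        raise ValueError("coverage factor must be positive")
    if rsd_R < 0:
        raise ValueError("RSDR must be non-negative")
    return k * math.hypot(rsd_R, bias)


@dataclass(frozen=True)
class ValidationReport:
    """One pesticide's validation summary (the shape of a method-table row)."""

    analyte: str
    linear_range: tuple[float, float]
    r_squared: float
    loq: float
    recovery_by_level: dict[float, float]
    rsd_r: float
    rsd_R: float
    uncertainty: float
    recovery_pass: bool
    precision_pass: bool
    linearity_pass: bool
    missing_levels: tuple[float, ...] = ()

    @property
    def mean_recovery(self) -> float:
        return float(np.mean(list(self.recovery_by_level.values())))


def validate_pesticide(
    spike_tables: Mapping[float, Sequence[Sequence[float]]],
    curve: CalibrationCurve,
    spec: PesticideSpec,
    k: float = 2.0,
) -> ValidationReport:
    """Assemble the validation metrics for one pesticide.

    ``spike_tables`` maps spike level (μg/kg) to a list of per-day replicate
    lists of back-calculated concentrations, e.g. three days × five
    replicates.  Precision RSDs are taken at the level equal to the
    analyte's LOQ (falling back to the lowest provided level if the LOQ
    level is absent); recovery is computed per level over all days.  Missing
    levels are flagged rather than fatal.
    """
    if not spike_tables:
        raise ValueError("no spike data provided")
    recoveries: dict[float, float] = {}
    missing = []
    for level in sorted(spike_tables):
        batches = spike_tables[level]
        if not batches or all(len(b) == 0 for b in batches):
            missing.append(level)
            continue
        pooled = np.concatenate([np.asarray(b, dtype=float) for b in batches])
        recoveries[level] = recovery_pct(float(pooled.mean()), level)
    if not recoveries:
        raise ValueError("all spike levels empty")

    prec_level = spec.loq if spec.loq in recoveries else min(recoveries)
    batches = [b for b in spike_tables[prec_level] if len(b) >= 2]
    rsd_r_val = rsd(batches[0])
    rsd_R_val = rsd_reproducibility(batches) if len(batches) >= 2 else rsd_r_val

    mean_rec = float(np.mean(list(recoveries.values())))
    u = expanded_uncertainty(rsd_R_val, mean_rec - 100.0, k=k)

    lo, hi = RECOVERY_WINDOW_PCT
    return ValidationReport(
        analyte=spec.name,
        linear_range=spec.linear_range,
        r_squared=curve.r_squared,
        loq=spec.loq,
        recovery_by_level=recoveries,
        rsd_r=rsd_r_val,
        rsd_R=rsd_R_val,
        uncertainty=u,
        recovery_pass=all(lo <= r <= hi for r in recoveries.values()),
        precision_pass=rsd_r_val <= RSD_LIMIT_PCT and rsd_R_val <= RSD_LIMIT_PCT,
        linearity_pass=curve.r_squared >= R2_FLAG_THRESHOLD,
        missing_levels=tuple(missing),
    )
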