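"""SANTE-style identification criteria for targeted MRM acquisition.

A detection counts as a positive identification only when two criteria hold
simultaneously:

* retention time: the sample RT deviates from the mean calibration RT of the
  same analyte by less than 0.1 min, ``ΔRT = RT_sample − RT_mean,calib``;
* ion ratio: the sample ion ratio (area of the less intense of the two MRM
  transitions over the more intense one, ×100) deviates from the mean
  calibration ion ratio by less than 30 % relative,
  ``ΔIR = (IR_sample − IR_mean,calib) / IR_mean,calib × 100``.

Both tolerances are strict: an observation sitting exactly on the 0.1 min or
30 % boundary fails.  The ion ratio is always formed min/max, so it is
symmetric in the two transition areas and bounded in (0, 100]; which
transition is "lowest intensity" may flip under noise when the true ratio is
close to 100, and that is intentional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .records import InjectionRecord
from .registry import PesticideSpec

__all__ = [
    "RT_TOLERANCE_MIN",
    "IR_TOLERANCE_PCT",
    "IdentificationResult",
    "delta_rrt",
    "ion_ratio",
    "delta_ir",
    "identify",
    "identify_batch",
    "calibration_reference",
]

#: Strict upper bound on |ΔRT| in minutes.
RT_TOLERANCE_MIN = 0.1
#: Strict upper bound on |ΔIR| in percent.
IR_TOLERANCE_PCT = 30.0


@dataclass(frozen=True)
class IdentificationResult:
    analyte: str
    delta_rrt: float
    ir_sample: float
    delta_ir: float
    rt_pass: bool
    ir_pass: bool

    @property
    def identified(self) -> bool:
        return self.rt_pass and self.ir_pass


def delta_rrt(rt_sample: float, rt_mean_calibration: float) -> float:
    """Signed retention-time deviation in minutes.

    The decision rule uses the absolute value; the sign is kept so drift
    direction stays visible in reports.
    """
    if not (math.isfinite(rt_sample) and math.isfinite(rt_mean_calibration)):
        raise ValueError("retention times must be finite")
    if rt_sample <= 0 or rt_mean_calibration <= 0:
        raise ValueError("retention times must be positive")
    return rt_sample - rt_mean_calibration


def ion_ratio(area_a: float, area_b: float) -> float:
    """Ion ratio in percent: lower transition area over higher, ×100.

    Symmetric in its arguments; result lies in (0, 100].
    """
    if area_a <= 0 or area_b <= 0:
        raise ValueError("ion ratio requires two positive transition areas")
    return min(area_a, area_b) / max(area_a, area_b) * 100.0


def delta_ir(ir_sample: float, ir_mean_calibration: float) -> float:
    """Signed relative ion-ratio deviation in percent of the calibration mean."""
    if ir_mean_calibration <= 0:
        raise ValueError("mean calibration ion ratio must be positive")
    return (ir_sample - ir_mean_calibration) / ir_mean_calibration * 100.0


def identify(record: InjectionRecord, spec: PesticideSpec) -> IdentificationResult:
    """Apply both identification criteria to one injection.

    ``spec`` must carry the calibration references (``rt_mean_calibration``
    and ``ir_mean_calibration``), either from the registry or computed from
    the run's own calibration batch via :func:`calibration_reference`.
    """
    if record.analyte != spec.name:
        raise ValueError(f"record is {record.analyte!r} but spec is {spec.name!r}")
    if spec.rt_mean_calibration is None or spec.ir_mean_calibration is None:
        raise ValueError(
            f"{spec.name}: calibration RT/ion-ratio references are not set; "
            "derive them from a calibration batch first"
        )
    d_rt = delta_rrt(record.rt_min, spec.rt_mean_calibration)
    ir = ion_ratio(record.area_quant, record.area_qual)
    d_ir = delta_ir(ir, spec.ir_mean_calibration)
    return IdentificationResult(
        analyte=record.analyte,
        delta_rrt=d_rt,
        ir_sample=ir,
        delta_ir=d_ir,
        rt_pass=abs(d_rt) < RT_TOLERANCE_MIN,
        ir_pass=abs(d_ir) < IR_TOLERANCE_PCT,
    )


def calibration_reference(
    records: Iterable[InjectionRecord],
) -> dict[str, tuple[float, float]]:
    """Mean RT and mean ion ratio per analyte over a calibration batch.

    Returns ``{analyte: (rt_mean, ir_mean)}`` computed from the records with
    role ``"calib"``; arithmetic means, matching how the references are
    established from the matrix-matched calibration injections of a run.
    """
    sums: dict[str, list[float]] = {}
    for r in records:
        if r.role != "calib":
            continue
        acc = sums.setdefault(r.analyte, [0.0, 0.0, 0])
        acc[0] += r.rt_min
        acc[1] += ion_ratio(r.area_quant, r.area_qual)
        acc[2] += 1
    return {a: (s[0] / s[2], s[1] / s[2]) for a, s in sums.items() if s[2] > 0}


def identify_batch(
    records: Iterable[InjectionRecord],
    registry: Mapping[str, PesticideSpec],
) -> pd.DataFrame:
    """Identification report, one row per injection.

    Analytes whose registry entry lacks calibration references take them from
    the batch's own calibration injections.  Calibration injections themselves
    are included in the report (they should trivially pass).
    """
    records = list(records)
    refs = calibration_reference(records)
    rows = []
    for r in records:
        spec = registry[r.analyte]
        if spec.rt_mean_calibration is None or spec.ir_mean_calibration is None:
            if r.analyte not in refs:
                raise ValueError(
                    f"{r.analyte}: no registry reference and no calibration injections"
                )
            spec = spec.with_calibration_reference(*refs[r.analyte])
        res = identify(r, spec)
        rows.append(
            dict(
                analyte=r.analyte,
                role=r.role,
                level_ug_kg=r.level_ug_kg,
                replicate=r.replicate,
                delta_rrt_min=res.delta_rrt,
                ir_pct=res.ir_sample,
                delta_ir_pct=res.delta_ir,
                rt_pass=res.rt_pass,
                ir_pass=res.ir_pass,
                identified=res.identified,
            )
        )
    return pd.DataFrame(rows)
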