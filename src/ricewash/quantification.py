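"""Matrix-matched internal-standard calibration and LOQ-censored back-calculation.

The response ratio (analyte quantifier area / internal-standard area) is
regressed on concentration by ordinary least squares over the matrix-matched
calibration levels; sample concentrations are read off the inverted line and
censored below the analyte's LOQ.  Calibration in blank matrix extract keeps
matrix effects common to standards and samples, and the internal standard
normalises injection-to-injection variability — so a plain straight line is
an adequate response model here.  Unweighted OLS is the default (1/x
weighting is available, as residue laboratories often prefer it at the low
end of the range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .identification import identify_batch
from .records import InjectionRecord
from .registry import PesticideSpec

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "fit_matrix_curve",
    "fit_study_curves",
    "quantify",
    "batch_quantify",
    "R2_FLAG_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Curves with a coefficient of determination below this are flagged.  The
#: default mirrors the weakest in-range value seen in practice for this kind
#: of matrix-matched multi-residue method (≈0.95).
R2_FLAG_THRESHOLD = 0.95


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted response-ratio line for one analyte.

    ``slope`` is in response-ratio units per μg/kg, ``intercept`` in
    response-ratio units, ``r_squared`` the coefficient of determination of
    the fit.
    """

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    levels_used: tuple[float, ...]
    n_points: int
    weighting: str = "none"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError(f"{self.analyte}: calibration needs ≥ 3 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"{self.analyte}: r² out of [0, 1]: {self.r_squared}")

    @property
    def linearity_ok(self) -> bool:
        return self.r_squared >= R2_FLAG_THRESHOLD


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated concentration with censoring state.

    When ``censored`` is true the value is reported only as the bound
    "< LOQ"; ``concentration`` then still holds the raw back-calculated
    number (clamped at 0) for diagnostics, but reports must not print it as
    a measured concentration.
    """

    analyte: str
    concentration: float
    censored: bool
    loq_used: float
    clamped: bool = False

    def __str__(self) -> str:  # report convention
        return f"< {self.loq_used:g}" if self.censored else f"{self.concentration:.3g}"


def fit_matrix_curve(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    weighting: str = "none",
) -> CalibrationCurve:
    """Least-squares fit of response ratio on concentration.

    ``points`` is a sequence of ``(concentration μg/kg, response ratio)``.
    ``weighting="1/x"`` performs weighted least squares with weights 1/x
    (all concentrations must then be positive); ``r_squared`` is always the
    unweighted coefficient of determination of the returned line.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, response_ratio) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("calibration requires at least 3 distinct concentrations")
    if np.ptp(x) == 0:
        raise ValueError("zero concentration variance")
    if weighting == "none":
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / x
        sw = w.sum()
        xbar = (w * x).sum() / sw
        ybar = (w * y).sum() / sw
        slope = float((w * (x - xbar) * (y - ybar)).sum() / (w * (x - xbar) ** 2).sum())
        intercept = float(ybar - slope * xbar)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    resid = y - (intercept + slope * x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        levels_used=tuple(sorted(set(x.tolist()))),
        n_points=len(x),
        weighting=weighting,
    )


def fit_study_curves(
    records: Iterable[InjectionRecord],
    weighting: str = "none",
) -> dict[str, CalibrationCurve]:
    """Fit one curve per analyte from the calibration injections of a batch."""
    pts: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        if r.role != "calib":
            continue
        pts.setdefault(r.analyte, []).append((r.level_ug_kg, r.response_ratio))
    return {a: fit_matrix_curve(p, analyte=a, weighting=weighting) for a, p in pts.items()}


def quantify(
    record: InjectionRecord,
    curve: CalibrationCurve,
    spec: PesticideSpec,
) -> QuantResult:
    """Invert the calibration line for one injection and apply LOQ censoring.

    Negative back-calculations (possible for blank-level noise) are clamped
    to 0 and censored, with the ``clamped`` flag set.
    """
    if record.analyte != curve.analyte and curve.analyte:
        raise ValueError(f"record {record.analyte!r} does not match curve {curve.analyte!r}")
    if record.analyte != spec.name:
        raise ValueError(f"record {record.analyte!r} does not match spec {spec.name!r}")
    if curve.slope == 0:
        raise ZeroDivisionError(f"{record.analyte}: calibration slope is zero")
    conc = (record.response_ratio - curve.intercept) / curve.slope
    clamped = conc < 0
    if clamped:
        conc = 0.0
    return QuantResult(
        analyte=record.analyte,
        concentration=conc,
        censored=clamped or conc < spec.loq,
        loq_used=spec.loq,
        clamped=clamped,
    )


class QuantBatch(NamedTuple):
    """Result of :func:`batch_quantify`: the concentration table plus an
    exclusions report (injections skipped and why)."""

    table: pd.DataFrame
    exclusions: pd.DataFrame


_TABLE_COLUMNS = [
    "analyte",
    "role",
    "level_ug_kg",
    "replicate",
    "day",
    "conc_ug_kg",
    "censored",
    "loq_ug_kg",
]
_EXCL_COLUMNS = ["analyte", "role", "level_ug_kg", "replicate", "reason"]


def batch_quantify(
    records: Iterable[InjectionRecord],
    curves: Mapping[str, CalibrationCurve],
    registry: Mapping[str, PesticideSpec],
    require_identified: bool = True,
) -> QuantBatch:
    """Quantify every non-calibration injection of a batch.

    Injections failing the identification criteria are excluded (unless
    ``require_identified`` is false), as are analytes without a calibration
    curve; both are listed in the exclusions report rather than raising.
    """
    records = list(records)
    identified: dict[tuple, bool] = {}
    if require_identified:
        report = identify_batch(records, registry)
        for row in report.itertuples(index=False):
            key = (row.analyte, row.role, row.level_ug_kg, row.replicate)
            identified[key] = bool(row.identified)
    rows, excluded = [], []
    for r in records:
        if r.role == "calib":
            continue
        key = (r.analyte, r.role, r.level_ug_kg, r.replicate)
        if require_identified and not identified.get(key, False):
            excluded.append(
                dict(analyte=r.analyte, role=r.role, level_ug_kg=r.level_ug_kg,
                     replicate=r.replicate, reason="not identified")
            )
            continue
        if r.analyte not in curves:
            excluded.append(
                dict(analyte=r.analyte, role=r.role, level_ug_kg=r.level_ug_kg,
                     replicate=r.replicate, reason="no calibration curve")
            )
            continue
        q = quantify(r, curves[r.analyte], registry[r.analyte])
        rows.append(
            dict(
                analyte=r.analyte,
                role=r.role,
                level_ug_kg=r.level_ug_kg,
                replicate=r.replicate,
                day=r.day,
                conc_ug_kg=q.concentration,
                censored=q.censored,
                loq_ug_kg=q.loq_used,
            )
        )
    for e in excluded:
        logger.info("excluded %(analyte)s (%(role)s, level %(level_ug_kg)s): %(reason)s", e)
    return QuantBatch(
        table=pd.DataFrame(rows, columns=_TABLE_COLUMNS),
        exclusions=pd.DataFrame(excluded, columns=_EXCL_COLUMNS),
    )
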