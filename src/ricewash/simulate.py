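"""Seeded synthetic residue studies with known ground truth.

The generator emulates the designs of the washing study so every downstream
stage can be tested against a known truth: a 10-level matrix-matched
calibration series (5–100 μg/kg), spike/recovery batches at 5, 10 and
50 μg/kg with five replicates on each of three days, and paired
washing experiments at nominal 20 and 50 μg/kg with three replicates and a
per-analyte true processing factor.

Noise model
-----------
All measurement noise is multiplicative lognormal on peak areas, scaled so
that a requested coefficient of variation ``cv`` is the CV of the resulting
factor and its mean is exactly 1 (``sigma² = ln(1 + cv²)``, ``mu = −sigma²/2``).
Concentration scatter in residue data is scale-proportional, and a
multiplicative model keeps areas positive.  Repeatability noise (default
CV 7 %) applies within a day; a between-day factor with
``cv_day = sqrt(cv_R² − cv_r²)`` lifts the pooled scatter to the
reproducibility CV (default 12 %).  The qualifier transition receives its
own independent multiplicative noise, so realized ion ratios fluctuate
around the analyte's true ratio.  Retention times jitter around the
reference with Gaussian noise (default SD 0.02 min).

Contamination in the washing experiment takes up only part of the nominal
level: the unprocessed true mean is ``nominal × uptake`` with uptake 0.65 by
default, mirroring that measured unprocessed means in this kind of
soak-contamination design sit well below nominal (sun-drying and surface
losses); the washed true mean is the unprocessed mean times the analyte's
true processing factor.

Randomness is driven by a single root seed with per-analyte, per-purpose
child streams, so adding an analyte to a study does not shift the draws of
the others.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import InjectionRecord, records_to_frame
from .registry import PesticideRegistry, PesticideSpec, UnknownAnalyteError

__all__ = [
    "GENERATOR_VERSION",
    "SimConfig",
    "SyntheticStudy",
    "lognormal_factor",
    "simulate_injection",
    "make_calibration_series",
    "make_spike_batches",
    "make_washing_experiment",
    "simulate_study",
]

GENERATOR_VERSION = "1"

#: The 10 matrix-matched calibration levels, μg/kg.
DEFAULT_CALIB_LEVELS = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 100.0)
DEFAULT_SPIKE_LEVELS = (5.0, 10.0, 50.0)
DEFAULT_WASH_LEVELS = (20.0, 50.0)


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic study.

    Per-analyte parameters (``true_recovery``, ``true_pf``, ``ir_true``,
    ``response_slope``, ``rt_ref``) accept a scalar (applied to every
    analyte), a ``{analyte: value}`` mapping, or ``None`` for built-in
    defaults spread deterministically across the analyte list:
    recoveries span 0.70–1.19 (the validated method's observed range),
    true processing factors span 0.70–1.00 at the 20 μg/kg level and
    0.27–1.00 at 50 μg/kg (the printed PF ranges), ion ratios span
    20–80 %, and reference retention times 2–12 min across the gradient.
    ``true_pf`` may also map an analyte to a ``{level: pf}`` dict.
    """

    seed: int
    analytes: tuple[str, ...]
    calib_levels: tuple[float, ...] = DEFAULT_CALIB_LEVELS
    spike_levels: tuple[float, ...] = DEFAULT_SPIKE_LEVELS
    n_spike_reps: int = 5
    n_days: int = 3
    wash_levels: tuple[float, ...] = DEFAULT_WASH_LEVELS
    n_wash_reps: int = 3
    true_recovery: object = None
    true_pf: object = None
    cv_repeatability: float = 0.07
    cv_reproducibility: float = 0.12
    rt_jitter_sd: float = 0.02
    ir_true: object = None
    response_slope: object = 0.02
    rt_ref: object = None
    uptake_factor: float = 0.65
    is_area: float = 1.0e5

    def __post_init__(self) -> None:
        object.__setattr__(self, "analytes", tuple(self.analytes))
        object.__setattr__(self, "calib_levels", tuple(float(x) for x in self.calib_levels))
        object.__setattr__(self, "spike_levels", tuple(float(x) for x in self.spike_levels))
        object.__setattr__(self, "wash_levels", tuple(float(x) for x in self.wash_levels))
        if not self.analytes:
            raise ValueError("at least one analyte required")
        for cv in (self.cv_repeatability, self.cv_reproducibility):
            if cv < 0:
                raise ValueError("CVs must be non-negative")
        if self.cv_reproducibility < self.cv_repeatability:
            raise ValueError("reproducibility CV cannot be below repeatability CV")
        if any(b >= a for b, a in zip(self.calib_levels, self.calib_levels[1:])):
            raise ValueError("calibration levels must be strictly increasing")
        if self.n_wash_reps < 2:
            raise ValueError("washing needs at least 2 replicates")
        if self.n_spike_reps < 2:
            raise ValueError("spiking needs at least 2 replicates")
        if self.rt_jitter_sd < 0:
            raise ValueError("RT jitter SD must be non-negative")
        if not 0 < self.uptake_factor <= 1.5:
            raise ValueError("uptake factor out of plausible range (0, 1.5]")
        for a in self.analytes:
            for lvl in self.wash_levels:
                pf = self.pf_for(a, lvl)
                if not 0 <= pf <= 1.2:
                    raise ValueError(f"true PF for {a} at {lvl} out of [0, 1.2]: {pf}")

    # -- per-analyte parameter resolution ---------------------------------

    def _spread(self, analyte: str, lo: float, hi: float) -> float:
        i = self.analytes.index(analyte)
        n = len(self.analytes)
        return lo if n == 1 else lo + (hi - lo) * i / (n - 1)

    def _resolve(self, value, analyte: str, default_lo: float, default_hi: float) -> float:
        if value is None:
            return self._spread(analyte, default_lo, default_hi)
        if isinstance(value, Mapping):
            return float(value[analyte])
        return float(value)

    def recovery_for(self, analyte: str) -> float:
        return self._resolve(self.true_recovery, analyte, 0.70, 1.19)

    def ir_for(self, analyte: str) -> float:
        return self._resolve(self.ir_true, analyte, 20.0, 80.0)

    def slope_for(self, analyte: str) -> float:
        return self._resolve(self.response_slope, analyte, 0.02, 0.02)

    def rt_for(self, analyte: str) -> float:
        return self._resolve(self.rt_ref, analyte, 2.0, 12.0)

    def pf_for(self, analyte: str, level: float) -> float:
        if self.true_pf is None:
            lo = 0.70 if level <= 20 else 0.27
            return self._spread(analyte, lo, 1.00)
        if isinstance(self.true_pf, Mapping):
            v = self.true_pf[analyte]
            if isinstance(v, Mapping):
                return float(v[level])
            return float(v)
        return float(self.true_pf)

    # -- plain-text round trip -------------------------------------------

    def to_text(self) -> str:
        lines = [f"seed={self.seed}", "analytes=" + ",".join(self.analytes)]
        for key in (
            "calib_levels", "spike_levels", "wash_levels",
        ):
            lines.append(f"{key}=" + ",".join(f"{v:g}" for v in getattr(self, key)))
        for key in (
            "n_spike_reps", "n_days", "n_wash_reps",
            "cv_repeatability", "cv_reproducibility", "rt_jitter_sd",
            "uptake_factor", "is_area",
        ):
            lines.append(f"{key}={getattr(self, key):g}")
        for key in ("true_recovery", "true_pf", "ir_true", "response_slope", "rt_ref"):
            val = getattr(self, key)
            if val is None:
                continue
            if isinstance(val, Mapping):
                enc = ";".join(
                    f"{a}:{v}" if not isinstance(v, Mapping)
                    else f"{a}:" + "|".join(f"{l}>{p}" for l, p in v.items())
                    for a, v in val.items()
                )
                lines.append(f"{key}={enc}")
            else:
                lines.append(f"{key}={val:g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SimConfig":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        def floats(s): return tuple(float(x) for x in s.split(","))
        def per_analyte(s):
            if ";" not in s and ":" not in s:
                return float(s)
            out = {}
            for part in s.split(";"):
                a, _, v = part.partition(":")
                if "|" in v or ">" in v:
                    out[a] = {float(l): float(p) for l, p in
                              (item.split(">") for item in v.split("|"))}
                else:
                    out[a] = float(v)
            return out
        kwargs: dict = dict(seed=int(kv["seed"]), analytes=tuple(kv["analytes"].split(",")))
        for key, conv in [
            ("calib_levels", floats), ("spike_levels", floats), ("wash_levels", floats),
            ("n_spike_reps", int), ("n_days", int), ("n_wash_reps", int),
            ("cv_repeatability", float), ("cv_reproducibility", float),
            ("rt_jitter_sd", float), ("uptake_factor", float), ("is_area", float),
            ("true_recovery", per_analyte), ("true_pf", per_analyte),
            ("ir_true", per_analyte), ("response_slope", per_analyte),
            ("rt_ref", per_analyte),
        ]:
            if key in kv:
                kwargs[key] = conv(kv[key])
        return cls(**kwargs)


def child_rng(seed: int, analyte: str, purpose: str) -> np.random.Generator:
    """Independent, reproducible stream for one analyte and purpose."""
    key = (zlib.crc32(analyte.encode()), zlib.crc32(purpose.encode()))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and coefficient of variation ``cv``."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_injection(
    spec: PesticideSpec,
    true_conc: float,
    cv: float,
    rng: np.random.Generator,
    *,
    slope: float = 0.02,
    ir_true: float = 50.0,
    is_area: float = 1.0e5,
    rt_jitter_sd: float = 0.02,
    role: str = "sample",
    level: float = float("nan"),
    replicate: int = 1,
    day: int = 1,
) -> InjectionRecord:
    """One synthetic injection of ``spec`` at a known true concentration.

    The quantifier area is ``slope · true_conc · IS_area`` times a lognormal
    factor of CV ``cv``; the qualifier area is the quantifier times
    ``ir_true/100`` with its own independent noise of the same CV, so the
    realized ion ratio fluctuates around ``ir_true``.  RT is the reference
    RT plus Gaussian jitter.  Three draws are consumed per call regardless
    of the CVs, keeping streams aligned across configurations.
    """
    if true_conc < 0:
        raise ValueError("true concentration must be non-negative")
    if spec.rt_mean_calibration is None:
        raise ValueError(f"{spec.name}: reference RT not set")
    noise_q = float(lognormal_factor(rng, cv))
    noise_ir = float(lognormal_factor(rng, cv))
    jitter = float(rng.normal(0.0, 1.0)) * rt_jitter_sd
    area_quant = slope * true_conc * is_area * noise_q
    area_qual = area_quant * (ir_true / 100.0) * noise_ir
    return InjectionRecord(
        analyte=spec.name,
        rt_min=spec.rt_mean_calibration + jitter,
        area_quant=area_quant,
        area_qual=area_qual,
        area_is=is_area,
        role=role,
        level_ug_kg=true_conc if math.isnan(level) else level,
        replicate=replicate,
        day=day,
    )


def make_calibration_series(
    spec: PesticideSpec,
    levels: Sequence[float],
    rng: np.random.Generator,
    cv: float = 0.0,
    **inj_kwargs,
) -> list[InjectionRecord]:
    """One calibration injection per level (role ``"calib"``).

    The matrix-matched construction (1:1 blank-extract dilution plus
    internal-standard addition) is a pure relabeling here: the nominal level
    of each standard is the stated matrix level.  Levels outside the spec's
    linear range are flagged ``in_range=False``; levels beyond twice the
    range maximum raise a warning flag rather than an error.
    """
    levels = [float(l) for l in levels]
    if not levels:
        raise ValueError("calibration needs at least one level")
    if any(l <= 0 for l in levels):
        raise ValueError("calibration levels must be positive")
    low, high = spec.linear_range
    records = []
    for i, lvl in enumerate(levels, start=1):
        rec = simulate_injection(
            spec, lvl, cv, rng, role="calib", level=lvl, replicate=i, **inj_kwargs
        )
        in_range = low <= lvl <= high
        if lvl > 2 * high:
            import warnings

            warnings.warn(
                f"{spec.name}: calibration level {lvl} exceeds twice the range maximum",
                stacklevel=2,
            )
        records.append(dataclasses.replace(rec, in_range=in_range))
    return records


def make_spike_batches(
    spec: PesticideSpec,
    level: float,
    true_recovery: float,
    rng: np.random.Generator,
    n_reps: int = 5,
    n_days: int = 3,
    cv_r: float = 0.07,
    cv_R: float = 0.12,
    **inj_kwargs,
) -> list[list[InjectionRecord]]:
    """Spike/recovery batches: ``n_days`` days × ``n_reps`` replicates.

    The true concentration recovered from the matrix is
    ``level × true_recovery``; each day carries a common multiplicative
    day factor with CV ``sqrt(cv_R² − cv_r²)`` and each replicate its own
    repeatability noise, so pooled scatter approaches ``cv_R``.
    """
    if cv_R < cv_r:
        raise ValueError("cv_R must be at least cv_r")
    cv_day = math.sqrt(max(cv_R * cv_R - cv_r * cv_r, 0.0))
    batches = []
    for day in range(1, n_days + 1):
        day_factor = float(lognormal_factor(rng, cv_day))
        batch = [
            simulate_injection(
                spec,
                level * true_recovery * day_factor,
                cv_r,
                rng,
                role="spike",
                level=level,
                replicate=rep,
                day=day,
                **inj_kwargs,
            )
            for rep in range(1, n_reps + 1)
        ]
        batches.append(batch)
    return batches


def make_washing_experiment(
    spec: PesticideSpec,
    nominal_level: float,
    pf_true: float,
    rng: np.random.Generator,
    n_reps: int = 3,
    cv: float = 0.07,
    uptake: float = 0.65,
    **inj_kwargs,
) -> tuple[list[InjectionRecord], list[InjectionRecord]]:
    """Paired unprocessed/washed replicate sets for one contamination level.

    The unprocessed true mean is ``nominal_level × uptake`` (measured
    unprocessed means sit below nominal in this design); the washed true
    mean is that times ``pf_true``.  Both sets carry replicate noise.
    """
    if pf_true < 0:
        raise ValueError("true PF must be non-negative")
    if n_reps < 2:
        raise ValueError("washing needs at least 2 replicates")
    cb_true = nominal_level * uptake
    ca_true = cb_true * pf_true
    before = [
        simulate_injection(spec, cb_true, cv, rng, role="wash_before",
                           level=nominal_level, replicate=rep, **inj_kwargs)
        for rep in range(1, n_reps + 1)
    ]
    after = [
        simulate_injection(spec, ca_true, cv, rng, role="wash_after",
                           level=nominal_level, replicate=rep, **inj_kwargs)
        for rep in range(1, n_reps + 1)
    ]
    return before, after


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete simulated study: config echo, truth table, injections.

    ``truth`` is a tidy table with one row per (analyte, design point):
    columns ``analyte, kind, level_ug_kg, true_conc_ug_kg, true_pf,
    true_recovery``.  Regenerating with the same config yields identical
    truth and injections.
    """

    config: SimConfig
    registry: PesticideRegistry
    truth: pd.DataFrame
    injections: list[InjectionRecord]
    provenance: dict

    def injections_frame(self) -> pd.DataFrame:
        return records_to_frame(self.injections)

    def write(self, out_dir) -> dict[str, Path]:
        """Write injections.csv, truth.csv and config.txt; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "injections": out / "injections.csv",
            "truth": out / "truth.csv",
            "config": out / "config.txt",
        }
        self.injections_frame().to_csv(paths["injections"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        paths["config"].write_text(self.config.to_text())
        return paths


def simulate_study(
    config: SimConfig,
    registry: PesticideRegistry | None = None,
) -> SyntheticStudy:
    """Generate the full study described by ``config``.

    Registry entries provide LOQ and linear range; analytes missing from the
    registry raise.  Reference RTs and true ion ratios are filled into the
    study's own registry copy so identification can run against it directly.
    """
    if registry is None:
        from .registry import default_registry

        registry = default_registry()
    for a in config.analytes:
        if a not in registry:
            raise UnknownAnalyteError(a)

    study_specs = []
    injections: list[InjectionRecord] = []
    truth_rows = []
    for analyte in config.analytes:
        spec = registry[analyte].with_calibration_reference(
            rt_mean=config.rt_for(analyte), ir_mean=config.ir_for(analyte)
        )
        study_specs.append(spec)
        common = dict(
            slope=config.slope_for(analyte),
            ir_true=config.ir_for(analyte),
            is_area=config.is_area,
            rt_jitter_sd=config.rt_jitter_sd,
        )
        injections.extend(
            make_calibration_series(
                spec, config.calib_levels,
                child_rng(config.seed, analyte, "calib"),
                cv=config.cv_repeatability, **common,
            )
        )
        recovery = config.recovery_for(analyte)
        for level in config.spike_levels:
            batches = make_spike_batches(
                spec, level, recovery,
                child_rng(config.seed, analyte, f"spike-{level:g}"),
                n_reps=config.n_spike_reps, n_days=config.n_days,
                cv_r=config.cv_repeatability, cv_R=config.cv_reproducibility,
                **common,
            )
            for batch in batches:
                injections.extend(batch)
            truth_rows.append(
                dict(analyte=analyte, kind="spike", level_ug_kg=level,
                     true_conc_ug_kg=level * recovery, true_pf=np.nan,
                     true_recovery=recovery)
            )
        for level in config.wash_levels:
            pf = config.pf_for(analyte, level)
            before, after = make_washing_experiment(
                spec, level, pf,
                child_rng(config.seed, analyte, f"wash-{level:g}"),
                n_reps=config.n_wash_reps, cv=config.cv_repeatability,
                uptake=config.uptake_factor, **common,
            )
            injections.extend(before)
            injections.extend(after)
            cb_true = level * config.uptake_factor
            truth_rows.append(
                dict(analyte=analyte, kind="wash_before", level_ug_kg=level,
                     true_conc_ug_kg=cb_true, true_pf=pf, true_recovery=np.nan)
            )
            truth_rows.append(
                dict(analyte=analyte, kind="wash_after", level_ug_kg=level,
                     true_conc_ug_kg=cb_true * pf, true_pf=pf, true_recovery=np.nan)
            )

    return SyntheticStudy(
        config=config,
        registry=PesticideRegistry(study_specs),
        truth=pd.DataFrame(truth_rows),
        injections=injections,
        provenance=dict(seed=config.seed, generator_version=GENERATOR_VERSION),
    )
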