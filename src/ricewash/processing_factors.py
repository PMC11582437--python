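"""Washing-effect analysis: processing factors, reductions, significance.

The effect of washing on each pesticide is summarised by the processing
factor

    PF = Ca / Cb,

the ratio of the mean residue concentration in washed (Ca) to unprocessed
(Cb) rice — a ratio of group means, not a mean of per-replicate ratios.
PF < 1 signals reduction, PF > 1 an increase.  The percent reduction is
%Re = 100·(1 − PF).

Censoring conventions follow the study's reporting:

* washed mean below LOQ, unprocessed quantifiable — the reduction is only
  known to be at least ``100·(1 − LOQ/Cb)``, reported as a "> x" minimal
  bound;
* both means below LOQ — PF and reduction are undefined ("–").

Significance of the before/after difference is a two-tailed two-sample
Student's t-test with pooled variance, applied after Shapiro–Wilk normality
checks on each group and Levene's homogeneity-of-variance check (computed
around group means, matching common statistical packages); when Levene
fails, Welch's t is used as a flagged fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import PesticideSpec

__all__ = [
    "PFResult",
    "ReductionSummary",
    "compute_pf",
    "compute_reduction",
    "minimal_reduction_bound",
    "compare_groups",
    "summary_ttest",
    "build_pf_table",
    "pf_table_from_summaries",
    "summarize_reductions",
    "pf_results_to_frame",
]

DEFAULT_ALPHA = 0.05
#: Reduction bin edges in percent for the summary histogram.
DEFAULT_BINS = (20.0, 40.0, 60.0)


def compute_pf(ca_mean: float, cb_mean: float) -> float:
    """Processing factor Ca/Cb (washed over unprocessed mean)."""
    if cb_mean <= 0:
        raise ValueError("unprocessed mean must be positive for a defined PF")
    if ca_mean < 0:
        raise ValueError("washed mean must be non-negative")
    return ca_mean / cb_mean


def compute_reduction(ca_mean: float, cb_mean: float) -> float:
    """Percent reduction 100·(1 − Ca/Cb); negative when residues increase."""
    return 100.0 * (1.0 - compute_pf(ca_mean, cb_mean))


def minimal_reduction_bound(cb_mean: float, loq: float) -> float:
    """Minimal percent reduction when the washed sample is censored.

    With the washed concentration known only to lie below the LOQ, the
    reduction is at least ``100·(1 − LOQ/Cb)``.  Requires ``cb_mean > loq``;
    otherwise the bound is non-positive and carries no information.
    """
    if loq <= 0:
        raise ValueError("LOQ must be positive")
    if cb_mean < loq:
        raise ValueError(
            f"uninformative bound: unprocessed mean {cb_mean} below LOQ {loq}"
        )
    return 100.0 * (1.0 - loq / cb_mean)


# ---------------------------------------------------------------------------
# significance testing


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    p_value: float
    significant: bool
    normality_ok: bool
    variance_ok: bool
    welch_used: bool


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Pooled-variance Student's t from summary statistics.

    Returns ``(t, df, p)`` for a two-tailed test.  Lets published
    mean ± SD (n) rows be re-tested without raw replicates; equals the
    raw-replicate pooled t whenever the summaries derive from those
    replicates.  Both SDs zero: p = 1 for equal means, p = 0 (t = ±inf)
    otherwise.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n ≥ 2")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, float(df), 1.0
        return math.copysign(float("inf"), mean1 - mean2), float(df), 0.0
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t), float(df), float(p)


def compare_groups(
    before: Sequence[float],
    after: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """Test whether washing changed the concentration.

    Shapiro–Wilk on each group and Levene's test (center='mean') across the
    groups are run at ``alpha``; if variances are homogeneous the pooled
    Student's t is used, otherwise Welch's t with the comparison flagged.
    Significance is declared at ``p < alpha``.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size < 2 or a.size < 2:
        raise ValueError("each group needs n ≥ 2")
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must lie in [0, 1]")

    var_b, var_a = b.var(ddof=1), a.var(ddof=1)
    if var_b == 0 and var_a == 0:
        equal = b.mean() == a.mean()
        t = 0.0 if equal else math.copysign(float("inf"), b.mean() - a.mean())
        p = 1.0 if equal else 0.0
        return GroupComparison(t, float(b.size + a.size - 2), p, p < alpha,
                               True, True, False)

    def _shapiro_ok(x: np.ndarray) -> bool:
        if x.var(ddof=1) == 0 or x.size < 3:
            return True  # degenerate or too small to test; do not block the t-test
        return stats.shapiro(x).pvalue >= alpha

    normality_ok = _shapiro_ok(b) and _shapiro_ok(a)
    variance_ok = stats.levene(b, a, center="mean").pvalue >= alpha
    welch = not variance_ok
    t, p = stats.ttest_ind(b, a, equal_var=not welch)
    df = (b.size + a.size - 2) if not welch else _welch_df(var_b, b.size, var_a, a.size)
    return GroupComparison(float(t), float(df), float(p), bool(p < alpha),
                           normality_ok, variance_ok, welch)


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


# ---------------------------------------------------------------------------
# per-analyte washing outcome


@dataclass(frozen=True)
class PFResult:
    """Washing outcome for one analyte at one contamination level.

    ``pf`` and ``reduction_pct`` are ``None`` when undefined (unprocessed
    sample censored).  ``is_bound`` marks a censored washed sample whose
    reduction is reported as the minimal bound "> reduction_pct".
    """

    analyte: str
    level: float
    n: int
    cb_mean: float | None
    cb_sd: float | None
    ca_mean: float | None
    ca_sd: float | None
    cb_censored: bool
    ca_censored: bool
    pf: float | None
    reduction_pct: float | None
    is_bound: bool
    p_value: float | None
    significant: bool
    loq_used: float | None = None
    flags: tuple[str, ...] = ()

    def reduction_label(self) -> str:
        """The table-style rendering: number, "> x" bound, or "–"."""
        if self.reduction_pct is None:
            return "–"
        txt = f"{self.reduction_pct:.3g}"
        return f"> {txt}" if self.is_bound else txt

    def pf_label(self) -> str:
        return "–" if self.pf is None else f"{self.pf:.2f}"


def _pf_row(
    analyte: str,
    level: float,
    n: int,
    cb_mean: float | None,
    cb_sd: float | None,
    cb_censored: bool,
    ca_mean: float | None,
    ca_sd: float | None,
    ca_censored: bool,
    loq: float | None,
    p_value: float | None,
    significant: bool,
    flags: tuple[str, ...],
) -> PFResult:
    pf = red = None
    is_bound = False
    if cb_censored:
        pass  # both PF and reduction undefined, even if washed is quantifiable
    elif ca_censored:
        if loq is not None and cb_mean is not None and cb_mean > loq:
            red = minimal_reduction_bound(cb_mean, loq)
            is_bound = True
        else:
            flags = flags + ("uninformative bound",)
    else:
        pf = compute_pf(ca_mean, cb_mean)
        red = compute_reduction(ca_mean, cb_mean)
    return PFResult(
        analyte=analyte, level=level, n=n,
        cb_mean=cb_mean, cb_sd=cb_sd, ca_mean=ca_mean, ca_sd=ca_sd,
        cb_censored=cb_censored, ca_censored=ca_censored,
        pf=pf, reduction_pct=red, is_bound=is_bound,
        p_value=p_value, significant=significant,
        loq_used=loq, flags=flags,
    )


def build_pf_table(
    conc_table: pd.DataFrame,
    registry: Mapping[str, PesticideSpec],
    alpha: float = DEFAULT_ALPHA,
    loq_overrides: Mapping[str, float] | None = None,
) -> list[PFResult]:
    """Washing outcomes from a replicate-level concentration table.

    ``conc_table`` is the long table produced by quantification, with roles
    ``wash_before`` / ``wash_after`` and columns ``analyte, role,
    level_ug_kg, replicate, conc_ug_kg, censored, loq_ug_kg``.  A group is
    reported censored when its mean back-calculated concentration falls
    below the LOQ.  Significance comes from :func:`compare_groups` on the
    raw replicate values and is only defined when neither group is censored.
    """
    overrides = dict(loq_overrides or {})
    wash = conc_table[conc_table.role.isin(["wash_before", "wash_after"])]
    results: list[PFResult] = []
    for (analyte, level), grp in wash.groupby(["analyte", "level_ug_kg"], sort=True):
        before = grp[grp.role == "wash_before"].conc_ug_kg.to_numpy(float)
        after = grp[grp.role == "wash_after"].conc_ug_kg.to_numpy(float)
        loq = overrides.get(analyte, registry[analyte].loq)
        flags: tuple[str, ...] = ()
        if len(before) < 2 or len(after) < 2:
            flags = ("incomplete replicates",)
        cb_cens = len(before) == 0 or before.mean() < loq
        ca_cens = len(after) == 0 or after.mean() < loq
        p_value = None
        significant = False
        if not cb_cens and not ca_cens and len(before) >= 2 and len(after) >= 2:
            cmp = compare_groups(before, after, alpha=alpha)
            p_value, significant = cmp.p_value, cmp.significant
            if cmp.welch_used:
                flags = flags + ("welch",)
        results.append(
            _pf_row(
                analyte, float(level), int(min(len(before), len(after))),
                float(before.mean()) if len(before) else None,
                float(before.std(ddof=1)) if len(before) > 1 else None,
                cb_cens,
                float(after.mean()) if len(after) else None,
                float(after.std(ddof=1)) if len(after) > 1 else None,
                ca_cens,
                loq, p_value, significant, flags,
            )
        )
    return results


_SUMMARY_COLUMNS = [
    "pesticide", "level_ug_kg", "n",
    "cb_mean", "cb_sd", "cb_censored",
    "ca_mean", "ca_sd", "ca_censored",
]


def pf_table_from_summaries(
    summaries: pd.DataFrame,
    registry: Mapping[str, PesticideSpec],
    alpha: float = DEFAULT_ALPHA,
    loq_overrides: Mapping[str, float] | None = None,
) -> list[PFResult]:
    """Washing outcomes from published mean ± SD rows (no raw replicates).

    ``summaries`` needs the columns ``pesticide, level_ug_kg, n, cb_mean,
    cb_sd, cb_censored, ca_mean, ca_sd, ca_censored``.  Significance uses
    the summary-statistic pooled t-test.  Analytes absent from the registry
    get no LOQ (their censored-washed rows carry no bound) unless an
    override provides one.
    """
    missing = [c for c in _SUMMARY_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"summary table is missing columns: {missing}")
    overrides = dict(loq_overrides or {})
    results: list[PFResult] = []
    for row in summaries.itertuples(index=False):
        name = row.pesticide
        if name in overrides:
            loq = overrides[name]
        elif name in registry:
            loq = registry[name].loq
        else:
            loq = None
        cb_cens, ca_cens = bool(row.cb_censored), bool(row.ca_censored)
        p_value = None
        significant = False
        if not cb_cens and not ca_cens:
            _, _, p_value = summary_ttest(
                float(row.cb_mean), float(row.cb_sd), int(row.n),
                float(row.ca_mean), float(row.ca_sd), int(row.n),
            )
            significant = p_value < alpha
        results.append(
            _pf_row(
                name, float(row.level_ug_kg), int(row.n),
                None if cb_cens else float(row.cb_mean),
                None if cb_cens else float(row.cb_sd),
                cb_cens,
                None if ca_cens else float(row.ca_mean),
                None if ca_cens else float(row.ca_sd),
                ca_cens,
                loq, p_value, significant,
                () if name in registry or loq is not None else ("not in registry",),
            )
        )
    return results


# ---------------------------------------------------------------------------
# aggregate summary


@dataclass(frozen=True)
class ReductionSummary:
    """Binned counts of percent reductions across analytes.

    Censored "> x" bounds are excluded from the bin counts and fractions
    (their exact reduction is unknown) and reported as a separate stratum;
    rows with undefined reduction are counted in ``n_undefined``.  Fractions
    are over ``n_numeric`` only.
    """

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_numeric: int
    n_bounds: int
    n_undefined: int

    @property
    def labels(self) -> tuple[str, ...]:
        edges = self.bin_edges
        labels = [f"< {edges[0]:g}"]
        labels += [f"{lo:g}–{hi:g}" for lo, hi in zip(edges, edges[1:])]
        labels.append(f"> {edges[-1]:g}")
        return tuple(labels)

    @property
    def fractions(self) -> tuple[float, ...]:
        if self.n_numeric == 0:
            return tuple(0.0 for _ in self.counts)
        return tuple(c / self.n_numeric for c in self.counts)

    def fraction(self, label: str) -> float:
        return dict(zip(self.labels, self.fractions))[label]


def summarize_reductions(
    pf_results: Sequence[PFResult],
    bins: Sequence[float] = DEFAULT_BINS,
) -> ReductionSummary:
    """Histogram of numeric reductions over analytes.

    ``bins`` are interior edges, e.g. (20, 40, 60) gives the bins
    <20, [20, 40), [40, 60) and ≥60 percent.
    """
    edges = tuple(float(b) for b in bins)
    if any(nxt <= prev for prev, nxt in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    counts = [0] * (len(edges) + 1)
    n_numeric = n_bounds = n_undefined = 0
    for r in pf_results:
        if r.reduction_pct is None:
            n_undefined += 1
        elif r.is_bound:
            n_bounds += 1
        else:
            n_numeric += 1
            counts[int(np.searchsorted(edges, r.reduction_pct, side="right"))] += 1
    return ReductionSummary(
        bin_edges=edges,
        counts=tuple(counts),
        n_numeric=n_numeric,
        n_bounds=n_bounds,
        n_undefined=n_undefined,
    )


def pf_results_to_frame(results: Sequence[PFResult]) -> pd.DataFrame:
    """PF report table mirroring the published layout (plus flags)."""
    rows = []
    for r in results:
        rows.append(
            dict(
                analyte=r.analyte,
                level_ug_kg=r.level,
                n=r.n,
                cb_mean=r.cb_mean,
                cb_sd=r.cb_sd,
                cb_censored=r.cb_censored,
                ca_mean=r.ca_mean,
                ca_sd=r.ca_sd,
                ca_censored=r.ca_censored,
                pf=r.pf,
                reduction_pct=r.reduction_pct,
                is_bound=r.is_bound,
                pf_label=r.pf_label(),
                reduction_label=r.reduction_label(),
                p_value=r.p_value,
                significant=r.significant,
                loq_used=r.loq_used,
                flags=";".join(r.flags),
            )
        )
    return pd.DataFrame(rows)
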