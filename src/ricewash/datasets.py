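"""Bundled reference tables.

``registry_table.csv`` — the validated rice multi-residue method table
(120 pesticides): linear range, matrix-matched r², LOQ, repeatability and
within-lab reproducibility RSDs, recovery and expanded uncertainty.  Only the
LOQ and linear range are computed on; the remaining columns are reference
metadata.

``washing_20ugkg.csv`` / ``washing_50ugkg.csv`` — summary concentration
tables from the washing study on long-grain rice contaminated at nominal 20
and 50 μg/kg: mean ± SD (n = 3) before and after washing, censoring flags,
the published processing factor / percent reduction / minimal-reduction
bound, and the published significance mark.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_registry_table", "load_washing_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ricewash.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_registry_table() -> pd.DataFrame:
    """Validated-method table, one row per pesticide."""
    return _read("registry_table.csv")


def load_washing_table(level: int) -> pd.DataFrame:
    """Washing-study summary table at contamination ``level`` (20 or 50 μg/kg).

    Columns: ``pesticide, level_ug_kg, n, cb_mean, cb_sd, cb_censored,
    ca_mean, ca_sd, ca_censored, significant, pf_printed, reduction_printed,
    bound_printed``.  ``cb`` is the unprocessed concentration, ``ca`` the
    washed one; censored entries have NaN mean/SD.
    """
    if level not in (20, 50):
        raise ValueError("washing tables exist for levels 20 and 50 μg/kg")
    return _read(f"washing_{level}ugkg.csv")
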