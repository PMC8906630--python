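"""Skin-dose table handling.

During whole-breast radiotherapy the skin dose at each of the four
measurement sites (upper, lower, inner, outer of the nipple) is
measured on the first fraction with a group of three nanoDot OSLD
chips; the triplet is averaged into one site dose in cGy.  This
module builds the per-patient dose table from such triplets, computes
its printed summaries (per-patient means, cohort minimum, which site
tends to receive the least/most dose), and ships the measured doses
of a published 20-patient cohort as a CSV fixture for tests and
examples.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .roi import SITES

__all__ = [
    "average_triplet",
    "patient_mean",
    "build_dose_table",
    "read_dose_table",
    "write_dose_table",
    "reference_dose_table",
    "site_extremes",
    "cohort_min_mean",
]


def average_triplet(readings) -> float:
    """Mean of one OSLD triplet (cGy). Exactly 3 positive readings."""
    r = np.asarray(readings, dtype=float)
    if r.shape != (3,):
        raise ValueError("an OSLD triplet has exactly 3 readings")
    if (r <= 0).any():
        raise ValueError("dose readings must be positive")
    return float(r.mean())


def patient_mean(site_doses) -> float:
    """Arithmetic mean of the four site doses for one patient (cGy)."""
    d = np.asarray(site_doses, dtype=float)
    if d.shape != (4,):
        raise ValueError("expected doses for exactly 4 sites")
    if np.isnan(d).any():
        raise ValueError("missing site dose")
    return float(d.mean())


def build_dose_table(triplets: pd.DataFrame) -> pd.DataFrame:
    """Dose table from raw triplet readings.

    ``triplets`` needs columns patient_id, site, r1, r2, r3 with one
    row per patient x site.  Returns the standard table layout:
    patient_id, upper, lower, inner, outer, mean.
    """
    required = {"patient_id", "site", "r1", "r2", "r3"}
    if not required.issubset(triplets.columns):
        raise ValueError(f"triplet table needs columns {sorted(required)}")
    rows = []
    for pid, grp in triplets.groupby("patient_id", sort=False):
        doses = {}
        for _, row in grp.iterrows():
            doses[row["site"]] = average_triplet([row["r1"], row["r2"], row["r3"]])
        missing = set(SITES) - doses.keys()
        if missing:
            raise ValueError(f"patient {pid}: missing sites {sorted(missing)}")
        rec = {"patient_id": pid, **{s: doses[s] for s in SITES}}
        rec["mean"] = patient_mean([doses[s] for s in SITES])
        rows.append(rec)
    return pd.DataFrame(rows)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    needed = ["patient_id", *SITES]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"dose table missing columns {missing}")
    table = table.copy()
    if "mean" not in table.columns:
        table["mean"] = table[list(SITES)].mean(axis=1)
    return table


def read_dose_table(path: str | Path) -> pd.DataFrame:
    """Read a dose CSV (``patient_id,upper,lower,inner,outer[,mean]``)."""
    return _validate(pd.read_csv(path))


def write_dose_table(table: pd.DataFrame, path: str | Path) -> None:
    _validate(table).to_csv(path, index=False, float_format="%.1f")


def reference_dose_table() -> pd.DataFrame:
    """Packaged skin-dose table of the published 20-patient cohort."""
    with resources.files("dermachroma.data").joinpath("skin_dose_cohort.csv").open() as fh:
        return _validate(pd.read_csv(fh))


def site_extremes(table: pd.DataFrame) -> dict:
    """Count, per site, how often it is the row minimum / maximum.

    Ties increment every tied site, so minimum counts can sum to more
    than the number of rows.  Also reports how often the row maximum
    lands on the upper or lower site combined, the pattern expected
    from tangential-field dose distributions.
    """
    table = _validate(table)
    if len(table) == 0:
        raise ValueError("dose table is empty")
    doses = table[list(SITES)].to_numpy(dtype=float)
    row_min = doses.min(axis=1, keepdims=True)
    row_max = doses.max(axis=1, keepdims=True)
    min_counts = dict(zip(SITES, (doses == row_min).sum(axis=0).tolist()))
    max_counts = dict(zip(SITES, (doses == row_max).sum(axis=0).tolist()))
    max_upper_or_lower = int(
        ((doses[:, SITES.index("upper")] == row_max[:, 0])
         | (doses[:, SITES.index("lower")] == row_max[:, 0])).sum()
    )
    return {
        "min_counts": min_counts,
        "max_counts": max_counts,
        "max_upper_or_lower": max_upper_or_lower,
        "n_rows": len(table),
    }


def cohort_min_mean(table: pd.DataFrame) -> float:
    """Smallest per-patient mean skin dose in the cohort (cGy)."""
    table = _validate(table)
    if len(table) == 0:
        raise ValueError("dose table is empty")
    return float(table["mean"].min())
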