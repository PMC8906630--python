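"""Study orchestration: images -> parameter records -> report tables.

The analysis mirrors a paired longitudinal design: 20 patients, two
breasts (irradiated and control), four sites per breast, four time
points.  Each image reduces to twelve color parameters; per subject
the four sites are averaged before any statistics (subjects, not
sites, are the repeated unit), and five report tables are produced:

* ``summary`` — mean +/- SD of every parameter per group x time;
* ``anova`` — two-way repeated-measures ANOVA p-values per parameter;
* ``paired`` — Wilcoxon irradiated-vs-control p per parameter x time,
  flagged at the Bonferroni-adjusted level (0.05/3 by default);
* ``dose_corr`` — Spearman of each parameter against skin dose at the
  three post-baseline time points, with entries masked unless p < 0.05;
* ``early_late`` — Spearman of early (7/14-day) values against the
  post-treatment value, per parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import dosimetry, stats
from .color import PARAMETER_NAMES
from .roi import BREASTS, SITES, TIME_POINTS, SkinImage, default_roi, extract_parameters, read_skin_image
from .synthetic import ErythemaModelParams, SyntheticCohort, generate_cohort

__all__ = [
    "extract_all",
    "load_images",
    "site_average",
    "summarize_parameters",
    "anova_table",
    "paired_tests",
    "correlate_dose",
    "correlate_early_late",
    "correlate_rtog",
    "run_study",
]

_KEY = ["patient_id", "breast", "site", "time_point"]


def _safe_spearman(x, y, method: str = "asymptotic"):
    """Spearman that degrades to NaN for constant inputs, so one
    degenerate parameter column cannot abort a whole report table."""
    try:
        res = stats.spearman(x, y, method=method)
        return res.rho, res.p, res.n
    except ValueError:
        return np.nan, np.nan, len(x)

#: Post-baseline time points entering dose-correlation analysis.
POST_TIME_POINTS = ("RT_7days", "RT_14days", "RT_after")


def _check_complete(cells: pd.DataFrame) -> None:
    patients = sorted(cells["patient_id"].unique())
    have = set(map(tuple, cells[_KEY].itertuples(index=False)))
    missing = [
        (p, b, s, t)
        for p in patients
        for b in BREASTS
        for s in SITES
        for t in TIME_POINTS
        if (p, b, s, t) not in have
    ]
    if missing:
        head = ", ".join(map(str, missing[:5]))
        raise ValueError(f"incomplete design: {len(missing)} missing cell(s): {head}")


def extract_all(images: Iterable[SkinImage] | SyntheticCohort) -> pd.DataFrame:
    """Tidy parameter records from a complete image set.

    Returns long-format rows ``patient_id, breast, site, time_point,
    parameter, value`` — 384 values per patient (12 parameters x 4
    sites x 2 breasts x 4 time points).  Raises naming the missing
    design cell if the set is incomplete.
    """
    if isinstance(images, SyntheticCohort):
        images = images.images
    rows = []
    for im in images:
        vec = extract_parameters(im, default_roi(im))
        for name, value in zip(PARAMETER_NAMES, vec):
            rows.append(
                dict(patient_id=im.patient_id, breast=im.breast, site=im.site,
                     time_point=im.time_point, parameter=name, value=float(value))
            )
    if not rows:
        raise ValueError("no images supplied")
    records = pd.DataFrame(rows)
    _check_complete(records[_KEY].drop_duplicates())
    return records


def load_images(image_dir: str | Path) -> list[SkinImage]:
    """Read every PNG/TIFF under the
    ``patient/breast/site/timepoint.png`` layout."""
    image_dir = Path(image_dir)
    paths = sorted(
        p for ext in ("*.png", "*.tif", "*.tiff") for p in image_dir.rglob(ext)
    )
    if not paths:
        raise ValueError(f"no images found under {image_dir}")
    return [read_skin_image(p) for p in paths]


def site_average(records: pd.DataFrame) -> pd.DataFrame:
    """Mean over the four sites: one value per patient x breast x time
    x parameter."""
    return (
        records.groupby(["patient_id", "breast", "time_point", "parameter"], sort=False)[
            "value"
        ]
        .mean()
        .reset_index()
    )


def _wide(site_avg: pd.DataFrame, breast: str, time_point: str, parameter: str) -> pd.Series:
    sel = site_avg[
        (site_avg.breast == breast)
        & (site_avg.time_point == time_point)
        & (site_avg.parameter == parameter)
    ]
    return sel.set_index("patient_id")["value"].sort_index()


def summarize_parameters(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) of the site-averaged value over
    patients, per parameter x group x time point."""
    sa = site_average(records)
    if sa["patient_id"].nunique() < 2:
        raise ValueError("SD undefined with fewer than 2 patients")
    out = (
        sa.groupby(["parameter", "breast", "time_point"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    order = {p: i for i, p in enumerate(PARAMETER_NAMES)}
    out["__o"] = out["parameter"].map(order)
    out = out.sort_values(
        ["__o", "breast", "time_point"],
        key=lambda c: c.map({t: i for i, t in enumerate(TIME_POINTS)}) if c.name == "time_point" else c,
    ).drop(columns="__o")
    return out.reset_index(drop=True)


def anova_table(records: pd.DataFrame, sphericity_alpha: float = 0.05) -> pd.DataFrame:
    """Two-way RM-ANOVA (group x time, both within subject) per
    parameter, on site-averaged values."""
    sa = site_average(records)
    patients = sorted(sa["patient_id"].unique())
    rows = []
    for param in PARAMETER_NAMES:
        y = np.empty((len(patients), len(BREASTS), len(TIME_POINTS)))
        for bi, b in enumerate(BREASTS):
            for ti, t in enumerate(TIME_POINTS):
                y[:, bi, ti] = _wide(sa, b, t, param).reindex(patients).to_numpy()
        for res in stats.rm_anova_two_way(y, sphericity_alpha=sphericity_alpha):
            rows.append(dict(parameter=param, **dataclasses.asdict(res)))
    return pd.DataFrame(rows)


def paired_tests(
    records: pd.DataFrame, family_alpha: float = 0.05, m_comparisons: int = 3
) -> pd.DataFrame:
    """Wilcoxon signed-rank, irradiated vs control, per parameter and
    time point, at the Bonferroni-adjusted level."""
    sa = site_average(records)
    alpha_adj = stats.bonferroni_alpha(family_alpha, m_comparisons)
    rows = []
    for param in PARAMETER_NAMES:
        for t in TIME_POINTS:
            irr = _wide(sa, "irradiated", t, param)
            ctl = _wide(sa, "unirradiated", t, param)
            res = stats.wilcoxon_signed_rank(
                irr.to_numpy(), ctl.reindex(irr.index).to_numpy(), alpha_adjusted=alpha_adj
            )
            rows.append(
                dict(parameter=param, time_point=t, W=res.statistic, p=res.p,
                     n_effective=res.n_effective, significant=res.significant,
                     alpha_adjusted=alpha_adj)
            )
    return pd.DataFrame(rows)


def correlate_dose(
    records: pd.DataFrame,
    dose_table: pd.DataFrame,
    mask_alpha: float = 0.05,
    pairing: str = "patient_mean",
) -> pd.DataFrame:
    """Spearman correlation of irradiated-breast parameter values with
    skin dose at each post-baseline time point.

    ``pairing='patient_mean'`` correlates the site-averaged parameter
    with the patient's mean dose (n = patients); ``'site'`` pairs each
    site's value with that site's dose (n = patients x 4).  ``rho_masked``
    is NaN wherever p >= ``mask_alpha``, mirroring reports that print
    only significant entries.
    """
    dose_table = dose_table.set_index("patient_id")
    rows = []
    if pairing == "patient_mean":
        sa = site_average(records)
        for param in PARAMETER_NAMES:
            for t in POST_TIME_POINTS:
                vals = _wide(sa, "irradiated", t, param)
                if not set(vals.index).issubset(dose_table.index):
                    raise ValueError("patients in records and dose table do not match")
                doses = dose_table["mean"].reindex(vals.index)
                rho, p, n = _safe_spearman(doses.to_numpy(), vals.to_numpy())
                rows.append(dict(parameter=param, time_point=t, rho=rho, p=p, n=n))
    elif pairing == "site":
        irr = records[records.breast == "irradiated"]
        for param in PARAMETER_NAMES:
            for t in POST_TIME_POINTS:
                sel = irr[(irr.parameter == param) & (irr.time_point == t)]
                if not set(sel["patient_id"]).issubset(dose_table.index):
                    raise ValueError("patients in records and dose table do not match")
                doses = [dose_table.loc[p, s] for p, s in zip(sel["patient_id"], sel["site"])]
                rho, p, n = _safe_spearman(np.asarray(doses), sel["value"].to_numpy())
                rows.append(dict(parameter=param, time_point=t, rho=rho, p=p, n=n))
    else:
        raise ValueError("pairing must be 'patient_mean' or 'site'")
    out = pd.DataFrame(rows)
    out["rho_masked"] = out["rho"].where(out["p"] < mask_alpha)
    return out


def correlate_early_late(records: pd.DataFrame) -> pd.DataFrame:
    """Spearman of each parameter's early values (7 and 14 days)
    against its post-treatment value, irradiated breast."""
    sa = site_average(records)
    rows = []
    for param in PARAMETER_NAMES:
        late = _wide(sa, "irradiated", "RT_after", param)
        for t in ("RT_7days", "RT_14days"):
            early = _wide(sa, "irradiated", t, param).reindex(late.index)
            rho, p, n = _safe_spearman(early.to_numpy(), late.to_numpy())
            rows.append(dict(parameter=param, time_point=t, rho=rho, p=p, n=n))
    return pd.DataFrame(rows)


def correlate_rtog(records: pd.DataFrame, rtog: pd.DataFrame) -> pd.DataFrame:
    """Spearman of parameter values against RTOG grade at the graded
    time points; grade-constant cohorts (e.g. all grade 1) yield NaN
    with a note rather than an error."""
    sa = site_average(records)
    rows = []
    for param in PARAMETER_NAMES:
        for t in ("RT_14days", "RT_after"):
            vals = _wide(sa, "irradiated", t, param)
            grades = (
                rtog[rtog.time_point == t].set_index("patient_id")["grade"].reindex(vals.index)
            )
            try:
                res = stats.spearman(grades.to_numpy(dtype=float), vals.to_numpy(), method="asymptotic")
                rows.append(dict(parameter=param, time_point=t, rho=res.rho, p=res.p,
                                 n=res.n, note=""))
            except ValueError:
                rows.append(dict(parameter=param, time_point=t, rho=np.nan, p=np.nan,
                                 n=len(vals), note="grade constant; correlation undefined"))
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_study(
    outdir: str | Path,
    n_patients: int = 20,
    seed: int = 0,
    params: ErythemaModelParams | None = None,
    image_dir: str | Path | None = None,
    dose_csv: str | Path | None = None,
    rtog_csv: str | Path | None = None,
    config: Mapping | None = None,
) -> dict:
    """Run the full analysis and write all report artifacts.

    Inputs are either a directory of images plus a dose CSV, or (by
    default) a simulated cohort with ``n_patients`` and ``seed``.  A
    dose CSV alone produces just the dosimetry summary.  Outputs under
    ``outdir``: ``records.csv``, ``summary.csv``, ``anova.csv``,
    ``paired.csv``, ``dose_corr.csv``, ``early_late.csv``,
    ``rtog_corr.csv`` (when grades exist) and ``report.json`` with the
    run configuration, its hash and the dosimetry summary.  Outputs are
    deterministic for a fixed config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dict(config or {})
    cfg.setdefault("n_patients", n_patients)
    cfg.setdefault("seed", seed)

    rtog = None
    if image_dir is not None:
        if dose_csv is None:
            raise ValueError("analyzing an image directory requires a dose CSV")
        images = load_images(image_dir)
        doses = dosimetry.read_dose_table(dose_csv)
        if rtog_csv is not None:
            rtog = pd.read_csv(rtog_csv)
    elif dose_csv is not None:
        doses = dosimetry.read_dose_table(dose_csv)
        images = None
    else:
        cohort = generate_cohort(n_patients=n_patients, params=params, seed=seed)
        images, doses, rtog = cohort.images, cohort.dose_table, cohort.rtog
        cfg["params"] = dataclasses.asdict(cohort.params)

    report: dict = {
        "config": cfg,
        "dose_summary": {
            "cohort_min_mean_cGy": dosimetry.cohort_min_mean(doses),
            **dosimetry.site_extremes(doses),
        },
    }
    dosimetry.write_dose_table(doses, outdir / "doses.csv")

    if images is not None:
        records = extract_all(images)
        _write_csv(records, outdir / "records.csv")
        _write_csv(summarize_parameters(records), outdir / "summary.csv")
        _write_csv(anova_table(records), outdir / "anova.csv")
        _write_csv(paired_tests(records), outdir / "paired.csv")
        _write_csv(correlate_dose(records, doses), outdir / "dose_corr.csv")
        _write_csv(correlate_early_late(records), outdir / "early_late.csv")
        if rtog is not None:
            _write_csv(correlate_rtog(records, rtog), outdir / "rtog_corr.csv")
        report["n_parameter_values"] = int(len(records))
        report["n_patients"] = int(records["patient_id"].nunique())

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report["config_hash"] = cfg_hash
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
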