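"""Seeded synthetic erythema cohort generator.

Real inputs to the analysis are longitudinal photographs of both
breasts during whole-breast radiotherapy; no public image set exists,
so this module generates a cohort with the statistical structure the
analysis assumes and known ground truth:

* each patient has a baseline skin tone drawn in CIE L*a*b*;
* the irradiated breast reddens with cumulative treatment: a* gains
  ``dose_slope_a * skin_dose * time_profile[t]``, with a configurable
  fraction of that shift added to b* (yellowing) and subtracted from
  L* (darkening), matching the directions reported for radiation
  dermatitis (R, S, V, a*, Cr rise; G, B, H, L*, Cb fall);
* the unirradiated control breast only drifts by a small symmetric
  perturbation over time;
* pixels carry i.i.d. Gaussian texture noise on each 8-bit channel.

Skin doses are sampled per site inside the observed clinical range
(default 186.7-284.0 cGy) with a site-ordering bias — the inner site
lowest, upper/lower highest — mimicking tangential-field dosimetry.
RTOG grades are derived by thresholding the final erythema shift and,
with default parameters, are all grade 1, as in mild cohorts.

Everything is reproducible from one master seed: each image draws
from its own substream keyed by (patient, breast, site, time point),
so regenerating part of a cohort gives identical pixels.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import color
from .roi import BREASTS, SITES, TIME_POINTS, SkinImage

__all__ = ["ErythemaModelParams", "SyntheticCohort", "sample_doses",
           "render_skin_image", "generate_cohort", "write_cohort"]

# Per-site sub-interval of the dose range (fractions of the interval
# width) implementing the site-ordering bias.  For a degenerate
# interval every site collapses to the same single dose.
#: Weight of the shared per-patient component in each site's dose draw.
_PATIENT_DOSE_WEIGHT = 0.75

_SITE_DOSE_FRACTIONS = {
    "upper": (0.35, 1.00),
    "lower": (0.30, 1.00),
    "inner": (0.00, 0.55),
    "outer": (0.10, 0.80),
}


@dataclass
class ErythemaModelParams:
    """Generator configuration; defaults reproduce the magnitudes of a
    mild (all grade-1) whole-breast radiotherapy cohort.

    ``dose_slope_a`` is the full-course a* gain per cGy of skin dose:
    at the default 0.03 and a typical ~235 cGy first-fraction skin
    dose the irradiated breast's a* rises by ~7 units, from a slightly
    green baseline to a clearly red final value.  ``time_profile``
    gives the fraction of that shift realized at each time point
    (baseline, ~7 days, ~14 days, ~10 days post treatment).
    """

    baseline_L_range: tuple[float, float] = (71.8, 72.2)
    baseline_a_range: tuple[float, float] = (-1.4, -0.6)
    baseline_b_range: tuple[float, float] = (19.5, 20.5)
    dose_slope_a: float = 0.03
    b_fraction: float = 0.38
    L_fraction: float = 0.11
    time_profile: tuple[float, float, float, float] = (0.0, 0.36, 0.72, 1.0)
    control_drift: float = 0.3
    site_offset_sd: float = 0.3
    pixel_noise_sd: float = 2.0
    image_size: tuple[int, int] = (128, 128)
    dose_interval: tuple[float, float] = (186.7, 284.0)
    grade_threshold: float = 3.0

    def __post_init__(self) -> None:
        tp = self.time_profile
        if tp[0] != 0 or any(tp[i] >= tp[i + 1] for i in range(3)):
            raise ValueError("time_profile must increase strictly from 0")
        if self.dose_slope_a < 0:
            raise ValueError("dose_slope_a must be >= 0")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """Generated study data: 32 images per patient (2 breasts x 4
    sites x 4 time points), the dose table, RTOG grades, and the
    per-patient generating truth."""

    images: list[SkinImage]
    dose_table: pd.DataFrame
    rtog: pd.DataFrame
    truth: pd.DataFrame
    params: ErythemaModelParams
    seed: int


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def sample_doses(n_patients: int, seed: int = 0,
                 interval: tuple[float, float] = (186.7, 284.0)) -> pd.DataFrame:
    """Per-patient, per-site skin doses (cGy) with the site bias.

    Each site dose is uniform on a site-specific sub-interval of
    ``interval``; the inner site's sub-interval sits lowest and the
    upper/lower sites' highest, so row minima concentrate on the inner
    site as observed clinically.  Within a patient the four site doses
    share a common anatomical component (weight ``_PATIENT_DOSE_WEIGHT``
    of the sub-interval position), reproducing the uniformly-high /
    uniformly-low patients seen in measured tables.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    lo, hi = interval
    width = hi - lo
    rows = []
    for p in range(n_patients):
        rng = _substream(seed, 7, p)
        u_patient = rng.uniform()
        rec = {"patient_id": f"P{p + 1:03d}"}
        for s, site in enumerate(SITES):
            f0, f1 = _SITE_DOSE_FRACTIONS[site]
            u = _PATIENT_DOSE_WEIGHT * u_patient + (1 - _PATIENT_DOSE_WEIGHT) * rng.uniform()
            rec[site] = lo + width * (f0 + (f1 - f0) * u)
        rec["mean"] = float(np.mean([rec[s] for s in SITES]))
        rows.append(rec)
    return pd.DataFrame(rows)


def erythema_shift(dose: float, time_point: str, params: ErythemaModelParams) -> float:
    """a* shift of the irradiated breast at ``time_point`` for a given
    site skin dose (cGy)."""
    return params.dose_slope_a * dose * params.time_profile[TIME_POINTS.index(time_point)]


def render_skin_image(
    baseline_lab,
    dose: float,
    time_point: str,
    params: ErythemaModelParams,
    rng: np.random.Generator,
    irradiated: bool = True,
    drift_lab=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Render one capture as a float (H, W, 3) array on the 0-255 scale.

    The base color is uniform in L*a*b*: the patient baseline plus the
    dose- and time-dependent erythema shift (irradiated breast only)
    plus ``drift_lab`` (control drift / site offset).  It is converted
    to sRGB through the inverse of the analysis Lab path, pixel noise
    is added, and channels are clipped to [0, 255].  Pixels stay
    floating point so that, at zero noise, parameter extraction
    recovers the constructed color exactly.
    """
    L, a, b = (float(v) for v in baseline_lab)
    if irradiated:
        shift = erythema_shift(dose, time_point, params)
        L, a, b = L - params.L_fraction * shift, a + shift, b + params.b_fraction * shift
    L, a, b = L + drift_lab[0], a + drift_lab[1], b + drift_lab[2]
    rgb = color.lab_to_rgb([L, a, b], clip=False)
    if (rgb < 0).any() or (rgb > 1).any():
        warnings.warn("base color outside sRGB gamut; clipping", stacklevel=2)
        rgb = np.clip(rgb, 0.0, 1.0)
    w, h = params.image_size
    img = np.broadcast_to(rgb * 255.0, (h, w, 3)).copy()
    if params.pixel_noise_sd > 0:
        img += rng.normal(0.0, params.pixel_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 255.0)


def generate_cohort(
    n_patients: int = 20,
    params: ErythemaModelParams | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Full longitudinal cohort: images, doses, RTOG grades, truth."""
    if n_patients < 1:
        raise ValueError("need at least one patient")
    params = params or ErythemaModelParams()
    doses = sample_doses(n_patients, seed=seed, interval=params.dose_interval)

    images: list[SkinImage] = []
    truth_rows, rtog_rows = [], []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        prng = _substream(seed, 11, p)
        baseline = np.array(
            [
                prng.uniform(*params.baseline_L_range),
                prng.uniform(*params.baseline_a_range),
                prng.uniform(*params.baseline_b_range),
            ]
        )
        # constant per-site tone offsets (both breasts), plus a
        # symmetric per-time drift for the control breast
        site_offsets = {
            (br, s): prng.normal(0.0, params.site_offset_sd, size=3)
            for br in BREASTS
            for s in SITES
        }
        drifts = {tp: prng.normal(0.0, params.control_drift, size=3) for tp in TIME_POINTS}
        drifts["RT_before"] = np.zeros(3)

        site_dose = {s: float(doses.loc[p, s]) for s in SITES}
        for bi, breast in enumerate(BREASTS):
            for si, site in enumerate(SITES):
                for ti, tp in enumerate(TIME_POINTS):
                    rng = _substream(seed, 13, p, bi, si, ti)
                    irr = breast == "irradiated"
                    drift = site_offsets[(breast, site)] + (0 if irr else drifts[tp])
                    pix = render_skin_image(
                        baseline, site_dose[site], tp, params, rng,
                        irradiated=irr, drift_lab=drift,
                    )
                    images.append(
                        SkinImage(pix, patient_id=pid, breast=breast, site=site, time_point=tp)
                    )

        final_shift = erythema_shift(float(doses.loc[p, "mean"]), "RT_after", params)
        grade = 1 if final_shift > params.grade_threshold else 0
        truth_rows.append(
            dict(patient_id=pid, baseline_L=baseline[0], baseline_a=baseline[1],
                 baseline_b=baseline[2], mean_dose=float(doses.loc[p, "mean"]),
                 final_a_shift=final_shift, rtog=grade)
        )
        for tp in ("RT_14days", "RT_after"):
            rtog_rows.append(dict(patient_id=pid, time_point=tp, grade=grade))

    return SyntheticCohort(
        images=images,
        dose_table=doses,
        rtog=pd.DataFrame(rtog_rows),
        truth=pd.DataFrame(truth_rows),
        params=params,
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write the cohort in the on-disk layout the analysis consumes:
    ``images/<patient>/<breast>/<site>/<time>.png`` (8-bit), plus
    ``doses.csv``, ``rtog.csv`` and ``params.json``."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    img_root = outdir / "images"
    for im in cohort.images:
        p = img_root / im.patient_id / im.breast / im.site / f"{im.time_point}.png"
        p.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(p, np.clip(np.rint(im.pixels), 0, 255).astype(np.uint8))
    cohort.dose_table.to_csv(outdir / "doses.csv", index=False)
    cohort.rtog.to_csv(outdir / "rtog.csv", index=False)
    meta = dataclasses.asdict(cohort.params) | {"seed": cohort.seed}
    (outdir / "params.json").write_text(json.dumps(meta, indent=2))
    return outdir
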