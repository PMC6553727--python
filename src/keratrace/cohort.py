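"""Synthetic post-SMILE cohort generator.

Emulates the statistical structure of a 40-eye myopic SMILE cohort:
truncated-normal preoperative keratometry (42.52 ± 1.30 D on [39.80,
44.50]), preoperative spherical equivalent (−4.91 ± 2.01 D on [−9.50,
−1.50]) and postoperative spherical equivalent (0.20 ± 0.40 D on [−0.62,
1.12]), with 6.0–6.5 mm optical zones, an anterior-to-posterior radius
ratio of 0.822, and a simple lenticule-extraction reshape of the anterior
surface.

The reshape is a deliberately minimal surgical model: the anterior apical
power (keratometric convention) drops by the corneal-plane refractive
change, the central thickness drops by a Munnerlyn-approximation lenticule
(ΔSE · OZ² / 3 μm plus a fixed base thickness), and the anterior
asphericity shifts toward oblateness per diopter of correction so that
ray-traced power rises toward the periphery, as measured maps do after
myopic surgery.  The posterior surface and pupil offset are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats

from .cornea import ConicSurface, CornealModel, OpticalConstants
from .errors import DomainError, ReshapeError
from .formulas import (
    KERATOMETRY_NAMES,
    FormulaConstants,
    RefractionPair,
    keratometry_set,
    vertex_to_corneal_plane,
)
from .tracing import GridSpec, build_power_map

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "smile_reshape",
    "generate_cohort",
    "cohort_to_table",
    "validate_record",
    "truncated_mean_sd",
]

#: Base columns preceding the per-eye keratometry columns in the cohort table.
BASE_COLUMNS = [
    "id",
    "se_pre_D",
    "se_post_D",
    "vertex_mm",
    "r1_pre_mm",
    "r1_post_mm",
    "r2_mm",
    "cct_pre_mm",
    "cct_post_mm",
    "oz_mm",
    "pupil_dx_mm",
    "pupil_dy_mm",
]


class CohortConfig(BaseModel):
    """Distributional description of the simulated cohort.

    Means/SDs/truncation bounds are the study-cohort statistics; the noise
    terms (radius measurement noise, refraction measurement noise, pupil
    decentration) are generator choices documented in the methods note.
    """

    model_config = ConfigDict(extra="forbid")

    n: int = 40
    seed: int = 1234

    pre_km_mean: float = 42.52
    pre_km_sd: float = 1.30
    pre_km_bounds: tuple[float, float] = (39.80, 44.50)

    pre_se_mean: float = -4.91
    pre_se_sd: float = 2.01
    pre_se_bounds: tuple[float, float] = (-9.50, -1.50)

    post_se_mean: float = 0.20
    post_se_sd: float = 0.40
    post_se_bounds: tuple[float, float] = (-0.62, 1.12)

    optical_zones: tuple[float, ...] = (6.0, 6.5)
    ap_ratio: float = 0.822
    cct_mean: float = 0.540
    cct_sd: float = 0.030
    q_anterior: float = -0.25
    q_posterior: float = -0.20
    q_shift_per_diopter: float = 0.08
    lenticule_base_um: float = 15.0
    pupil_offset_sd: float = 0.1
    radius_noise_sd: float = 0.01
    refraction_noise_sd: float = 0.15
    vertex_distance_mm: float = 12.0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        for lo, hi in (self.pre_km_bounds, self.pre_se_bounds, self.post_se_bounds):
            if not lo < hi:
                raise ValueError("truncation bounds must be ordered")
        for sd in (
            self.pre_km_sd,
            self.pre_se_sd,
            self.post_se_sd,
            self.cct_sd,
            self.pupil_offset_sd,
            self.radius_noise_sd,
            self.refraction_noise_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        return self


@dataclass
class SubjectRecord:
    """One synthetic eye: measured pre/post corneal models, manifest
    refraction, optical zone, and the derived keratometry sets."""

    id: int
    preop: CornealModel
    postop: CornealModel
    refraction: RefractionPair
    optical_zone: float
    keratometry_pre: dict[str, float | None] | None = None
    keratometry_post: dict[str, float | None] | None = None


def validate_record(rec: SubjectRecord) -> None:
    """Assert the structural invariants of a subject record."""
    if not rec.postop.anterior.apical_radius > rec.preop.anterior.apical_radius:
        raise DomainError(f"eye {rec.id}: no myopic anterior flattening")
    if rec.postop.posterior != ConicSurface(
        rec.preop.posterior.apical_radius,
        rec.preop.posterior.asphericity_q,
        rec.postop.central_thickness,
    ):
        raise DomainError(f"eye {rec.id}: posterior surface changed by surgery")
    if not rec.postop.central_thickness < rec.preop.central_thickness:
        raise DomainError(f"eye {rec.id}: cornea did not thin")


def smile_reshape(
    preop: CornealModel,
    delta_se_corneal: float,
    optical_zone: float,
    q_shift_per_diopter: float = 0.08,
    lenticule_base_um: float = 15.0,
) -> CornealModel:
    """Apply a myopic lenticule extraction of ``delta_se_corneal`` D
    (corneal-plane refractive change, > 0 for power removed) with the given
    optical zone (mm) to the anterior surface.

    Anterior apical power in the keratometric convention drops by delta;
    central thickness drops by the Munnerlyn-approximation lenticule
    thickness delta*OZ^2/3 μm plus a fixed base; anterior Q shifts toward
    oblate by ``q_shift_per_diopter`` per diopter.  delta = 0 returns the
    model unchanged.
    """
    if delta_se_corneal < 0:
        raise ReshapeError("myopic reshape requires delta_se_corneal >= 0")
    if delta_se_corneal == 0:
        return preop
    nk = preop.constants.n_keratometric
    R = preop.anterior.apical_radius
    inv = (nk - 1.0) / R - delta_se_corneal / 1000.0
    if inv <= 0:
        raise ReshapeError("requested correction exceeds the anterior surface power")
    r_new = (nk - 1.0) / inv
    lenticule_mm = (delta_se_corneal * optical_zone**2 / 3.0 + lenticule_base_um) / 1000.0
    cct_new = preop.central_thickness - lenticule_mm
    if cct_new < 0.25:
        raise ReshapeError("residual central thickness would underflow 0.25 mm")
    anterior = ConicSurface(
        r_new, preop.anterior.asphericity_q + q_shift_per_diopter * delta_se_corneal, 0.0
    )
    posterior = ConicSurface(
        preop.posterior.apical_radius, preop.posterior.asphericity_q, cct_new
    )
    return CornealModel(
        anterior=anterior,
        posterior=posterior,
        central_thickness=cct_new,
        pupil_offset=preop.pupil_offset,
        constants=preop.constants,
    )


def _truncnorm(rng, mean, sd, bounds, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_mean_sd(mean: float, sd: float, bounds: tuple[float, float]) -> tuple[float, float]:
    """Expectation and SD of the truncated normal implied by a config entry."""
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    m, v = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(m), float(np.sqrt(v))


def generate_cohort(
    config: CohortConfig,
    grid: GridSpec | None = None,
    compute_keratometry: bool = True,
    constants: OpticalConstants | None = None,
    formula_constants: FormulaConstants | None = None,
) -> list[SubjectRecord]:
    """Draw a deterministic synthetic cohort.

    Preop Km and SE and the surgical target SE come from the configured
    truncated normals; r1 = (1.3375-1)/Km and r2 = ap_ratio * r1.  The
    reshape is driven by the corneal-plane change to the *target* SE; the
    recorded manifest refraction is target + refraction noise.  Measured
    radii (used for all keratometry) carry independent radius noise, with
    the posterior radius sharing one draw across visits.  With
    ``compute_keratometry=False`` only the geometric records are built
    (moment-recovery studies do not need the ray-traced maps).
    """
    consts = constants or OpticalConstants()
    fconsts = formula_constants or FormulaConstants()
    grid = grid or GridSpec(meridians=64)
    rng = np.random.default_rng(config.seed)
    n = config.n

    km_pre = _truncnorm(rng, config.pre_km_mean, config.pre_km_sd, config.pre_km_bounds, n)
    se_pre = _truncnorm(rng, config.pre_se_mean, config.pre_se_sd, config.pre_se_bounds, n)
    sd_target = float(np.sqrt(max(config.post_se_sd**2 - config.refraction_noise_sd**2, 0.0)))
    se_post_target = _truncnorm(rng, config.post_se_mean, sd_target, config.post_se_bounds, n)
    se_post = se_post_target + rng.normal(0.0, config.refraction_noise_sd, n)
    cct = np.clip(rng.normal(config.cct_mean, config.cct_sd, n), 0.45, 0.65)
    pupil = rng.normal(0.0, config.pupil_offset_sd, (n, 2))
    oz = rng.choice(np.asarray(config.optical_zones, dtype=float), size=n)
    noise_r1_pre = rng.normal(0.0, config.radius_noise_sd, n)
    noise_r1_post = rng.normal(0.0, config.radius_noise_sd, n)
    noise_r2 = rng.normal(0.0, config.radius_noise_sd, n)

    nk = consts.n_keratometric
    records: list[SubjectRecord] = []
    for i in range(n):
        r1_pre = (nk - 1.0) / km_pre[i] * 1000.0
        r2 = config.ap_ratio * r1_pre
        vd = config.vertex_distance_mm
        preop_true = CornealModel(
            anterior=ConicSurface(r1_pre, config.q_anterior, 0.0),
            posterior=ConicSurface(r2, config.q_posterior, cct[i]),
            central_thickness=float(cct[i]),
            pupil_offset=(float(pupil[i, 0]), float(pupil[i, 1])),
            constants=consts,
        )
        delta = vertex_to_corneal_plane(se_post_target[i], vd) - vertex_to_corneal_plane(
            se_pre[i], vd
        )
        try:
            postop_true = smile_reshape(
                preop_true,
                delta,
                float(oz[i]),
                config.q_shift_per_diopter,
                config.lenticule_base_um,
            )
        except ReshapeError as exc:
            raise ReshapeError(f"eye {i}: {exc}") from exc

        preop = _with_measured_radii(preop_true, noise_r1_pre[i], noise_r2[i])
        postop = _with_measured_radii(postop_true, noise_r1_post[i], noise_r2[i])
        refraction = RefractionPair(float(se_pre[i]), float(se_post[i]), vd)
        rec = SubjectRecord(
            id=i, preop=preop, postop=postop, refraction=refraction, optical_zone=float(oz[i])
        )
        if compute_keratometry:
            maps_pre = {c: build_power_map(preop, c, grid) for c in ("apex", "pupil")}
            maps_post = {c: build_power_map(postop, c, grid) for c in ("apex", "pupil")}
            rec.keratometry_pre = keratometry_set(preop, maps_pre, constants=fconsts)
            pre_km_meas = rec.keratometry_pre["Km"]
            rec.keratometry_post = keratometry_set(
                postop, maps_post, pre_km=pre_km_meas, refraction=refraction, constants=fconsts
            )
        records.append(rec)
    return records


def _with_measured_radii(model: CornealModel, dr1: float, dr2: float) -> CornealModel:
    anterior = ConicSurface(
        model.anterior.apical_radius + dr1, model.anterior.asphericity_q, 0.0
    )
    posterior = ConicSurface(
        model.posterior.apical_radius + dr2,
        model.posterior.asphericity_q,
        model.central_thickness,
    )
    return CornealModel(
        anterior=anterior,
        posterior=posterior,
        central_thickness=model.central_thickness,
        pupil_offset=model.pupil_offset,
        constants=model.constants,
    )


def cohort_to_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten a cohort into one row per eye.

    Base geometry/refraction columns come first, then ``pre_<name>`` and
    ``post_<name>`` for every enumerated keratometry measure; measures not
    computed are explicit NaN cells, never silently dropped.
    """
    if not records:
        raise DomainError("empty cohort")
    rows = []
    for rec in records:
        row: dict[str, float] = {
            "id": rec.id,
            "se_pre_D": rec.refraction.se_pre,
            "se_post_D": rec.refraction.se_post,
            "vertex_mm": rec.refraction.vertex_mm,
            "r1_pre_mm": rec.preop.anterior.apical_radius,
            "r1_post_mm": rec.postop.anterior.apical_radius,
            "r2_mm": rec.postop.posterior.apical_radius,
            "cct_pre_mm": rec.preop.central_thickness,
            "cct_post_mm": rec.postop.central_thickness,
            "oz_mm": rec.optical_zone,
            "pupil_dx_mm": rec.preop.pupil_offset[0],
            "pupil_dy_mm": rec.preop.pupil_offset[1],
        }
        for prefix, kset in (("pre_", rec.keratometry_pre), ("post_", rec.keratometry_post)):
            for name in KERATOMETRY_NAMES:
                v = None if kset is None else kset.get(name)
                row[prefix + name] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows, columns=BASE_COLUMNS + [p + n for p in ("pre_", "post_") for n in KERATOMETRY_NAMES])
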