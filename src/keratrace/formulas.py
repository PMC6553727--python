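"""Closed-form keratometric estimates, the clinical history method (CHM)
benchmark, and the modified-TCRP conversion.

All formula operations take radii in *metres* (the convention in which the
formulas are usually printed); the geometry layer works in mm and call
sites convert.  Conventions:

- SimK / Km:  (1.3375 - 1) / r1 — the fictitious-index keratometry reading.
- TNP:        0.376/r1 - 0.040/r2 — thin Gaussian sum with true indices
              (no thickness term, matching the tomographer's readout).
- EKR:        0.376/r1 - 0.03165/r2 — Holladay's adjusted posterior
              coefficient, printed without any diameter dependence, so the
              4.0 mm and 4.5 mm names evaluate identically here.
- CHM:        preoperative Km minus the surgically induced refractive
              change *at the corneal plane*.
- K_Haigis:   1.119 * postKm - 5.78;  K_Shammas: 1.14 * postKm - 6.8.
- modified TCRP: 4 mm zone TCRP + 0.70 D conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict

from .cornea import CornealModel
from .errors import DomainError
from .tracing import PowerMap, tcrp_ring, tcrp_zone

__all__ = [
    "FormulaConstants",
    "RefractionPair",
    "sim_k",
    "tnp",
    "ekr",
    "vertex_to_corneal_plane",
    "chm",
    "k_haigis",
    "k_shammas",
    "modified_tcrp",
    "keratometry_set",
    "KERATOMETRY_NAMES",
    "TCRP_DIAMETERS",
    "tcrp_name",
]


class FormulaConstants(BaseModel):
    """Published constants of the regression formulas and conversions."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    haigis_slope: float = 1.119
    haigis_intercept: float = 5.78
    shammas_slope: float = 1.14
    shammas_intercept: float = 6.8
    tcrp_conversion: float = 0.70
    loa_multiplier: float = 1.96
    vertex_distance_mm: float = 12.0


@dataclass(frozen=True)
class RefractionPair:
    """Pre/post spherical equivalents (D) at the spectacle plane."""

    se_pre: float
    se_post: float
    vertex_mm: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vertex_mm <= 20.0:
            raise DomainError("vertex distance must be in [0, 20] mm")


def _check_radius(r: float) -> None:
    if not r > 0:
        raise DomainError("radius must be positive")


def sim_k(r1: float, n_keratometric: float = 1.3375) -> float:
    """Keratometry reading (D) from the anterior radius r1 in metres."""
    _check_radius(r1)
    return (n_keratometric - 1.0) / r1


def tnp(r1: float, r2: float) -> float:
    """True net power (D): thin sum of both surface powers, radii in metres."""
    _check_radius(r1)
    _check_radius(r2)
    return 0.376 / r1 - 0.040 / r2


def ekr(r1: float, r2: float) -> float:
    """Equivalent keratometry reading (D), radii in metres."""
    _check_radius(r1)
    _check_radius(r2)
    return 0.376 / r1 - 0.03165 / r2


def vertex_to_corneal_plane(se: float, vertex_mm: float = 12.0) -> float:
    """Convert a spectacle-plane power (D) to the corneal plane."""
    denom = 1.0 - (vertex_mm / 1000.0) * se
    if abs(denom) < 1e-12:
        raise DomainError("vertex conversion singular for this power")
    return se / denom


def chm(pre_km: float, refraction: RefractionPair) -> float:
    """Clinical history method benchmark (D).

    Subtracts the corneal-plane refractive change (postop minus preop
    spherical equivalent, each converted through the vertex distance) from
    the preoperative keratometry.
    """
    change = vertex_to_corneal_plane(
        refraction.se_post, refraction.vertex_mm
    ) - vertex_to_corneal_plane(refraction.se_pre, refraction.vertex_mm)
    return pre_km - change


def k_haigis(post_km: float, constants: FormulaConstants | None = None) -> float:
    """Haigis equivalent-power regression on the postoperative Km."""
    c = constants or FormulaConstants()
    return c.haigis_slope * post_km - c.haigis_intercept


def k_shammas(post_km: float, constants: FormulaConstants | None = None) -> float:
    """Shammas regression on the postoperative Km."""
    c = constants or FormulaConstants()
    return c.shammas_slope * post_km - c.shammas_intercept


def modified_tcrp(tcrp_zone_4mm: float, constants: FormulaConstants | None = None) -> float:
    """4 mm zone TCRP converted toward a conventional keratometry reading."""
    c = constants or FormulaConstants()
    return tcrp_zone_4mm + c.tcrp_conversion


TCRP_DIAMETERS: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
_CENTERS = ("pupil", "apex")
_GEOMS = ("ring", "zone")


def tcrp_name(center: str, geom: str, diameter: float) -> str:
    return f"TCRP_{center}_{geom}_{diameter:.1f}"


def _enumerate_names() -> list[str]:
    names = ["Km", "TNP", "EKR_4.0", "EKR_4.5"]
    for center in _CENTERS:
        for geom in _GEOMS:
            for d in TCRP_DIAMETERS:
                names.append(tcrp_name(center, geom, d))
    names += ["CHM", "K_Haigis", "K_Shammas"]
    names += [f"modTCRP_{c}_zone_4.0" for c in _CENTERS]
    return names


#: Canonical ordering of every dioptric measure reported per eye.
KERATOMETRY_NAMES: tuple[str, ...] = tuple(_enumerate_names())


def keratometry_set(
    model: CornealModel,
    maps: dict[str, PowerMap],
    pre_km: float | None = None,
    refraction: RefractionPair | None = None,
    constants: FormulaConstants | None = None,
) -> dict[str, float | None]:
    """Assemble every enumerated dioptric measure for one eye.

    ``maps`` must contain 'apex'- and 'pupil'-centered power maps of the
    same model.  ``pre_km``/``refraction`` feed the CHM; when omitted (e.g.
    for a preoperative eye) the CHM entry is explicitly None.  Formula-based
    values (Km, TNP, EKR, Haigis, Shammas) are evaluated from the model's
    apical radii; the rotationally symmetric geometry makes meridian
    selection moot.
    """
    c = constants or FormulaConstants()
    for key in _CENTERS:
        if key not in maps:
            raise DomainError(f"missing {key!r}-centered power map")

    r1 = model.anterior.apical_radius * 1e-3
    r2 = model.posterior.apical_radius * 1e-3
    out: dict[str, float | None] = {}
    km = sim_k(r1, model.constants.n_keratometric)
    out["Km"] = km
    out["TNP"] = tnp(r1, r2)
    out["EKR_4.0"] = out["EKR_4.5"] = ekr(r1, r2)
    for center in _CENTERS:
        pmap = maps[center]
        for d in TCRP_DIAMETERS:
            out[tcrp_name(center, "ring", d)] = tcrp_ring(pmap, d)
            out[tcrp_name(center, "zone", d)] = tcrp_zone(pmap, d)
    out["CHM"] = chm(pre_km, refraction) if (pre_km is not None and refraction is not None) else None
    out["K_Haigis"] = k_haigis(km, c)
    out["K_Shammas"] = k_shammas(km, c)
    for center in _CENTERS:
        out[f"modTCRP_{center}_zone_4.0"] = modified_tcrp(
            out[tcrp_name(center, "zone", 4.0)], c
        )
    # physiologic sanity: every present value in (20, 60) D
    bad = [k for k, v in out.items() if v is not None and not (20.0 < v < 60.0 or np.isnan(v))]
    if bad:
        raise DomainError(f"non-physiologic keratometry values for {bad}")
    return out
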