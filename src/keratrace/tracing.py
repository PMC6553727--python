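"""Exact Snell's-law ray tracing through both corneal surfaces and
aggregation of per-ray powers into ring/zone total corneal refractive power
(TCRP) values.

A bundle of rays parallel to the optical axis is refracted at the anterior
and posterior conicoids using the vector form of Snell's law with the
physical indices (air 1.0, cornea 1.376, aqueous 1.336).  Each ray entering
at height ``h`` from the aggregation center yields the per-ray power

    P(h) = n_aqueous * sin(U') / h        (h in metres)

where ``U'`` is the exit ray's angle with the optical axis.  As h -> 0 this
converges to the Gaussian thick-lens equivalent power, so the paraxial limit
acts as a built-in oracle.  An alternative definition based on the axial
crossing distance of the exit ray is available behind ``definition`` for
sensitivity analysis.

Powers are aggregated either on a *ring* (the mean over meridians at a
single radius, radially interpolated) or over a *zone* (the area-weighted
mean over the filled disc), each centered on either the corneal apex or the
pupil axis — the four TCRP variants reported by Scheimpflug tomographers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict

from .cornea import CornealModel, _intersect_t, sag, sag_slope
from .errors import (
    DomainError,
    InsufficientCoverageError,
    NoIntersectionError,
    TotalInternalReflectionError,
)

__all__ = [
    "GridSpec",
    "PowerMap",
    "snell_refract",
    "gaussian_equivalent_power",
    "trace_power_at",
    "build_power_map",
    "tcrp_ring",
    "tcrp_zone",
]


class GridSpec(BaseModel):
    """Polar sampling grid for power maps.

    radial_step : mm between radial nodes (nodes at k*step, k = 1..K).
    meridians   : number of equally spaced meridians.
    max_radius  : outermost radial node in mm (covers the 8 mm diameter
                  aperture at the default 4.0).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    radial_step: float = 0.05
    meridians: int = 256
    max_radius: float = 4.0

    def radii(self) -> np.ndarray:
        n = int(round(self.max_radius / self.radial_step))
        return self.radial_step * np.arange(1, n + 1)

    def thetas_deg(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.meridians, endpoint=False)


@dataclass(frozen=True)
class PowerMap:
    """Ray-traced power P(r, θ) on a polar grid around one center.

    ``power`` has shape (len(r), len(theta_deg)); NaN marks rays that could
    not be traced (outside the surface aperture or total internal
    reflection).  ``center`` is the (x, y) position of the grid origin in
    the apex frame.
    """

    r: np.ndarray
    theta_deg: np.ndarray
    power: np.ndarray
    center_ref: str
    center: tuple[float, float]
    radial_step: float

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.r), len(self.theta_deg)):
            raise DomainError("power grid shape mismatch")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.power)


def snell_refract(incident_dir, normal, n_in: float, n_out: float) -> np.ndarray:
    """Vector Snell refraction; preserves the plane of incidence.

    ``normal`` must point against the incident ray (incident_dir · normal < 0);
    both inputs are unit vectors, broadcastable with trailing axis 3.
    Raises :class:`TotalInternalReflectionError` for scalar input when the
    discriminant is negative; vectorized input yields NaN rows instead.
    """
    d = np.asarray(incident_dir, dtype=float)
    n = np.asarray(normal, dtype=float)
    scalar = d.ndim == 1
    d = np.atleast_2d(d)
    n = np.atleast_2d(n)
    cos_i = -np.sum(d * n, axis=-1)
    if np.any(cos_i < -1e-9):
        raise DomainError("normal must oppose the incident ray direction")
    eta = n_in / n_out
    k = 1.0 - eta**2 * (1.0 - cos_i**2)
    if scalar and k[0] < 0:
        raise TotalInternalReflectionError(
            f"total internal reflection (n {n_in} -> {n_out})"
        )
    with np.errstate(invalid="ignore"):
        t = eta * d + (eta * cos_i - np.sqrt(np.maximum(k, 0.0)))[..., None] * n
    t = np.where((k >= 0)[..., None], t, np.nan)
    return t[0] if scalar else t


def gaussian_equivalent_power(model: CornealModel) -> float:
    """Paraxial thick-lens equivalent power of the two-surface cornea (D).

    P = P1 + P2 - (d / n_cornea) * P1 * P2, with surface powers
    P1 = (n_cornea - n_air)/r1 and P2 = (n_aqueous - n_cornea)/r2 and all
    lengths in metres.  This *includes* the thickness term, unlike the
    Scheimpflug "true net power" readout which is the thin sum only.
    """
    c = model.constants
    r1 = model.anterior.apical_radius * 1e-3
    r2 = model.posterior.apical_radius * 1e-3
    d = model.central_thickness * 1e-3
    p1 = (c.n_cornea - c.n_air) / r1
    p2 = (c.n_aqueous - c.n_cornea) / r2
    return p1 + p2 - (d / c.n_cornea) * p1 * p2


def _trace_exit(model: CornealModel, x, y):
    """Trace axis-parallel rays entering at apex-frame coordinates (x, y).

    Returns (exit_points, exit_dirs); rows are NaN where tracing fails.
    """
    c = model.constants
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, y)

    # anterior intersection: axis-parallel rays meet the surface at its sag
    R, Q = model.anterior.apical_radius, model.anterior.asphericity_q
    arg = 1.0 - (1.0 + Q) * rho**2 / R**2
    ok = arg > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        z1 = np.where(ok, rho**2 / (R * (1.0 + np.sqrt(np.clip(arg, 0, None)))), np.nan)
        m1 = np.where(ok, rho / (R * np.sqrt(np.clip(arg, 1e-300, None))), np.nan)
    p1 = np.stack([x, y, z1], axis=-1)

    # outward normal from the radial sag slope
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = np.where(rho > 0, x / rho, 0.0)
        cy = np.where(rho > 0, y / rho, 0.0)
    norm = np.sqrt(1.0 + m1**2)
    n1 = np.stack([m1 * cx, m1 * cy, -np.ones_like(m1)], axis=-1) / norm[..., None]

    d0 = np.zeros_like(p1)
    d0[..., 2] = 1.0
    d1 = snell_refract(d0, n1, c.n_air, c.n_cornea)

    # posterior intersection: closed-form quadratic, NaN where missed
    t = _intersect_t(model.posterior, p1, d1)
    p2 = p1 + t[..., None] * d1
    rho2 = np.hypot(p2[..., 0], p2[..., 1])
    R2, Q2 = model.posterior.apical_radius, model.posterior.asphericity_q
    arg2 = 1.0 - (1.0 + Q2) * rho2**2 / R2**2
    ok2 = arg2 > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = np.where(ok2, rho2 / (R2 * np.sqrt(np.clip(arg2, 1e-300, None))), np.nan)
        cx2 = np.where(rho2 > 0, p2[..., 0] / rho2, 0.0)
        cy2 = np.where(rho2 > 0, p2[..., 1] / rho2, 0.0)
    norm2 = np.sqrt(1.0 + m2**2)
    n2 = np.stack([m2 * cx2, m2 * cy2, -np.ones_like(m2)], axis=-1) / norm2[..., None]

    d2 = snell_refract(d1, n2, c.n_cornea, c.n_aqueous)
    return p2, d2


def _power_from_exit(model, p2, d2, hx, hy, h_mm):
    """Per-ray "Snell power" from the exit ray; (hx, hy) is the entry offset
    from the aggregation center and h_mm its magnitude."""
    n_aq = model.constants.n_aqueous
    h_m = h_mm * 1e-3
    sin_u = np.hypot(d2[..., 0], d2[..., 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = n_aq * sin_u / h_m
    # converging rays (transverse direction opposing the entry offset) carry
    # positive power
    conv = d2[..., 0] * hx + d2[..., 1] * hy
    sign = np.where(conv <= 0, 1.0, -1.0)
    return p * sign


def _power_crossing(model, p2, d2, cx, cy, h_mm):
    """Alternative per-ray power: n_aqueous over the axial crossing distance.

    The crossing distance is measured along z from the posterior apex plane
    to the exit ray's closest approach to the axis through the aggregation
    center (exact axis crossing for meridional rays)."""
    n_aq = model.constants.n_aqueous
    rx = p2[..., 0] - cx
    ry = p2[..., 1] - cy
    dt2 = d2[..., 0] ** 2 + d2[..., 1] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tstar = -(rx * d2[..., 0] + ry * d2[..., 1]) / dt2
        z_cross = p2[..., 2] + tstar * d2[..., 2]
        f = (z_cross - model.central_thickness) * 1e-3
        return n_aq / f


def trace_power_at(
    model: CornealModel,
    h: float,
    theta_deg: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    definition: str = "sine",
) -> float:
    """Ray-traced power (D) of the axis-parallel ray entering at height ``h``
    (mm) on meridian ``theta_deg``, measured from ``center`` in the apex
    frame.

    Raises for h <= 0, rays missing a surface, or total internal reflection.
    """
    if not 0.0 < h <= 4.5:
        raise DomainError("ray height must be in (0, 4.5] mm")
    th = np.radians(theta_deg)
    hx, hy = h * np.cos(th), h * np.sin(th)
    x, y = center[0] + hx, center[1] + hy
    p2, d2 = _trace_exit(model, np.array([x]), np.array([y]))
    if not np.all(np.isfinite(d2)):
        if np.isfinite(p2).all():
            raise TotalInternalReflectionError("ray lost to total internal reflection")
        raise NoIntersectionError("ray misses the posterior surface")
    if definition not in ("sine", "crossing"):
        raise DomainError(f"unknown power definition {definition!r}")
    if definition == "crossing":
        p = _power_crossing(model, p2, d2, center[0], center[1], np.array([h]))[0]
    else:
        p = _power_from_exit(model, p2, d2, np.array([hx]), np.array([hy]), np.array([h]))[0]
    return float(p)


def build_power_map(
    model: CornealModel,
    center_ref: str = "apex",
    grid: GridSpec | None = None,
    definition: str = "sine",
) -> PowerMap:
    """Sample :func:`trace_power_at` on a polar grid.

    ``center_ref='apex'`` puts the grid origin at the corneal apex;
    ``'pupil'`` shifts it by the model's pupil offset.  Ray heights are
    measured from the chosen center while rays stay parallel to the common
    optical axis.  Untraceable samples are NaN.
    """
    grid = grid or GridSpec()
    if grid.meridians < 8:
        raise DomainError("at least 8 meridians required")
    if center_ref == "apex":
        cx, cy = 0.0, 0.0
    elif center_ref == "pupil":
        cx, cy = model.pupil_offset
    else:
        raise DomainError(f"unknown center_ref {center_ref!r}")

    r = grid.radii()
    th = np.radians(grid.thetas_deg())
    hx = r[:, None] * np.cos(th)[None, :]
    hy = r[:, None] * np.sin(th)[None, :]
    p2, d2 = _trace_exit(model, cx + hx, cy + hy)
    if definition not in ("sine", "crossing"):
        raise DomainError(f"unknown power definition {definition!r}")
    if definition == "crossing":
        power = _power_crossing(model, p2, d2, cx, cy, r[:, None] + 0 * hx)
    else:
        power = _power_from_exit(model, p2, d2, hx, hy, r[:, None] + 0 * hx)
    return PowerMap(
        r=r,
        theta_deg=grid.thetas_deg(),
        power=power,
        center_ref=center_ref,
        center=(cx, cy),
        radial_step=grid.radial_step,
    )


def _ring_values(pmap: PowerMap, radius: float) -> np.ndarray:
    """Per-meridian power at an exact radius, linearly interpolated between
    the bracketing radial nodes; NaN where a needed node is missing."""
    r = pmap.r
    if radius > r[-1] + 1e-9:
        raise DomainError(f"ring radius {radius} mm beyond sampled range {r[-1]} mm")
    j = int(np.searchsorted(r, radius - 1e-12))
    if j < len(r) and abs(r[j] - radius) < 1e-9:
        return pmap.power[j]
    if j == 0:  # inside the innermost node: use the innermost ring
        return pmap.power[0]
    w = (radius - r[j - 1]) / (r[j] - r[j - 1])
    return (1 - w) * pmap.power[j - 1] + w * pmap.power[j]


def tcrp_ring(pmap: PowerMap, diameter: float) -> float:
    """Unweighted mean power over all meridians on the circle of the given
    diameter (mm), radially interpolating between grid nodes.

    Raises :class:`InsufficientCoverageError` when more than 10% of the
    meridian samples on the ring are missing.
    """
    vals = _ring_values(pmap, diameter / 2.0)
    ok = np.isfinite(vals)
    if ok.mean() < 0.9:
        raise InsufficientCoverageError(
            f"only {ok.mean():.0%} of ring samples traceable at d={diameter} mm"
        )
    return float(vals[ok].mean())


def tcrp_zone(pmap: PowerMap, diameter: float) -> float:
    """Area-weighted mean power over the filled disc of the given diameter.

    Each sample at radial node r_j is weighted by its annulus-sector area;
    the innermost annulus extends to r = 0 so the d -> 0 limit equals the
    central (paraxial) power, and the outermost annulus is clipped at the
    zone edge.  Requires >= 90% area coverage by traceable samples.
    """
    rad = diameter / 2.0
    r, s = pmap.r, pmap.radial_step
    if rad > r[-1] + s / 2 + 1e-9:
        raise DomainError(f"zone radius {rad} mm beyond sampled range")
    inner = np.maximum(r - s / 2.0, 0.0)
    inner[0] = 0.0
    outer = np.minimum(r + s / 2.0, rad)
    w_r = np.clip(outer**2 - inner**2, 0.0, None) / 2.0  # annulus area / (2*pi*M)
    w = np.repeat(w_r[:, None], pmap.power.shape[1], axis=1)
    ok = pmap.valid
    total = w.sum()
    if total <= 0:
        raise DomainError("empty zone")
    covered = w[ok].sum()
    if covered / total < 0.9:
        raise InsufficientCoverageError(
            f"only {covered / total:.0%} of zone area traceable at d={diameter} mm"
        )
    return float((pmap.power[ok] * w[ok]).sum() / covered)
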