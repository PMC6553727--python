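"""Two-surface conicoid corneal geometry.

The cornea is modeled as two rotationally symmetric conicoid surfaces in
axial alignment: an anterior surface with its apex at the coordinate origin
and a posterior surface whose apex sits one central corneal thickness behind
it.  The frame is right-handed with +z pointing from air into the eye; all
lengths are millimetres.  Refractive powers derived from this geometry are
in diopters, with lengths converted to metres at the point of power
computation.

A conicoid with apical radius ``R`` (mm) and asphericity ``Q`` has sag

    z(r) = r^2 / ( R * (1 + sqrt(1 - (1+Q) r^2 / R^2)) )

measured from its apex toward the eye.  ``Q < 0`` is prolate (flattening
toward the periphery, the physiologic shape), ``Q = 0`` spherical, ``Q > 0``
oblate.  For ``Q > -1`` the sag is real only for ``r < R / sqrt(1+Q)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, NoIntersectionError

__all__ = [
    "OpticalConstants",
    "ConicSurface",
    "CornealModel",
    "sag",
    "sag_slope",
    "surface_normal",
    "ray_surface_intersect",
]

_EPS = 1e-12


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices used throughout the pipeline.

    ``n_keratometric`` is the fictitious keratometric index (1.3375) that
    converts an anterior radius into a conventional keratometry reading;
    the other three are the physical indices used in exact ray tracing.
    """

    n_air: float = 1.0
    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    n_keratometric: float = 1.3375

    def __post_init__(self) -> None:
        if min(self.n_air, self.n_cornea, self.n_aqueous, self.n_keratometric) < 1.0:
            raise DomainError("refractive indices must be >= 1")
        if not (self.n_cornea > self.n_aqueous > self.n_air):
            raise DomainError("expected n_cornea > n_aqueous > n_air")


@dataclass(frozen=True)
class ConicSurface:
    """One rotationally symmetric conicoid surface.

    apical_radius : mm, > 0, convex toward the incoming light.
    asphericity_q : dimensionless conic constant Q.
    apex_z        : mm, axial position of the surface apex.
    """

    apical_radius: float
    asphericity_q: float = 0.0
    apex_z: float = 0.0

    def __post_init__(self) -> None:
        if not self.apical_radius > 0:
            raise DomainError("apical_radius must be > 0")

    @property
    def max_aperture_radius(self) -> float:
        """Largest radial coordinate with a real-valued sag (mm)."""
        q1 = 1.0 + self.asphericity_q
        if q1 <= 0:
            return np.inf
        return self.apical_radius / np.sqrt(q1)


@dataclass(frozen=True)
class CornealModel:
    """Two coaxial conicoids plus the pupil decentration.

    The anterior apex defines the origin; the posterior apex lies at
    ``z = central_thickness``.  ``pupil_offset`` is the (dx, dy) displacement
    of the pupil center from the corneal apex in mm, used only as an
    aggregation center for pupil-centered power maps.
    """

    anterior: ConicSurface
    posterior: ConicSurface
    central_thickness: float
    pupil_offset: tuple[float, float] = (0.0, 0.0)
    constants: OpticalConstants = field(default_factory=OpticalConstants)

    def __post_init__(self) -> None:
        if not (0.2 < self.central_thickness < 1.0):
            raise DomainError(
                f"central_thickness {self.central_thickness} mm outside (0.2, 1.0)"
            )
        if abs(self.anterior.apex_z) > _EPS:
            raise DomainError("anterior apex must sit at z = 0")
        if abs(self.posterior.apex_z - self.central_thickness) > _EPS:
            raise DomainError("posterior apex_z must equal central_thickness")
        self._check_separation()

    def _check_separation(self, aperture_mm: float = 8.0) -> None:
        # surfaces must not intersect within the working aperture
        r = np.linspace(0.0, aperture_mm / 2.0, 65)
        r = r[r < min(self.anterior.max_aperture_radius, self.posterior.max_aperture_radius) * 0.999]
        za = sag(self.anterior, r)
        zp = self.central_thickness + sag(self.posterior, r)
        if np.any(zp - za <= 0):
            raise DomainError("anterior and posterior surfaces intersect within 8 mm aperture")

    def with_constants(self, constants: OpticalConstants) -> "CornealModel":
        return replace(self, constants=constants)


def _maybe_scalar(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


def sag(surface: ConicSurface, r) -> float | np.ndarray:
    """Axial depth z(r) of the surface, measured from its apex toward the eye.

    Raises :class:`DomainError` where the conicoid has no real sag.
    """
    scalar = np.isscalar(r)
    r = np.asarray(r, dtype=float)
    R, Q = surface.apical_radius, surface.asphericity_q
    arg = 1.0 - (1.0 + Q) * r**2 / R**2
    if np.any(arg < -1e-12):
        raise DomainError(
            f"radial coordinate outside real-valued domain of conicoid (R={R}, Q={Q})"
        )
    arg = np.clip(arg, 0.0, None)
    z = r**2 / (R * (1.0 + np.sqrt(arg)))
    return _maybe_scalar(z, scalar)


def sag_slope(surface: ConicSurface, r) -> float | np.ndarray:
    """Radial derivative dz/dr of the sag: r / (R * sqrt(1 - (1+Q) r^2/R^2))."""
    scalar = np.isscalar(r)
    r = np.asarray(r, dtype=float)
    R, Q = surface.apical_radius, surface.asphericity_q
    arg = 1.0 - (1.0 + Q) * r**2 / R**2
    if np.any(arg <= 0):
        raise DomainError("slope undefined at or beyond the conicoid equator")
    m = r / (R * np.sqrt(arg))
    return _maybe_scalar(m, scalar)


def surface_normal(surface: ConicSurface, r, theta_deg) -> np.ndarray:
    """Outward (toward incoming light) unit normal at the surface point (r, θ).

    On axis the normal is (0, 0, -1): straight back along the optical axis.
    For a sphere (Q = 0) this equals (p - c)/R with c the center of curvature.
    """
    scalar = np.isscalar(r) and np.isscalar(theta_deg)
    r = np.asarray(r, dtype=float)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    r, th = np.broadcast_arrays(r, th)
    m = sag_slope(surface, r)
    norm = np.sqrt(1.0 + m**2)
    n = np.stack([m * np.cos(th), m * np.sin(th), -np.ones_like(m)], axis=-1)
    n /= norm[..., None]
    return n[0] if (scalar and n.shape == (1, 3)) else n


def _intersect_t(surface: ConicSurface, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Vectorized ray/conicoid intersection path lengths.

    Implicit conicoid: x^2 + y^2 + (1+Q) z'^2 - 2 R z' = 0 with
    z' = z - apex_z.  Returns the smallest positive root on the apex-side
    branch, NaN where the ray misses.  The paraboloid (Q = -1) reduces the
    quadratic to a linear equation, solved exactly.
    """
    R, Q = surface.apical_radius, surface.asphericity_q
    q1 = 1.0 + Q
    ox, oy, oz = origins[..., 0], origins[..., 1], origins[..., 2]
    dx, dy, dz = dirs[..., 0], dirs[..., 1], dirs[..., 2]
    zp0 = oz - surface.apex_z

    a = dx * dx + dy * dy + q1 * dz * dz
    b = 2.0 * (ox * dx + oy * dy + q1 * zp0 * dz - R * dz)
    c = ox * ox + oy * oy + q1 * zp0 * zp0 - 2.0 * R * zp0

    with np.errstate(invalid="ignore", divide="ignore"):
        disc = b * b - 4.0 * a * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        sgn_b = np.where(b >= 0.0, 1.0, -1.0)
        qq = -0.5 * (b + sgn_b * sq)
        lin = np.abs(a) < 1e-14
        t_a = np.where(lin, np.where(np.abs(b) > 1e-300, -c / b, np.nan), qq / a)
        t_b = np.where(lin | (np.abs(qq) < 1e-300), np.nan, c / qq)
        t_a = np.where(~lin & (disc < 0.0), np.nan, t_a)
        t_b = np.where(~lin & (disc < 0.0), np.nan, t_b)

    zmax = R / q1 + 1e-9 if q1 > 0 else np.inf

    def _valid(t):
        zp = zp0 + t * dz
        return np.isfinite(t) & (t > 1e-9) & (zp >= -1e-9) & (zp <= zmax)

    va, vb = _valid(t_a), _valid(t_b)
    t_a = np.where(va, t_a, np.inf)
    t_b = np.where(vb, t_b, np.inf)
    t = np.minimum(t_a, t_b)
    return np.where(np.isfinite(t), t, np.nan)


def ray_surface_intersect(surface: ConicSurface, ray_origin, ray_dir) -> np.ndarray:
    """First intersection point of a forward-travelling ray with the conicoid.

    ``ray_dir`` must be a unit vector with positive axial component.  Solved
    in closed form (quadratic in path length; exact linear solve for the
    degenerate paraboloid).  Raises :class:`NoIntersectionError` when the
    ray misses the surface.
    """
    o = np.asarray(ray_origin, dtype=float)
    d = np.asarray(ray_dir, dtype=float)
    if d[2] <= 0:
        raise DomainError("ray direction must have positive axial component")
    t = _intersect_t(surface, o[None, :], d[None, :])[0]
    if not np.isfinite(t):
        raise NoIntersectionError("ray misses the conicoid surface")
    p = o + t * d
    rho = float(np.hypot(p[0], p[1]))
    if rho > surface.max_aperture_radius * (1 + 1e-9):
        raise NoIntersectionError("intersection outside the surface aperture")
    return p
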