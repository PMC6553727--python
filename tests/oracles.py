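"""Independent oracles used only by the test suite.

These deliberately avoid the package's implementation paths: the meridional
tracer works with scalar angles and a bracketing root find instead of 3-D
vectors and closed-form quadratics, and the repeated-measures ANOVA uses the
textbook partition of sums of squares instead of a model fit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import f as f_dist


def conic_sag(R: float, Q: float, r: float) -> float:
    return r * r / (R * (1.0 + np.sqrt(1.0 - (1.0 + Q) * r * r / (R * R))))


def conic_slope(R: float, Q: float, r: float) -> float:
    return r / (R * np.sqrt(1.0 - (1.0 + Q) * r * r / (R * R)))


def meridional_trace_power(model, h: float) -> float:
    """2-D angle-based trace of an axis-parallel meridional ray at height h
    (mm); returns the Snell power n_aq * sin(U') / h in diopters."""
    c = model.constants
    R1, Q1 = model.anterior.apical_radius, model.anterior.asphericity_q
    R2, Q2 = model.posterior.apical_radius, model.posterior.asphericity_q
    T = model.central_thickness

    z1 = conic_sag(R1, Q1, h)
    a1 = np.arctan(conic_slope(R1, Q1, h))  # incidence = surface slope angle
    i1p = np.arcsin(np.sin(a1) * c.n_air / c.n_cornea)
    u1 = a1 - i1p  # descent angle of the refracted ray w.r.t. the axis

    def gap(t: float) -> float:
        y = h - t * np.sin(u1)
        return (z1 + t * np.cos(u1)) - (T + conic_sag(R2, Q2, abs(y)))

    t = brentq(gap, 0.0, 5.0, xtol=1e-15, rtol=8.9e-16)
    y2 = h - t * np.sin(u1)
    a2 = np.arctan(conic_slope(R2, Q2, abs(y2)) * np.sign(y2))
    i2 = a2 - u1  # signed incidence at the posterior surface
    i2p = np.arcsin(np.sin(i2) * c.n_cornea / c.n_aqueous)
    phi2 = -a2 + i2p  # exit direction angle from the axis (negative = converging)
    return c.n_aqueous * (-np.sin(phi2)) / (h * 1e-3)


def rm_anova_oracle(X: np.ndarray) -> tuple[float, float]:
    """Textbook one-way repeated-measures ANOVA from the sums of squares."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = X.mean()
    ss_methods = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subjects = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_error = ss_total - ss_methods - ss_subjects
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_methods / df1) / (ss_error / df2)
    return F, float(f_dist.sf(F, df1, df2))
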