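"""Spherical-spline surface Laplacian (current source density, CSD) transform.

The scalp potential is interpolated by a spherical spline (Perrin-style):
the spline kernel is

    g(x) = (1 / 4pi) * sum_{n=1..N} (2n+1) / (n^m (n+1)^m) * P_n(x),

with ``x`` the cosine of the angle between electrode directions, ``m`` the
spline stiffness and ``P_n`` Legendre polynomials.  Because the surface
Laplacian of P_n(cos theta) on the unit sphere is -n(n+1) P_n(cos theta), the
Laplacian of the spline uses the companion kernel with exponent ``m - 1``:

    h(x) = (1 / 4pi) * sum_{n=1..N} (2n+1) / (n^{m-1} (n+1)^{m-1}) * P_n(x).

Spline coefficients ``c`` solve the regularized, zero-sum-constrained system
(G + lambda I) c + c0 1 = v, sum(c) = 0, and the CSD (negative surface
Laplacian of the interpolated potential, scaled to physical units) is
H c / r^2 in uV/cm^2 for a head radius ``r`` in cm.

The transform is a fixed channels x channels linear operator: it depends only
on montage geometry and the (m, lambda, N, r) parameters, annihilates
constants (and is therefore reference-free), and maps a surface harmonic of
degree l to l(l+1)/r^2 times itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .core_io import ElectrodeMontage, EpochsArray
from .errors import NumericalError, ValidationError

logger = logging.getLogger("erpdecode")


def _series_coeffs(m: int, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    n = np.arange(1, n_terms + 1, dtype=float)
    g = (2 * n + 1) / (n ** m * (n + 1) ** m) / (4 * np.pi)
    h = (2 * n + 1) / (n ** (m - 1) * (n + 1) ** (m - 1)) / (4 * np.pi)
    return g, h


def _legendre_sum(coeffs: np.ndarray, x: np.ndarray) -> np.ndarray:
    # legval expects coefficients from degree 0; the n=0 term is excluded.
    return legendre.legval(x, np.concatenate(([0.0], coeffs)))


@dataclass
class CSDOperator:
    """Precomputed linear CSD operator for one montage/parameter set."""

    montage: ElectrodeMontage
    m: int
    lam: float
    n_legendre: int
    head_radius: float
    matrix: np.ndarray            # channels x channels, uV -> uV/cm^2
    condition_number: float
    truncation_error: float       # size of the last kept h-series term at x=1

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Apply to a channel vector (or channels x ... array)."""
        return np.tensordot(self.matrix, v, axes=(1, 0))


def build_csd_operator(montage: ElectrodeMontage, m: int = 4, lam: float = 1e-5,
                       n_legendre: int = 50,
                       head_radius: float | None = None) -> CSDOperator:
    """Assemble the channels x channels CSD operator for ``montage``.

    Defaults (m=4, lambda=1e-5, 50 Legendre terms, 10 cm head radius) are the
    de-facto standard spherical-spline CSD parameterization.
    """
    if m < 2:
        raise ValidationError("spline order m must be >= 2")
    pos = montage.positions
    if len(montage.labels) < 3 or np.linalg.matrix_rank(pos) < 3:
        raise ValidationError("need >= 3 non-coplanar electrodes")
    r = montage.head_radius if head_radius is None else head_radius
    cosines = montage.cosine_distances()
    cg, ch = _series_coeffs(m, n_legendre)
    g_mat = _legendre_sum(cg, cosines)
    h_mat = _legendre_sum(ch, cosines)

    n_ch = len(montage.labels)
    reg = g_mat + lam * np.eye(n_ch)
    cond = float(np.linalg.cond(reg))
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(f"regularized spline system is ill-conditioned "
                             f"(condition number {cond:.3g})")
    try:
        g_inv = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"singular spline system (cond={cond:.3g})") from exc
    ones = np.ones(n_ch)
    denom = ones @ g_inv @ ones
    # v -> c with (G + lambda I) c + c0 1 = v and sum(c) = 0
    t_mat = g_inv @ (np.eye(n_ch) - np.outer(ones, ones @ g_inv) / denom)
    matrix = (h_mat @ t_mat) / r ** 2

    trunc = float(ch[-1])  # magnitude of the last h-series term at x = 1
    logger.info("CSD operator: m=%d lambda=%g N=%d r=%g cm, cond=%.3g, "
                "series tail=%.3g", m, lam, n_legendre, r, cond, trunc)
    return CSDOperator(montage, m, lam, n_legendre, r, matrix, cond, trunc)


def dense_sphere_montage(n: int = 64, head_radius: float = 10.0) -> ElectrodeMontage:
    """A synthetic montage of ``n`` Fibonacci-lattice points covering the whole
    sphere.

    Used to validate the operator against the analytic eigenfunctions of the
    sphere's Laplace-Beltrami operator: on a full-sphere sampling the spline
    has no extrapolation boundary, so a degree-l surface harmonic must map to
    l(l+1)/r^2 times itself.  (On a scalp montage the rim electrodes sit at
    the edge of the sampled cap and carry the usual surface-Laplacian edge
    error.)
    """
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z ** 2)
    pos = np.column_stack([rho * np.cos(golden * i), rho * np.sin(golden * i), z])
    return ElectrodeMontage(tuple(f"E{k:02d}" for k in range(n)), pos, head_radius)


def apply_csd(epochs: EpochsArray, operator: CSDOperator) -> EpochsArray:
    """Transform epochs (uV) to current source density (uV/cm^2)."""
    if tuple(epochs.channel_labels) != tuple(operator.montage.labels):
        raise ValidationError("epoch channel labels do not match the CSD "
                              "operator's montage")
    out = epochs.copy()
    out.data = np.einsum("ij,tjs->tis", operator.matrix, out.data)
    out.units = "uV/cm^2"
    return out
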