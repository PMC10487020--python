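"""M-spline and I-spline basis construction.

M-splines are non-negative polynomial spline basis functions normalised to
integrate to one over their support (Ramsay's definition).  I-splines are
their running integrals: each rises monotonically from 0 at the lower
boundary to 1 at the upper boundary.  A non-negative linear combination of
I-splines is therefore a monotone non-decreasing function, which is the
property the conversion models rely on.

M-splines are evaluated with the classic recursion

    M_{i,1}(x) = 1 / (t_{i+1} - t_i)          on [t_i, t_{i+1})
    M_{i,k}(x) = k [ (x - t_i) M_{i,k-1}(x) + (t_{i+k} - x) M_{i+1,k-1}(x) ]
                 / ( (k-1) (t_{i+k} - t_i) )

on a knot vector with the boundary knots repeated ``order`` times.  I-splines
use the exact B-spline identity: the I-spline of degree d is a tail sum of
B-splines of degree d+1 on the same interior knots, which lets
:class:`scipy.interpolate.BSpline` do the numerically careful part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ValidationError

__all__ = ["SplineSpec", "BasisMatrix", "build_ispline_basis", "build_mspline_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Defines one spline basis: polynomial degree, knots and boundaries.

    Parameters
    ----------
    degree
        Polynomial degree of the M-spline pieces (>= 0). The I-splines are
        piecewise polynomials of degree ``degree + 1``.
    internal_knots
        Non-decreasing knot positions strictly inside
        ``(boundary_lower, boundary_upper)``, in uIU/mL.
    boundary_lower, boundary_upper
        Support of the basis, in uIU/mL.
    """

    degree: int
    internal_knots: tuple[float, ...]
    boundary_lower: float
    boundary_upper: float

    def __post_init__(self):
        if int(self.degree) != self.degree or self.degree < 0:
            raise ValidationError(f"degree must be a non-negative integer, got {self.degree}")
        object.__setattr__(self, "degree", int(self.degree))
        object.__setattr__(self, "internal_knots", tuple(float(k) for k in self.internal_knots))
        if not np.all(np.isfinite([self.boundary_lower, self.boundary_upper])):
            raise ValidationError("boundaries must be finite")
        if not self.boundary_lower < self.boundary_upper:
            raise ValidationError(
                f"boundary_lower ({self.boundary_lower}) must be < boundary_upper "
                f"({self.boundary_upper})"
            )
        ik = np.asarray(self.internal_knots, dtype=float)
        if ik.size:
            if not np.all(np.isfinite(ik)):
                raise ValidationError("internal knots must be finite")
            if np.any(np.diff(ik) < 0):
                raise ValidationError("internal knots must be non-decreasing")
            if ik[0] <= self.boundary_lower or ik[-1] >= self.boundary_upper:
                raise ValidationError("internal knots must lie strictly inside the boundaries")

    @property
    def order(self) -> int:
        """Spline order of the M-spline pieces (degree + 1)."""
        return self.degree + 1

    @property
    def n_basis(self) -> int:
        """Number of basis functions: order + number of internal knots."""
        return self.order + len(self.internal_knots)

    def mspline_knots(self) -> np.ndarray:
        """Full knot vector for the M-spline recursion (boundaries x order)."""
        k = self.order
        return np.concatenate([
            np.full(k, self.boundary_lower),
            np.asarray(self.internal_knots, dtype=float),
            np.full(k, self.boundary_upper),
        ])

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "internal_knots": list(self.internal_knots),
            "boundary_lower": self.boundary_lower,
            "boundary_upper": self.boundary_upper,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            degree=d["degree"],
            internal_knots=tuple(d["internal_knots"]),
            boundary_lower=d["boundary_lower"],
            boundary_upper=d["boundary_upper"],
        )


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis: ``values`` is n_points x n_basis, ``kind`` is 'M' or 'I'."""

    values: np.ndarray
    spec: SplineSpec
    kind: str = field(default="I")

    def __post_init__(self):
        if self.kind not in ("M", "I"):
            raise ValidationError(f"kind must be 'M' or 'I', got {self.kind!r}")


def _validate_xs(xs, spec: SplineSpec) -> np.ndarray:
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if xs.ndim != 1:
        raise ValidationError("xs must be one-dimensional")
    if not np.all(np.isfinite(xs)):
        raise ValidationError("xs contains non-finite values")
    if spec.n_basis < 1:
        raise ValidationError("spec implies fewer than one basis function")
    # values outside the support are clamped; range gating is the caller's job
    return np.clip(xs, spec.boundary_lower, spec.boundary_upper)


def build_mspline_basis(xs, spec: SplineSpec) -> BasisMatrix:
    """Evaluate the M-spline basis at ``xs`` (clamped to the support)."""
    x = _validate_xs(xs, spec)
    t = spec.mspline_knots()
    k = spec.order
    n_total = len(t) - 1  # number of order-1 splines on this knot vector

    # order 1: indicator / knot-interval width; right-closed at the support end
    m = np.zeros((x.size, n_total))
    for i in range(n_total):
        if t[i + 1] > t[i]:
            inside = (x >= t[i]) & (x < t[i + 1])
            if t[i + 1] == spec.boundary_upper:
                inside |= x == spec.boundary_upper
            m[inside, i] = 1.0 / (t[i + 1] - t[i])

    for order in range(2, k + 1):
        n_cur = len(t) - order
        m_new = np.zeros((x.size, n_cur))
        for i in range(n_cur):
            denom = t[i + order] - t[i]
            if denom > 0:
                m_new[:, i] = (
                    order
                    * ((x - t[i]) * m[:, i] + (t[i + order] - x) * m[:, i + 1])
                    / ((order - 1) * denom)
                )
        m = m_new

    return BasisMatrix(values=m, spec=spec, kind="M")


def build_ispline_basis(xs, spec: SplineSpec) -> BasisMatrix:
    """Evaluate the I-spline basis at ``xs`` (clamped to the support).

    Each column is the running integral of the matching M-spline column:
    0 at the lower boundary, 1 at the upper boundary, non-decreasing in
    between.  Computed exactly via the tail-sum B-spline identity.
    """
    x = _validate_xs(xs, spec)
    kb = spec.order  # B-spline degree for the identity = M-spline degree + 1
    t2 = np.concatenate([
        np.full(kb + 1, spec.boundary_lower),
        np.asarray(spec.internal_knots, dtype=float),
        np.full(kb + 1, spec.boundary_upper),
    ])
    design = BSpline.design_matrix(x, t2, kb).toarray()
    # I_i = sum of B-splines j > i; dropping the full sum (identically 1)
    tail = np.cumsum(design[:, ::-1], axis=1)[:, ::-1]
    values = np.clip(tail[:, 1:], 0.0, 1.0)
    assert values.shape[1] == spec.n_basis
    return BasisMatrix(values=values, spec=spec, kind="I")
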