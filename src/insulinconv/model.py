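"""Directed monotone conversion models between insulin immunoassays.

One model converts a concentration measured on assay X into the concentration
that assay Y would have reported.  The regression function is a non-negative
linear combination of an intercept and I-spline basis functions, solved
jointly by non-negative least squares, which makes the fitted curve monotone
non-decreasing and non-negative by construction.  Because each direction is
fitted separately, X->Y and Y->X are not exact inverses of each other.

Prediction intervals condition on the selected active set and apply the
classical Gaussian linear-model formula with t quantiles

    estimate +/- t(1 - alpha/2, dof) * sigma * sqrt(1 + h(x0)),
    h(x0) = b0' (Xa' Xa)^{-1} b0

where ``b0`` is the [1 | active basis] row at the query point.  Coverage is
approximate near the non-negativity constraint boundaries.

The model's input range is gated: no prediction is made below the smallest
training value or above the largest training value minus one (the cap that
keeps the spline away from edge artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateDataError, ValidationError
from .nnls import nnls_solve
from .splines import SplineSpec, build_ispline_basis

__all__ = [
    "ACTIVE_TOL",
    "MonotoneSplineRegressor",
    "ConversionModel",
    "default_spline_spec",
    "fit_conversion",
    "predict_with_interval",
    "r_squared",
]

#: a coefficient counts as active (occupies a degree of freedom) above this
ACTIVE_TOL = 1e-10

_MONO_GRID = 512


#: default internal-knot placement: the quartiles plus two tail knots, which
#: keep the fit honest at the sparse extremes of right-skewed insulin data
DEFAULT_KNOT_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def default_spline_spec(x: np.ndarray, degree: int = 3,
                        knot_quantiles: tuple[float, ...] = DEFAULT_KNOT_QUANTILES) -> SplineSpec:
    """Data-driven default basis: boundary knots at the training extremes,
    internal knots at the stated quantiles of the training inputs
    (deduplicated, dropped when coincident with a boundary)."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    qs = np.quantile(x, knot_quantiles) if knot_quantiles else np.array([])
    internal = sorted({float(q) for q in qs if lo < q < hi})
    return SplineSpec(degree=degree, internal_knots=tuple(internal),
                      boundary_lower=lo, boundary_upper=hi)


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SSE/SST, clipped to [0, 1]."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.ndim != 1 or obs.size < 2:
        raise ValidationError("observed and fitted must be equal-length vectors of length >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValidationError("observed values have zero variance")
    sse = float(np.sum((obs - fit) ** 2))
    return float(np.clip(1.0 - sse / sst, 0.0, 1.0))


def _fit_arrays(x: np.ndarray, y: np.ndarray, spec: SplineSpec | None) -> dict:
    """Shared fitting core; returns the extracted model fields."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValidationError("x and y must be equal-length non-empty vectors")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("x and y must be finite")

    if np.unique(x).size == 1:
        raise DegenerateDataError("degenerate predictor: all input values identical")
    if np.unique(x).size < 3:
        raise DegenerateDataError("need at least 3 distinct input values")

    if spec is None:
        spec = default_spline_spec(x)
    n = x.size
    n_min = max(8, spec.n_basis + 2)
    if n < n_min:
        raise DegenerateDataError(f"too few samples: n={n}, need at least {n_min}")

    input_min = float(np.min(x))
    input_cap = float(np.max(x)) - 1.0
    if np.max(x) < 1.0 or input_cap <= input_min:
        raise DegenerateDataError(
            "training range too narrow: cap (max observed - 1) does not exceed the minimum"
        )

    basis = build_ispline_basis(x, spec).values
    design = np.column_stack([np.ones(n), basis])
    coef_all = nnls_solve(design, y)
    intercept, coef = float(coef_all[0]), coef_all[1:]

    fitted = design @ coef_all
    rss = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = float(np.clip(1.0 - rss / sst, 0.0, 1.0)) if sst > 0 else 0.0

    n_active = int(np.sum(coef_all > ACTIVE_TOL))
    dof = n - n_active
    if dof <= 0:
        raise DegenerateDataError(f"no residual degrees of freedom (n={n}, active={n_active})")
    sigma = float(np.sqrt(rss / dof))

    active_idx = [int(j) for j in np.flatnonzero(coef > ACTIVE_TOL)]
    cols = [0] + [j + 1 for j in active_idx]  # intercept column always retained
    xa = design[:, cols]
    gram_inv = np.linalg.pinv(xa.T @ xa)

    out = {
        "spec": spec, "intercept": intercept, "coefficients": coef,
        "sigma": sigma, "dof": dof, "active_idx": active_idx,
        "active_gram_inverse": gram_inv, "n_train": n, "r_squared": r2,
        "input_min": input_min, "input_cap": input_cap,
    }
    _check_monotone(out)
    return out


def _predict_arrays(fields: dict, x: np.ndarray) -> np.ndarray:
    basis = build_ispline_basis(x, fields["spec"]).values
    return fields["intercept"] + basis @ fields["coefficients"]


def _check_monotone(fields: dict) -> None:
    grid = np.linspace(fields["input_min"], fields["input_cap"], _MONO_GRID)
    pred = _predict_arrays(fields, grid)
    if np.any(np.diff(pred) < -1e-8) or np.any(pred < -1e-12):
        raise RuntimeError("fitted curve failed the monotone/non-negative grid check")


def _interval_arrays(fields: dict, x: np.ndarray, level: float):
    if not 0.0 < level < 1.0:
        raise ValidationError(f"interval level must be in (0, 1), got {level}")
    x = np.asarray(x, dtype=float)
    basis = build_ispline_basis(x, fields["spec"]).values
    est = fields["intercept"] + basis @ fields["coefficients"]
    b0 = np.column_stack([np.ones(x.size), basis[:, fields["active_idx"]]])
    h = np.einsum("ij,jk,ik->i", b0, fields["active_gram_inverse"], b0)
    tq = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df=fields["dof"])
    width = tq * fields["sigma"] * np.sqrt(1.0 + np.maximum(h, 0.0))
    lower = np.maximum(est - width, 0.0)  # concentrations are non-negative
    upper = est + width
    return est, lower, upper


class MonotoneSplineRegressor(RegressorMixin, BaseEstimator):
    """Monotone non-decreasing I-spline regression fitted by NNLS.

    scikit-learn-style estimator over univariate inputs. The design matrix is
    ``[1 | I-spline basis]`` and every coefficient, intercept included, is
    constrained non-negative, so the fitted curve is non-decreasing and
    non-negative everywhere.

    Parameters
    ----------
    degree : int, default 3
        Polynomial degree of the underlying M-spline pieces.
    knot_quantiles : tuple of float, default (0.05, 0.25, 0.5, 0.75, 0.95)
        Quantiles of the training inputs at which internal knots are placed
        (ignored when ``spec`` is given).
    spec : SplineSpec or None
        Explicit basis specification overriding the data-driven default.

    Attributes
    ----------
    spec_ : SplineSpec
    intercept_ : float
    coef_ : ndarray of shape (n_basis,)
    sigma_ : float
        Residual standard deviation (uIU/mL).
    dof_ : int
        Residual degrees of freedom, n minus the number of strictly positive
        coefficients (intercept included).
    active_idx_ : list of int
        Indices of the active spline coefficients.
    gram_inv_ : ndarray
        Inverse Gram matrix over [intercept | active columns], used for
        prediction-interval widths.
    r_squared_ : float
    input_min_, input_cap_ : float
        Supported input range; the cap is the largest training input minus
        one, so the spline is never evaluated at its extrapolation edge.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> x = rng.uniform(1, 100, 200)
    >>> y = 2 * x + rng.normal(0, 1, 200)
    >>> reg = MonotoneSplineRegressor().fit(x[:, None], y)
    >>> est, lo, hi = reg.predict_interval(np.array([[50.0]]))
    """

    def __init__(self, degree: int = 3,
                 knot_quantiles: tuple[float, ...] = DEFAULT_KNOT_QUANTILES,
                 spec: SplineSpec | None = None):
        self.degree = degree
        self.knot_quantiles = knot_quantiles
        self.spec = spec

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValidationError("expected a single input column")
            x = x[:, 0]
        elif x.ndim != 1:
            raise ValidationError("X must be 1-d or a single-column 2-d array")
        return x

    def fit(self, X, y):
        x = self._as_1d(X)
        spec = self.spec
        if spec is None and x.size and np.all(np.isfinite(x)) and np.unique(x).size >= 3:
            spec = default_spline_spec(x, self.degree, tuple(self.knot_quantiles))
        fields = _fit_arrays(x, np.asarray(y, dtype=float), spec)
        self.spec_ = fields["spec"]
        self.intercept_ = fields["intercept"]
        self.coef_ = fields["coefficients"]
        self.sigma_ = fields["sigma"]
        self.dof_ = fields["dof"]
        self.active_idx_ = fields["active_idx"]
        self.gram_inv_ = fields["active_gram_inverse"]
        self.n_train_ = fields["n_train"]
        self.r_squared_ = fields["r_squared"]
        self.input_min_ = fields["input_min"]
        self.input_cap_ = fields["input_cap"]
        self.n_features_in_ = 1
        return self

    def _fields(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "spec": self.spec_, "intercept": self.intercept_,
            "coefficients": self.coef_, "sigma": self.sigma_, "dof": self.dof_,
            "active_idx": self.active_idx_, "active_gram_inverse": self.gram_inv_,
            "n_train": self.n_train_, "r_squared": self.r_squared_,
            "input_min": self.input_min_, "input_cap": self.input_cap_,
        }

    def predict(self, X) -> np.ndarray:
        return _predict_arrays(self._fields(), self._as_1d(X))

    def predict_interval(self, X, level: float = 0.95):
        """Point estimates with prediction intervals at ``level``."""
        return _interval_arrays(self._fields(), self._as_1d(X), level)

    def to_conversion_model(self, from_assay: str, to_assay: str) -> "ConversionModel":
        """Extract the fitted formula as a self-contained directed model."""
        return ConversionModel(from_assay=from_assay, to_assay=to_assay, **self._fields())


@dataclass
class ConversionModel:
    """A fitted directed conversion, extracted to closed-form coefficients.

    Self-contained: prediction and interval formulas need only these fields,
    never the training data, so a serialised model reproduces estimates and
    intervals exactly.
    """

    from_assay: str
    to_assay: str
    spec: SplineSpec
    intercept: float
    coefficients: np.ndarray
    sigma: float
    dof: int
    active_idx: list[int]
    active_gram_inverse: np.ndarray
    n_train: int
    r_squared: float
    input_min: float
    input_cap: float

    def _fields(self) -> dict:
        return {
            "spec": self.spec, "intercept": self.intercept,
            "coefficients": self.coefficients, "sigma": self.sigma,
            "dof": self.dof, "active_idx": self.active_idx,
            "active_gram_inverse": self.active_gram_inverse,
            "n_train": self.n_train, "r_squared": self.r_squared,
            "input_min": self.input_min, "input_cap": self.input_cap,
        }

    def predict(self, x):
        scalar = np.isscalar(x)
        out = _predict_arrays(self._fields(), np.atleast_1d(np.asarray(x, dtype=float)))
        return float(out[0]) if scalar else out

    def predict_with_interval(self, x, level: float = 0.95):
        scalar = np.isscalar(x)
        est, lo, hi = _interval_arrays(
            self._fields(), np.atleast_1d(np.asarray(x, dtype=float)), level)
        if scalar:
            return float(est[0]), float(lo[0]), float(hi[0])
        return est, lo, hi

    def in_range(self, x: float) -> bool:
        return self.input_min <= x <= self.input_cap

    def to_dict(self) -> dict:
        return {
            "from_assay": self.from_assay,
            "to_assay": self.to_assay,
            "spec": self.spec.to_dict(),
            "intercept": self.intercept,
            "coefficients": [float(c) for c in self.coefficients],
            "sigma": self.sigma,
            "dof": self.dof,
            "active_idx": list(self.active_idx),
            "gram_inverse": [[float(v) for v in row] for row in self.active_gram_inverse],
            "input_min": self.input_min,
            "input_cap": self.input_cap,
            "n_train": self.n_train,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionModel":
        return cls(
            from_assay=d["from_assay"], to_assay=d["to_assay"],
            spec=SplineSpec.from_dict(d["spec"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            sigma=float(d["sigma"]), dof=int(d["dof"]),
            active_idx=[int(i) for i in d["active_idx"]],
            active_gram_inverse=np.asarray(d["gram_inverse"], dtype=float),
            n_train=int(d["n_train"]), r_squared=float(d["r_squared"]),
            input_min=float(d["input_min"]), input_cap=float(d["input_cap"]),
        )


def fit_conversion(data, from_assay: str, to_assay: str,
                   spec: SplineSpec | None = None) -> ConversionModel:
    """Fit one directed conversion model from a merged comparison dataset.

    ``data`` is a :class:`~insulinconv.registry.ComparisonDataset` whose
    canonical pair must contain both assay ids; the orientation is chosen
    accordingly. Samples are pooled across sources with equal weight and
    sorted by input before fitting (sample order never affects the fit).
    """
    pair = tuple(data.pair)
    if {from_assay, to_assay} != set(pair) or from_assay == to_assay:
        raise ValidationError(
            f"direction {from_assay}->{to_assay} does not match dataset pair {pair}")
    xs = np.array([s.x for s in data.samples], dtype=float)
    ys = np.array([s.y for s in data.samples], dtype=float)
    if from_assay != pair[0]:
        xs, ys = ys, xs
    order = np.lexsort((ys, xs))
    fields = _fit_arrays(xs[order], ys[order], spec)
    return ConversionModel(from_assay=from_assay, to_assay=to_assay, **fields)


def predict_with_interval(model: ConversionModel, x0: float, level: float = 0.95):
    """Point estimate and prediction interval for one converted value."""
    return model.predict_with_interval(x0, level=level)
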