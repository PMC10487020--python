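"""Non-negative least squares behind a validated interface.

The solver is Lawson-Hanson active-set NNLS as implemented by
:func:`scipy.optimize.nnls`; this module adds the input contract the rest of
the package relies on (finite inputs, non-degenerate design, convergence
diagnostics).
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

from .exceptions import ValidationError

__all__ = ["nnls_solve"]


def nnls_solve(design: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Minimise ``||design @ beta - response||^2`` subject to ``beta >= 0``.

    Parameters
    ----------
    design
        n x p matrix, finite, with at least one nonzero column.
    response
        Length-n vector, finite.

    Returns
    -------
    numpy.ndarray
        The length-p non-negative coefficient vector satisfying the NNLS
        KKT conditions.
    """
    a = np.asarray(design, dtype=float)
    b = np.asarray(response, dtype=float)
    if a.ndim != 2:
        raise ValidationError("design must be a 2-d matrix")
    if b.ndim != 1 or b.size != a.shape[0]:
        raise ValidationError("response must be a vector matching the design's rows")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ValidationError("design must have at least one row and one column")
    if not np.all(np.isfinite(a)) or not np.all(np.isfinite(b)):
        raise ValidationError("design and response must be finite")
    if not np.any(a):
        raise ValidationError("degenerate all-zero design matrix")
    try:
        coef, _ = scipy.optimize.nnls(a, b)
    except RuntimeError as exc:  # iteration limit
        raise ValidationError(
            f"NNLS failed to converge on a {a.shape[0]}x{a.shape[1]} problem: {exc}"
        ) from exc
    return coef
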