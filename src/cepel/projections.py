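"""Scalar projection functions used to decompose multidimensional data.

A projection maps a d-dimensional point to a scalar; the projected sample is
then handed to the 1-d estimator.  Supported kinds:

- ``axis``: a coordinate.
- ``linear``: dot product with a unit direction vector.
- ``radial``: Euclidean distance to a centre point.
- ``regression_along`` / ``regression_residual``: arc position along, and
  signed perpendicular distance to, an ordinary least-squares line fitted to
  2-d data.
- ``eigen``: coordinate along a unit eigenvector of the sample covariance
  (data centred at the sample mean).
- ``log_residual``: residual of a least-squares logarithmic curve
  ``y = a*ln(x) + b`` (abscissa must be positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kde1d import Sample1D, ValidationError

__all__ = [
    "Projection",
    "project",
    "fit_regression_line",
    "fit_eigen_projections",
    "fit_log_curve",
]

KINDS = ("axis", "linear", "radial", "regression_residual",
         "regression_along", "eigen", "log_residual")


@dataclass(frozen=True)
class Projection:
    """A scalar-valued map on d-dimensional points, with typed parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"unknown projection kind {self.kind!r}")
        p = dict(self.params)
        for key in ("direction", "eigenvector", "center", "mean"):
            if key in p:
                p[key] = np.asarray(p[key], dtype=float)
        for key in ("direction", "eigenvector"):
            if key in p:
                norm = float(np.linalg.norm(p[key]))
                if norm == 0.0:
                    raise ValidationError(f"{key} must be nonzero")
                p[key] = p[key] / norm
        object.__setattr__(self, "params", p)

    def __call__(self, points) -> np.ndarray:
        return _apply(self, _as_points(points))


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2:
        raise ValidationError("points must be a 2-d array (n, d)")
    return pts


def _check_dim(pts: np.ndarray, d: int):
    if pts.shape[1] != d:
        raise ValidationError(
            f"dimension mismatch: points have d={pts.shape[1]}, projection expects d={d}")


def _apply(proj: Projection, pts: np.ndarray) -> np.ndarray:
    p = proj.params
    kind = proj.kind
    if kind == "axis":
        idx = int(p["index"])
        if not (0 <= idx < pts.shape[1]):
            raise ValidationError("axis index out of range")
        return pts[:, idx]
    if kind == "linear":
        w = p["direction"]
        _check_dim(pts, w.size)
        return pts @ w
    if kind == "radial":
        c = p["center"]
        _check_dim(pts, c.size)
        return np.linalg.norm(pts - c, axis=1)
    if kind in ("regression_residual", "regression_along"):
        _check_dim(pts, 2)
        m, b = float(p["slope"]), float(p["intercept"])
        x, y = pts[:, 0], pts[:, 1]
        scale = np.sqrt(1.0 + m * m)
        if kind == "regression_residual":
            # signed perpendicular distance to the OLS line
            return (y - (m * x + b)) / scale
        # arc position along the line at the point's abscissa, measured from
        # the fit's mean abscissa; uncorrelated with the residual by the OLS
        # normal equations
        return (x - float(p.get("x_mean", 0.0))) * scale
    if kind == "eigen":
        v = p["eigenvector"]
        _check_dim(pts, v.size)
        mean = p.get("mean", np.zeros(v.size))
        return (pts - mean) @ v
    if kind == "log_residual":
        _check_dim(pts, 2)
        x, y = pts[:, 0], pts[:, 1]
        if np.any(x <= 0):
            raise ValidationError("log_residual requires positive abscissa")
        return y - (float(p["a"]) * np.log(x) + float(p["b"]))
    raise ValidationError(f"unknown projection kind {kind!r}")  # pragma: no cover


def project(points, projection: Projection) -> Sample1D:
    """Project points to scalars, returned as a :class:`Sample1D`."""
    return Sample1D(_apply(projection, _as_points(points)))


def fit_regression_line(points) -> tuple[Projection, Projection]:
    """Fit the OLS line of the second coordinate on the first.

    Returns the pair ``(regression_along, regression_residual)``.  The along
    projection is the arc position on the line corresponding to a point's
    abscissa; the residual is the signed perpendicular distance to the line.
    On the fitting data the two are exactly uncorrelated.
    """
    pts = _as_points(points)
    _check_dim(pts, 2)
    if pts.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.var(x))
    if sxx == 0.0:
        raise ValidationError("zero variance in the first coordinate")
    m = float(np.cov(x, y, bias=True)[0, 1] / sxx)
    b = float(np.mean(y) - m * np.mean(x))
    params = {"slope": m, "intercept": b, "x_mean": float(np.mean(x))}
    return (Projection("regression_along", params),
            Projection("regression_residual", params))


def fit_eigen_projections(points) -> list[Projection]:
    """Eigenvector projections of the sample covariance, descending eigenvalue.

    Data are centred at the sample mean; eigenvector signs are fixed so the
    largest-magnitude component is positive.  Zero-variance directions are
    flagged in the projection parameters (``zero_variance``) but returned.
    """
    pts = _as_points(points)
    n, d = pts.shape
    if n < d + 1:
        raise ValidationError(f"need at least d+1={d + 1} points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, bias=True).reshape(d, d)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    out = []
    tol = 1e-12 * max(float(evals.max()), 1.0)
    for rank, k in enumerate(order):
        v = evecs[:, k]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        out.append(Projection("eigen", {
            "eigenvector": v,
            "mean": mean,
            "eigenvalue": float(evals[k]),
            "rank": rank,
            "zero_variance": bool(evals[k] <= tol),
        }))
    return out


def fit_log_curve(points) -> tuple[Projection, Projection]:
    """Least-squares fit of ``y = a*ln(x) + b`` on 2-d data with x > 0.

    Returns ``(abscissa axis projection, log_residual projection)``.
    """
    pts = _as_points(points)
    _check_dim(pts, 2)
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x <= 0):
        raise ValidationError("logarithmic fit requires positive abscissa")
    lx = np.log(x)
    if float(np.var(lx)) == 0.0:
        raise ValidationError("zero variance in ln(abscissa)")
    a = float(np.cov(lx, y, bias=True)[0, 1] / np.var(lx))
    b = float(np.mean(y) - a * np.mean(lx))
    return (Projection("axis", {"index": 0}),
            Projection("log_residual", {"a": a, "b": b}))
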