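"""Radial-mixture density estimation for clustered data.

The pipeline estimates the density of clustered, noise-contaminated data in
three steps:

1. candidate cluster centres: the data are projected on each coordinate axis,
   a 1-d density is estimated, and for every mode the data point whose
   projection lies closest to it is picked; candidates from all axes are
   pooled and deduplicated;
2. for every candidate a radial projection (distance to the candidate) is
   fitted with the 1-d estimator, giving one back-projected density per
   candidate;
3. greedy forward selection: starting from the single most likely radial
   component, components are added as long as the normalised leave-one-out
   log-likelihood of the mean-combined model improves by at least
   ``gain_threshold``.

The combined estimate is p(x) = (1/K) * sum_k p_k(||x - c_k||), normalised
over a bounded support box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kde1d import (DEFAULT_CONFIG, Density1D, KDEConfig, Sample1D,
                    ValidationError, find_modes, fit_kde1d)
from .models import (CepelModel, Component, SupportBox, normalize,
                     radial_box_integral, radial_jacobian)
from .projections import Projection, _as_points

__all__ = [
    "ClusterConfig",
    "RadialMixture",
    "find_candidates",
    "greedy_select",
    "estimate_density",
    "fit_radial_mixture",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class ClusterConfig:
    """``gain_threshold`` is the minimum increase of the normalised LOO
    log-likelihood (nats per dimension) required to accept another radial
    component; ``dedup_radius`` defaults to 10% of the data's RMS spread."""

    gain_threshold: float = 0.01
    max_components: int = 20
    dedup_radius: float | None = None
    kde: KDEConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self):
        if self.gain_threshold < 0:
            raise ValidationError("gain_threshold must be >= 0")
        if self.max_components < 1:
            raise ValidationError("max_components must be >= 1")


@dataclass
class RadialMixture:
    """A selected set of radial components: centres (members of the data),
    their distance densities, and the greedy selection trace."""

    centers: np.ndarray            # (K, d)
    densities: list[Density1D]
    trace: list[dict]              # per accepted step: candidate, score, gain
    support: SupportBox
    integrals: np.ndarray          # per-component back-projection integral
    n_points: int

    @property
    def n_components(self) -> int:
        return self.centers.shape[0]

    def evaluator(self):
        """Unnormalised mean-combined density as a callable on points."""
        centers, dens = self.centers, self.densities
        d = centers.shape[1]

        def f(points):
            pts = _as_points(points)
            vals = np.stack([
                p(r := np.linalg.norm(pts - c, axis=1))
                / radial_jacobian(r, d, p.global_bandwidth)
                for c, p in zip(centers, dens)])
            return vals.mean(axis=0)

        return f


def _rms_spread(pts: np.ndarray) -> float:
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred * centred, axis=1))))


def find_candidates(data, config: ClusterConfig = ClusterConfig()) -> np.ndarray:
    """Candidate cluster centres from per-axis mode finding.

    Every candidate is an element of the input data (the point whose axis
    projection is closest to a mode).  Candidates closer than the
    deduplication radius to an already kept one are dropped, in axis-major,
    mode-ascending order.
    """
    pts = _as_points(data)
    n, d = pts.shape
    if n < 2:
        raise ValidationError("need at least 2 points")
    radius = config.dedup_radius
    if radius is None:
        radius = 0.1 * _rms_spread(pts)
    picked: list[np.ndarray] = []
    for axis in range(d):
        proj = pts[:, axis]
        if np.ptp(proj) == 0.0:
            warnings.warn(f"axis {axis} has zero variance; skipped")
            continue
        dens = fit_kde1d(Sample1D(proj), config.kde)
        for mode in find_modes(dens):
            idx = int(np.argmin(np.abs(proj - mode)))
            cand = pts[idx]
            if all(np.linalg.norm(cand - p) > radius for p in picked):
                picked.append(cand)
    if not picked:
        raise ValidationError("no candidate centres found")
    return np.array(picked)


def _prepare_components(candidates: np.ndarray, pts: np.ndarray,
                        support: SupportBox, config: ClusterConfig,
                        seed: int = 0):
    """Fit one radial density per candidate and precompute the per-point LOO
    densities and the back-projection integral over the support box."""
    d = pts.shape[1]
    densities, loo_rows, integrals = [], [], []
    for c in candidates:
        r = np.linalg.norm(pts - c, axis=1)
        dens = fit_kde1d(Sample1D(r), config.kde)
        densities.append(dens)
        loo_rows.append(dens.loo_density_at_fit_points()
                        / radial_jacobian(r, d, dens.global_bandwidth))
        integrals.append(radial_box_integral(dens, c, support,
                                             dens.global_bandwidth, seed=seed))
    return densities, np.array(loo_rows), np.array(integrals)


def _subset_score(loo: np.ndarray, integrals: np.ndarray, members: list[int],
                  d: int) -> float:
    """Normalised LOO score of the mean-combined model over a candidate subset.

    The mean combiner's integral is the mean of the per-component integrals,
    so normalisation is exact given the precomputed values.
    """
    mean_loo = loo[members].mean(axis=0)
    z = 1.0 / max(float(integrals[members].mean()), _LOG_FLOOR)
    return float(np.mean(np.log(np.maximum(mean_loo * z, _LOG_FLOOR)))) / d


def greedy_select(candidates, data, config: ClusterConfig = ClusterConfig(),
                  support: SupportBox | None = None, seed: int = 0) -> RadialMixture:
    """Forward selection of radial components by normalised LOO likelihood.

    Starts from the single most likely component; each further component must
    raise the score by at least ``gain_threshold``.  Equal gains resolve to
    the lower candidate index.
    """
    pts = _as_points(data)
    cands = _as_points(candidates)
    n, d = pts.shape
    if support is None:
        support = SupportBox.from_data(pts)
    densities, loo, integrals = _prepare_components(cands, pts, support, config,
                                                    seed=seed)
    n_cand = cands.shape[0]
    scores0 = np.array([_subset_score(loo, integrals, [k], d)
                        for k in range(n_cand)])
    first = int(np.argmax(scores0))
    members = [first]
    score = float(scores0[first])
    trace = [{"candidate": first, "score": score, "gain": float("inf")}]
    remaining = [k for k in range(n_cand) if k != first]
    while remaining and len(members) < config.max_components:
        gains = np.array([
            _subset_score(loo, integrals, members + [k], d) - score
            for k in remaining])
        j = int(np.argmax(gains))
        if gains[j] < config.gain_threshold:
            break
        k = remaining.pop(j)
        members.append(k)
        score += float(gains[j])
        trace.append({"candidate": k, "score": score, "gain": float(gains[j])})
    return RadialMixture(
        centers=cands[members],
        densities=[densities[k] for k in members],
        trace=trace,
        support=support,
        integrals=integrals[members],
        n_points=n,
    )


def estimate_density(mixture: RadialMixture,
                     support: SupportBox | None = None, seed: int = 0) -> CepelModel:
    """The normalised mean-combined model of a fitted radial mixture."""
    box = support if support is not None else mixture.support
    comps = tuple(
        Component(Projection("radial", {"center": c}), dens)
        for c, dens in zip(mixture.centers, mixture.densities))
    model = CepelModel(components=comps, combiner="mean",
                       dimensionality=mixture.centers.shape[1],
                       support=box, name="radial_mixture")
    return normalize(model, box, seed=seed)


def fit_radial_mixture(data, config: ClusterConfig = ClusterConfig(),
                       support: SupportBox | None = None,
                       seed: int = 0) -> RadialMixture:
    """Full pipeline: candidates, greedy selection."""
    pts = _as_points(data)
    if support is None:
        support = SupportBox.from_data(pts)
    cands = find_candidates(pts, config)
    return greedy_select(cands, pts, config, support=support, seed=seed)
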