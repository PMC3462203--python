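"""Seeded synthetic-data generators for every input family used in tests
and examples: clustered points with uniform background noise, correlated
feature pairs, and piecewise-homogeneous textured toy images with ground
truth partitions.

All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kde1d import ValidationError

__all__ = ["gen_clustered", "gen_pair", "gen_images", "gen_nested_image"]


def gen_clustered(d: int, n: int, clusters_per_dim: int = 3,
                  cluster_sigma: float = 0.05, noise_fraction: float = 0.1,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian clusters plus uniform background noise on [0, 1]^d.

    Cluster centres sit on a seeded jittered grid: per dimension,
    ``clusters_per_dim`` levels with minimum separation ``8 * cluster_sigma``
    are drawn and assigned to the clusters in a per-dimension random
    permutation, so every axis projection shows ``clusters_per_dim`` modes.

    Returns ``(points, labels)`` with label -1 for noise points and the
    cluster index otherwise; rows are shuffled.
    """
    if d < 1 or clusters_per_dim < 1 or n < 1:
        raise ValidationError("d, n and clusters_per_dim must be positive")
    if not (0.0 <= noise_fraction <= 1.0):
        raise ValidationError("noise_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = clusters_per_dim
    margin = 2.0 * cluster_sigma
    if k > 1:
        spacing = (1.0 - 2.0 * margin) / (k - 1)
        if spacing < 8.0 * cluster_sigma:
            raise ValidationError(
                f"cannot place {k} clusters with separation "
                f">= {8 * cluster_sigma} on the unit interval")
        jitter = (spacing - 8.0 * cluster_sigma) / 2.0
    else:
        spacing, jitter = 0.0, 0.25

    centers = np.empty((k, d))
    for dim in range(d):
        base = margin + spacing * np.arange(k) if k > 1 else np.array([0.5])
        levels = base + rng.uniform(-jitter, jitter, size=k)
        centers[:, dim] = levels[rng.permutation(k)]

    n_noise = int(round(noise_fraction * n))
    n_clustered = n - n_noise
    counts = np.full(k, n_clustered // k)
    counts[: n_clustered % k] += 1

    pts, labels = [], []
    for c in range(k):
        pts.append(centers[c] + cluster_sigma * rng.standard_normal((counts[c], d)))
        labels.append(np.full(counts[c], c))
    if n_noise:
        pts.append(rng.uniform(0.0, 1.0, size=(n_noise, d)))
        labels.append(np.full(n_noise, -1))
    points = np.vstack(pts) if pts else np.empty((0, d))
    labels = np.concatenate(labels)
    order = rng.permutation(n)
    return points[order], labels[order]


def gen_pair(kind: str, params: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Two-column synthetic tables with a known generating relation.

    Kinds
    -----
    ``linear``: y = a*x + b + N(0, sigma), x ~ U(x_lo, x_hi).
    ``logarithmic``: y = a*ln(x) + b + N(0, sigma), x ~ U(x_lo, x_hi), x > 0.
    ``independent``: two independent columns, uniform by default
    (``dist="normal"`` for Gaussians; scales via params).
    ``ring``: an annular (radial) cluster — points at distance
    N(radius, radial_sigma) from a centre, uniform direction.
    ``conditional_bimodal``: a continuous ``value`` column whose distribution
    is unimodal under class 0 and a symmetric two-component mixture under
    class 1, plus a discrete ``class`` column.
    """
    p = dict(params or {})
    n = int(p.pop("n", 200))
    rng = np.random.default_rng(seed)
    if kind == "linear":
        a, b = p.pop("a", 2.0), p.pop("b", 1.0)
        sigma = p.pop("sigma", 0.1)
        x = rng.uniform(p.pop("x_lo", 0.0), p.pop("x_hi", 3.0), n)
        y = a * x + b + sigma * rng.standard_normal(n)
    elif kind == "logarithmic":
        a, b = p.pop("a", 2.0), p.pop("b", 1.0)
        sigma = p.pop("sigma", 0.1)
        lo, hi = p.pop("x_lo", 0.1), p.pop("x_hi", 10.0)
        if lo <= 0:
            raise ValidationError("logarithmic kind requires positive abscissa")
        x = rng.uniform(lo, hi, n)
        y = a * np.log(x) + b + sigma * rng.standard_normal(n)
    elif kind == "independent":
        dist = p.pop("dist", "uniform")
        xs, ys = p.pop("x_scale", 1.0), p.pop("y_scale", 1.0)
        if dist == "uniform":
            x = xs * rng.uniform(0.0, 1.0, n)
            y = ys * rng.uniform(0.0, 1.0, n)
        elif dist == "normal":
            x = xs * rng.standard_normal(n)
            y = ys * rng.standard_normal(n)
        else:
            raise ValidationError(f"unknown marginal family {dist!r}")
    elif kind == "ring":
        center = np.asarray(p.pop("center", (0.5, 0.5)), dtype=float)
        radius = p.pop("radius", 0.35)
        rs = p.pop("radial_sigma", 0.03)
        r = radius + rs * rng.standard_normal(n)
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        x = center[0] + r * np.cos(theta)
        y = center[1] + r * np.sin(theta)
    elif kind == "conditional_bimodal":
        frac1 = p.pop("class1_fraction", 0.5)
        s = p.pop("sigma", 0.5)
        mu0 = p.pop("mu_normal", 5.0)
        lo, hi = p.pop("mu_low", 2.0), p.pop("mu_high", 8.0)
        cls = (rng.uniform(size=n) < frac1).astype(int)
        val = np.where(cls == 0, mu0, np.where(rng.uniform(size=n) < 0.5, lo, hi))
        val = val + s * rng.standard_normal(n)
        if p:
            raise ValidationError(f"unknown parameters {sorted(p)}")
        return pd.DataFrame({"value": val,
                             "class": np.where(cls == 1, "substandard", "normal")})
    else:
        raise ValidationError(f"unknown pair kind {kind!r}")
    if p:
        raise ValidationError(f"unknown parameters {sorted(p)}")
    return pd.DataFrame({"x": x, "y": y})


def _split_rects(size: int, n_rects: int, rng) -> list[tuple[int, int, int, int]]:
    min_side = max(4, size // 8)
    rects = [(0, size, 0, size)]
    while len(rects) < n_rects:
        areas = [(r[1] - r[0]) * (r[3] - r[2]) for r in rects]
        i = int(np.argmax(areas))
        r0, r1, c0, c1 = rects.pop(i)
        h, w = r1 - r0, c1 - c0
        horiz = h >= w if h != w else bool(rng.integers(2))
        if horiz and h >= 2 * min_side:
            cut = int(rng.integers(r0 + min_side, r1 - min_side + 1))
            rects += [(r0, cut, c0, c1), (cut, r1, c0, c1)]
        elif not horiz and w >= 2 * min_side:
            cut = int(rng.integers(c0 + min_side, c1 - min_side + 1))
            rects += [(r0, r1, c0, cut), (r0, r1, cut, c1)]
        elif h >= 2 * min_side:
            cut = int(rng.integers(r0 + min_side, r1 - min_side + 1))
            rects += [(r0, cut, c0, c1), (cut, r1, c0, c1)]
        elif w >= 2 * min_side:
            cut = int(rng.integers(c0 + min_side, c1 - min_side + 1))
            rects += [(r0, r1, c0, cut), (r0, r1, cut, c1)]
        else:
            raise ValidationError("image too small for the requested regions")
    return rects


def gen_images(count: int, size: int = 32, n_rects: int = 4,
               gray_step: int = 30, texture_sigmas=(0.0, 4.0),
               noise_sigma: float = 10.0, seed: int = 0
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Piecewise-homogeneous textured toy images with ground-truth partitions.

    Each image is a recursive random rectangular partition into ``n_rects``
    regions.  Regions get distinct gray levels from a palette spaced
    ``gray_step`` apart (so any two regions differ by at least ``gray_step``),
    a per-region texture sigma drawn from ``texture_sigmas``, and global
    Gaussian noise.  Returns ``count`` pairs ``(image, label_map)``; images
    are float arrays in [0, 255], label maps integer arrays.
    """
    if size < 16 or n_rects < 2:
        raise ValidationError("size must be >= 16 and n_rects >= 2")
    palette = np.arange(20, 256 - 5, gray_step, dtype=float)
    if n_rects > palette.size:
        raise ValidationError("too many regions for the gray palette")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        rects = _split_rects(size, n_rects, rng)
        levels = rng.choice(palette, size=n_rects, replace=False)
        tex = rng.choice(np.asarray(texture_sigmas, dtype=float), size=n_rects)
        img = np.zeros((size, size))
        labels = np.zeros((size, size), dtype=np.int32)
        for k, (r0, r1, c0, c1) in enumerate(rects):
            block = levels[k] + tex[k] * rng.standard_normal((r1 - r0, c1 - c0))
            img[r0:r1, c0:c1] = block
            labels[r0:r1, c0:c1] = k
        img += noise_sigma * rng.standard_normal(img.shape)
        out.append((np.clip(img, 0.0, 255.0), labels))
    return out


def gen_nested_image(size: int = 32, inner_fraction: float = 0.4,
                     gray_levels: tuple[float, float] = (60.0, 180.0),
                     noise_sigma: float = 0.0, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """A nested-region image: an inner rectangle fully surrounded by the outer
    region (the arrangement-feature fixture).  Returns (image, label_map) with
    label 0 outside and 1 inside."""
    if size < 16:
        raise ValidationError("size must be >= 16")
    rng = np.random.default_rng(seed)
    side = max(2, int(round(inner_fraction * size)))
    r0 = (size - side) // 2
    img = np.full((size, size), gray_levels[0])
    labels = np.zeros((size, size), dtype=np.int32)
    img[r0: r0 + side, r0: r0 + side] = gray_levels[1]
    labels[r0: r0 + side, r0: r0 + side] = 1
    if noise_sigma > 0:
        img = np.clip(img + noise_sigma * rng.standard_normal(img.shape), 0, 255)
    return img, labels
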