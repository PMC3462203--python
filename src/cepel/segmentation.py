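"""Probabilistic region-merging image segmentation.

Segmentation is phrased as density estimation: for two adjacent regions A and
B the posterior P(merge | features) is estimated with a Naive Bayes
combination of per-feature class-conditional 1-d kernel densities.  The
features (on 8-bit grayscale values) are

- brightness: |mean_A - mean_B|,
- texture:    |var_A - var_B|,
- arrangement: the percentage of the smaller region's boundary pixels lying
  on *outside* borders (touching neither region of the pair); two nested
  regions score 0%,
- size: the pixel counts, used not as a merge feature but to gate the others.

Small regions cannot provide reliable texture or arrangement values, so each
feature carries a reliability curve P(reliable | min region size); a feature
enters the Naive Bayes product only where its posterior reliability is at
least 0.5 (brightness is always used).

The merge loop starts from one region per pixel (4-connectivity), repeatedly
merges the globally most probable adjacent pair, recomputes the posteriors of
the new region against its neighbours, and stops when every remaining pair's
posterior is below 0.5.  The merge history yields a boundary-posterior map
(probability that two regions are *not* merged) and the boundary F-measure
scorer evaluates label maps or posterior maps against a ground truth.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .kde1d import (Density1D, KDEConfig, Sample1D, ValidationError, fit_kde1d)

# class-conditional likelihood ratios need thin, stable tails: adaptive
# (Abramson) bandwidths inflate the sparse-tail density of one class and can
# flip the ratio far from the data, so the merge model uses fixed-bandwidth
# fits throughout
SEG_KDE_CONFIG = KDEConfig(adaptivity_exponent=0.0)

__all__ = [
    "TrainingError",
    "PairFeatures",
    "Region",
    "RegionGraph",
    "ReliabilityCurve",
    "MergeModel",
    "compute_pair_features",
    "train_merge_model",
    "merge_posterior",
    "segment",
    "SegmentationResult",
    "boundary_posterior_map",
    "boundary_f_measure",
]

FEATURES = ("brightness", "texture", "arrangement")
GATED_FEATURES = ("texture", "arrangement")  # brightness is always used
_FLOOR = 1e-12


class TrainingError(RuntimeError):
    """Raised when the training data cannot support the model fit."""


# ---------------------------------------------------------------------------
# Regions and the adjacency graph
# ---------------------------------------------------------------------------


@dataclass
class Region:
    """Pixel statistics kept incrementally: mean and variance of gray values
    are O(1) on merge via the sum / sum-of-squares bookkeeping."""

    id: int
    pixels: np.ndarray          # flat pixel indices
    total: float                # sum of gray values
    total_sq: float             # sum of squared gray values

    @property
    def size(self) -> int:
        return self.pixels.size

    @property
    def mean(self) -> float:
        return self.total / self.size

    @property
    def variance(self) -> float:
        v = self.total_sq / self.size - self.mean ** 2
        return max(v, 0.0)


@dataclass(frozen=True)
class PairFeatures:
    brightness: float
    texture: float
    arrangement: float
    sizes: tuple[int, int]

    def value(self, feature: str) -> float:
        return getattr(self, feature)

    @property
    def min_size(self) -> int:
        return min(self.sizes)


class RegionGraph:
    """Current partition of an image: regions, 4-adjacency, cached posteriors."""

    def __init__(self, image: np.ndarray, labels: np.ndarray):
        image = np.asarray(image, dtype=float)
        labels = np.asarray(labels)
        if image.shape != labels.shape or image.ndim != 2:
            raise ValidationError("image and labels must be equal-shape 2-d")
        self.image = image
        self.shape = image.shape
        self.labels = labels.astype(np.int64).copy()
        flat_img = image.ravel()
        flat_lab = self.labels.ravel()
        self.regions: dict[int, Region] = {}
        order = np.argsort(flat_lab, kind="stable")
        sorted_lab = flat_lab[order]
        starts = np.flatnonzero(np.r_[True, sorted_lab[1:] != sorted_lab[:-1]])
        bounds = np.r_[starts, sorted_lab.size]
        for s, e in zip(bounds[:-1], bounds[1:]):
            idx = order[s:e]
            rid = int(sorted_lab[s])
            vals = flat_img[idx]
            self.regions[rid] = Region(rid, idx.copy(), float(vals.sum()),
                                       float((vals * vals).sum()))
        self.adjacency: dict[int, set[int]] = {r: set() for r in self.regions}
        h, w = self.shape
        right = (self.labels[:, :-1], self.labels[:, 1:])
        down = (self.labels[:-1, :], self.labels[1:, :])
        for a, b in (right, down):
            mask = a != b
            for x, y in zip(a[mask].ravel(), b[mask].ravel()):
                self.adjacency[int(x)].add(int(y))
                self.adjacency[int(y)].add(int(x))
        self.history: list[dict] = []
        self._neighbor_offsets = None

    # -- geometry helpers ---------------------------------------------------

    def _neighbor_labels(self, pixels: np.ndarray) -> np.ndarray:
        """Labels of the 4 neighbours of each pixel; -1 beyond the frame."""
        h, w = self.shape
        r, c = np.divmod(pixels, w)
        flat = self.labels.ravel()
        out = np.full((4, pixels.size), -1, dtype=np.int64)
        up = r > 0
        out[0, up] = flat[pixels[up] - w]
        dn = r < h - 1
        out[1, dn] = flat[pixels[dn] + w]
        lf = c > 0
        out[2, lf] = flat[pixels[lf] - 1]
        rt = c < w - 1
        out[3, rt] = flat[pixels[rt] + 1]
        return out

    def are_adjacent(self, a: int, b: int) -> bool:
        return b in self.adjacency.get(a, ())

    def merge(self, a: int, b: int, posterior: float) -> int:
        """Merge region b into region a (the smaller id survives)."""
        if a > b:
            a, b = b, a
        ra, rb = self.regions[a], self.regions[b]
        ra.pixels = np.concatenate([ra.pixels, rb.pixels])
        ra.total += rb.total
        ra.total_sq += rb.total_sq
        self.labels.ravel()[rb.pixels] = a
        neigh = (self.adjacency[a] | self.adjacency[b]) - {a, b}
        for n in self.adjacency[b]:
            self.adjacency[n].discard(b)
        for n in neigh:
            self.adjacency[n].add(a)
        self.adjacency[a] = neigh
        del self.adjacency[b], self.regions[b]
        self.history.append({"a": a, "b": b, "posterior": float(posterior)})
        return a


def compute_pair_features(graph: RegionGraph, pair) -> PairFeatures:
    """Table-of-features of an adjacent region pair.

    The arrangement percentage is computed over the boundary pixels of the
    smaller region: boundary pixels adjacent to the partner are *shared*,
    all other boundary pixels (including frame contact) are *outside*, and
    arrangement = 100 * outside / (outside + shared).
    """
    a, b = int(pair[0]), int(pair[1])
    if not graph.are_adjacent(a, b):
        raise ValidationError(f"regions {a} and {b} are not adjacent")
    ra, rb = graph.regions[a], graph.regions[b]
    small, other = (ra, rb) if ra.size <= rb.size else (rb, ra)
    neigh = graph._neighbor_labels(small.pixels)
    is_boundary = np.any(neigh != small.id, axis=0)
    touches_other = np.any(neigh == other.id, axis=0)
    shared = int(np.count_nonzero(is_boundary & touches_other))
    outside = int(np.count_nonzero(is_boundary & ~touches_other))
    arrangement = 100.0 * outside / max(outside + shared, 1)
    return PairFeatures(
        brightness=abs(ra.mean - rb.mean),
        texture=abs(ra.variance - rb.variance),
        arrangement=arrangement,
        sizes=(ra.size, rb.size),
    )


# ---------------------------------------------------------------------------
# Merge model: class-conditional densities, prior, reliability gating
# ---------------------------------------------------------------------------


class ReliabilityCurve:
    """Posterior probability that a feature is trustworthy as a function of
    the (minimum) region size, tabulated on a log-size grid."""

    def __init__(self, log_sizes: np.ndarray, posteriors: np.ndarray):
        self.log_sizes = np.asarray(log_sizes, dtype=float)
        self.posteriors = np.clip(np.asarray(posteriors, dtype=float), 0.0, 1.0)

    def __call__(self, size) -> np.ndarray | float:
        s = np.log(np.maximum(np.asarray(size, dtype=float), 1.0))
        out = np.interp(s, self.log_sizes, self.posteriors)
        return float(out) if np.ndim(size) == 0 else out

    @staticmethod
    def constant(value: float) -> "ReliabilityCurve":
        return ReliabilityCurve(np.array([0.0, 20.0]), np.array([value, value]))

    @staticmethod
    def step(threshold_size: float, low: float = 0.0,
             high: float = 1.0) -> "ReliabilityCurve":
        """A curve crossing 0.5 at ``threshold_size`` (handy for tests and
        hand-built models)."""
        t = np.log(max(threshold_size, 1.0))
        eps = 1e-9
        return ReliabilityCurve(
            np.array([0.0, t - eps, t, 20.0]),
            np.array([low, low, high, high]))

    def to_dict(self) -> dict:
        return {"log_sizes": self.log_sizes.tolist(),
                "posteriors": self.posteriors.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "ReliabilityCurve":
        return ReliabilityCurve(np.array(d["log_sizes"]),
                                np.array(d["posteriors"]))


def _density_to_dict(dens: Density1D) -> dict:
    return {"centers": dens.centers.tolist(),
            "weights": dens.weights.tolist(),
            "local_bandwidths": dens.local_bandwidths.tolist(),
            "global_bandwidth": dens.global_bandwidth,
            "support": list(dens.support),
            "loo_log_likelihood": dens.loo_log_likelihood}


def _density_from_dict(d: dict) -> Density1D:
    return Density1D(centers=np.array(d["centers"]),
                     weights=np.array(d["weights"]),
                     local_bandwidths=np.array(d["local_bandwidths"]),
                     global_bandwidth=float(d["global_bandwidth"]),
                     support=tuple(d["support"]),
                     loo_log_likelihood=float(d["loo_log_likelihood"]))


@dataclass
class MergeModel:
    """Per-feature class-conditional densities, the merge prior, and the
    per-feature reliability curves."""

    class_conditionals: dict      # feature -> (merge density, split density)
    prior: float
    reliability: dict             # feature -> ReliabilityCurve
    gate_threshold: float = 0.5
    ratio_cap: float = 100.0      # bound on each feature's likelihood ratio
    meta: dict = field(default_factory=dict)

    def active_features(self, min_size: float) -> list[str]:
        """Features entering the Naive Bayes product for a pair whose smaller
        region has ``min_size`` pixels; brightness always participates."""
        active = ["brightness"]
        for f in GATED_FEATURES:
            if float(self.reliability[f](min_size)) >= self.gate_threshold:
                active.append(f)
        return active

    def to_json(self) -> str:
        return json.dumps({
            "prior": self.prior,
            "gate_threshold": self.gate_threshold,
            "ratio_cap": self.ratio_cap,
            "class_conditionals": {
                f: [_density_to_dict(m), _density_to_dict(s)]
                for f, (m, s) in self.class_conditionals.items()},
            "reliability": {f: c.to_dict() for f, c in self.reliability.items()},
        })

    @staticmethod
    def from_json(text: str) -> "MergeModel":
        d = json.loads(text)
        return MergeModel(
            class_conditionals={
                f: (_density_from_dict(m), _density_from_dict(s))
                for f, (m, s) in d["class_conditionals"].items()},
            prior=float(d["prior"]),
            reliability={f: ReliabilityCurve.from_dict(c)
                         for f, c in d["reliability"].items()},
            gate_threshold=float(d.get("gate_threshold", 0.5)),
            ratio_cap=float(d.get("ratio_cap", 100.0)),
        )


def single_feature_posterior(model: MergeModel, feature: str, value) -> np.ndarray:
    """P(merge | one feature) from its class-conditional pair and the prior."""
    dm, ds = model.class_conditionals[feature]
    lm = np.maximum(dm(value), _FLOOR) * model.prior
    ls = np.maximum(ds(value), _FLOOR) * (1.0 - model.prior)
    return lm / (lm + ls)


def merge_posterior(features: PairFeatures, model: MergeModel) -> float:
    """Naive Bayes merge posterior over the reliable features only.

    A feature is included when its reliability posterior at the pair's
    minimum region size is at least the gate threshold; brightness is always
    included.  Each feature's likelihood ratio is clamped to
    ``[1/ratio_cap, ratio_cap]``: kernel density estimates are unreliable in
    their tails, and without the bound a single feature landing in one
    class's empty tail would veto every other feature with a hard zero.
    """
    active = model.active_features(features.min_size)
    cap = model.ratio_cap
    odds = model.prior / (1.0 - model.prior)
    for f in active:
        dm, ds = model.class_conditionals[f]
        v = features.value(f)
        lr = max(float(dm(v)), _FLOOR) / max(float(ds(v)), _FLOOR)
        odds *= min(max(lr, 1.0 / cap), cap)
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# Training from ground-truth partitions
# ---------------------------------------------------------------------------


def _fragment_segments(labels: np.ndarray, rng) -> np.ndarray:
    """Randomly split every ground-truth segment into connected fragments by
    multi-source breadth-first growth from random seed pixels, producing
    regions of arbitrary size and shape at all scales."""
    h, w = labels.shape
    frag = np.full(labels.size, -1, dtype=np.int64)
    flat = labels.ravel()
    next_id = 0
    for seg in np.unique(flat):
        idx = np.flatnonzero(flat == seg)
        size = idx.size
        # log-uniform target fragment area: small fragments must occur so the
        # reliability curves see unreliable sizes
        target = float(np.exp(rng.uniform(np.log(1.5), np.log(max(size, 2)))))
        n_frag = int(np.clip(round(size / target), 1, size))
        seeds = rng.choice(idx, size=n_frag, replace=False)
        frag[seeds] = next_id + np.arange(n_frag)
        queue = list(rng.permutation(seeds))
        while queue:
            p = queue.pop(0)
            r, c = divmod(int(p), w)
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < h and 0 <= nc < w:
                    q = nr * w + nc
                    if frag[q] == -1 and flat[q] == seg:
                        frag[q] = frag[p]
                        queue.append(q)
        next_id += n_frag
    return frag.reshape(labels.shape)


def _adjacent_pairs(frag: np.ndarray) -> list[tuple[int, int]]:
    pairs = set()
    a, b = frag[:, :-1], frag[:, 1:]
    m = a != b
    pairs.update(zip(np.minimum(a[m], b[m]).tolist(),
                     np.maximum(a[m], b[m]).tolist()))
    a, b = frag[:-1, :], frag[1:, :]
    m = a != b
    pairs.update(zip(np.minimum(a[m], b[m]).tolist(),
                     np.maximum(a[m], b[m]).tolist()))
    return sorted(pairs)


def sample_training_pairs(ground_truth, n_pairs: int, seed: int = 0,
                          rounds: int = 4):
    """Feature vectors and merge labels from random fragment pairs of
    ground-truth partitions.

    Each training image's true segments are fragmented ``rounds`` times with
    fresh seeds; all adjacent fragment pairs are pooled and ``n_pairs`` of
    them sampled.  A pair's label is 1 when both fragments belong to the same
    ground-truth segment.
    """
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for _ in range(rounds):
        for image, gt in ground_truth:
            frag = _fragment_segments(np.asarray(gt), rng)
            graph = RegionGraph(image, frag)
            gt_of = {}
            flat_gt = np.asarray(gt).ravel()
            for rid in graph.regions:
                gt_of[rid] = flat_gt[graph.regions[rid].pixels[0]]
            for a, b in _adjacent_pairs(frag):
                feats.append(compute_pair_features(graph, (a, b)))
                labels.append(int(gt_of[a] == gt_of[b]))
    if len(feats) < n_pairs:
        raise TrainingError(
            f"only {len(feats)} adjacent pairs available, need {n_pairs}")
    pick = rng.choice(len(feats), size=n_pairs, replace=False)
    return [feats[i] for i in pick], np.array([labels[i] for i in pick])


def _fit_conditional(values: np.ndarray, config: KDEConfig) -> Density1D:
    if np.unique(values).size < 2:
        # all identical feature values in a class: represent as a narrow
        # Gaussian at the common value
        jitter = np.array([values[0] - 1e-6, values[0] + 1e-6])
        return fit_kde1d(Sample1D(np.r_[values[:2], jitter]), config)
    return fit_kde1d(Sample1D(values), config)


def train_merge_model(ground_truth, n_pairs: int = 800, seed: int = 0,
                      config: KDEConfig = SEG_KDE_CONFIG) -> MergeModel:
    """Fit the merge model from images with known segmentations.

    Random adjacent fragment pairs are drawn from randomised partitions of
    the ground truth; per feature, class-conditional densities are fitted for
    the merge and split classes, the prior is the empirical merge fraction,
    and the reliability curve of each feature is the class posterior of
    "this feature classifies the pair correctly" as a function of
    log(min region size), via two further 1-d fits and Bayes' theorem.
    """
    if len(ground_truth) < 1:
        raise ValidationError("need at least one training image")
    if n_pairs < 100:
        raise ValidationError("need at least 100 training pairs")
    feats, labels = sample_training_pairs(ground_truth, n_pairs, seed=seed)
    n_merge = int(labels.sum())
    if n_merge < 10 or (labels.size - n_merge) < 10:
        raise TrainingError(
            f"class with too few samples: merge={n_merge}, "
            f"split={labels.size - n_merge}")
    cond = {}
    for f in FEATURES:
        vals = np.array([ft.value(f) for ft in feats])
        cond[f] = (_fit_conditional(vals[labels == 1], config),
                   _fit_conditional(vals[labels == 0], config))
    prior = float(labels.mean())
    model = MergeModel(class_conditionals=cond, prior=prior, reliability={})

    min_sizes = np.array([ft.min_size for ft in feats], dtype=float)
    log_grid = np.linspace(0.0, np.log(max(min_sizes.max(), 2.0)) + 0.5, 64)
    for f in FEATURES:
        vals = np.array([ft.value(f) for ft in feats])
        # informativeness is judged by the likelihood ratio alone (equal
        # priors): with the prior included, a merge-heavy prior would make
        # every single-feature decision "merge" and the curve would track the
        # class mix by size instead of the feature's discriminative power
        dm, ds = model.class_conditionals[f]
        ratio_says_merge = np.maximum(dm(vals), _FLOOR) > np.maximum(ds(vals), _FLOOR)
        informative = (ratio_says_merge.astype(int) == labels)
        p_inf = float(informative.mean())
        ls = np.log(min_sizes)
        if informative.all() or not informative.any() or \
                np.unique(ls[informative]).size < 2 or \
                np.unique(ls[~informative]).size < 2:
            model.reliability[f] = ReliabilityCurve.constant(p_inf)
            continue
        d_inf = fit_kde1d(Sample1D(ls[informative]), config)
        d_not = fit_kde1d(Sample1D(ls[~informative]), config)
        num = np.maximum(d_inf(log_grid), _FLOOR) * p_inf
        den = num + np.maximum(d_not(log_grid), _FLOOR) * (1.0 - p_inf)
        model.reliability[f] = ReliabilityCurve(log_grid, num / den)
    model.meta = {"n_pairs": int(n_pairs), "seed": int(seed),
                  "merge_fraction": prior}
    return model


# ---------------------------------------------------------------------------
# The merge loop
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    labels: np.ndarray            # final label map
    history: list[dict]           # per merge: a, b, posterior
    final_posteriors: dict        # (a, b) -> posterior of surviving pairs
    shape: tuple[int, int]

    @property
    def n_regions(self) -> int:
        return int(np.unique(self.labels).size)


def segment(image, model: MergeModel) -> SegmentationResult:
    """Greedy probabilistic region merging.

    Starts from one region per pixel, always merges the currently most
    probable adjacent pair (ties resolve to the smaller id pair), recomputes
    the posteriors of the merged region against its neighbours, and stops
    when every remaining posterior is below 0.5.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise ValidationError("image must be 2-d and at least 2x2")
    h, w = image.shape
    init = np.arange(h * w, dtype=np.int64).reshape(h, w)
    graph = RegionGraph(image, init)
    version = {r: 0 for r in graph.regions}
    cache: dict[tuple[int, int], float] = {}
    heap: list[tuple] = []

    def push(a: int, b: int):
        if a > b:
            a, b = b, a
        p = merge_posterior(compute_pair_features(graph, (a, b)), model)
        cache[(a, b)] = p
        heapq.heappush(heap, (-p, a, b, version[a], version[b]))

    done = set()
    for a in sorted(graph.adjacency):
        for b in sorted(graph.adjacency[a]):
            if (a, b) not in done and a < b:
                done.add((a, b))
                push(a, b)

    while heap:
        negp, a, b, va, vb = heapq.heappop(heap)
        if version.get(a) != va or version.get(b) != vb:
            continue
        if -negp < 0.5:
            break
        keep = graph.merge(a, b, -negp)
        gone = b if keep == a else a
        version.pop(gone, None)
        version[keep] += 1
        cache = {k: v for k, v in cache.items() if gone not in k and keep not in k}
        for n in sorted(graph.adjacency[keep]):
            push(*((keep, n) if keep < n else (n, keep)))

    final = {k: v for k, v in cache.items()
             if k[0] in graph.regions and k[1] in graph.regions
             and graph.are_adjacent(*k)}
    return SegmentationResult(labels=graph.labels.copy(), history=graph.history,
                              final_posteriors=final, shape=(h, w))


# ---------------------------------------------------------------------------
# Boundary posterior map and F-measure
# ---------------------------------------------------------------------------


def _merge_tree(history, n_pixels: int):
    """Kruskal-style merge forest over initial pixel regions; each internal
    node carries the posterior of the merge that created it."""
    parent = {}
    posterior = {}
    root_of = {i: i for i in range(n_pixels)}
    next_node = n_pixels
    for step in history:
        a, b = step["a"], step["b"]
        ra, rb = root_of[a], root_of[b]
        node = next_node
        next_node += 1
        parent[ra] = node
        parent[rb] = node
        posterior[node] = step["posterior"]
        # merged region keeps id a (the smaller); b disappears
        root_of[a] = node
        root_of.pop(b, None)
    return parent, posterior


def _lca_posterior(u: int, v: int, parent: dict, posterior: dict):
    anc = set()
    x = u
    while True:
        anc.add(x)
        if x not in parent:
            break
        x = parent[x]
    x = v
    while True:
        if x in anc:
            return posterior.get(x)
        if x not in parent:
            return None
        x = parent[x]
    return None


def boundary_posterior_map(result: SegmentationResult,
                           shape: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel boundary posterior in [0, 1].

    Every inter-pixel boundary gets 1 minus the posterior of the merge that
    dissolved it (via the merge forest's lowest common ancestor), or 1 minus
    the final unmerged posterior for boundaries between surviving regions.
    A pixel's value is the maximum over its four inter-pixel boundaries, so
    thresholding at 0.5 reproduces the final region boundaries exactly.
    """
    h, w = shape if shape is not None else result.shape
    parent, posterior = _merge_tree(result.history, h * w)
    labels = result.labels
    out = np.zeros((h, w))

    def boundary_value(p: int, q: int) -> float:
        lp, lq = labels.ravel()[p], labels.ravel()[q]
        if lp == lq:
            post = _lca_posterior(p, q, parent, posterior)
            return 0.0 if post is None else 1.0 - post
        key = (min(lp, lq), max(lp, lq))
        post = result.final_posteriors.get((int(key[0]), int(key[1])))
        if post is None:
            return 1.0
        return 1.0 - post

    for r in range(h):
        for c in range(w):
            p = r * w + c
            best = 0.0
            if c + 1 < w:
                best = max(best, boundary_value(p, p + 1))
            if r + 1 < h:
                best = max(best, boundary_value(p, p + w))
            if c > 0:
                best = max(best, boundary_value(p - 1, p))
            if r > 0:
                best = max(best, boundary_value(p - w, p))
            out[r, c] = best
    return out


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    return find_boundaries(np.asarray(labels), connectivity=1, mode="thick")


def _match_f(pred_mask: np.ndarray, truth_mask: np.ndarray,
             tolerance_px: float) -> float:
    p_idx = np.argwhere(pred_mask)
    t_idx = np.argwhere(truth_mask)
    if p_idx.size == 0 and t_idx.size == 0:
        return 1.0
    if p_idx.size == 0 or t_idx.size == 0:
        return 0.0
    tree = cKDTree(t_idx)
    neighbors = tree.query_ball_point(p_idx, r=tolerance_px + 1e-9)
    rows, cols = [], []
    for i, ns in enumerate(neighbors):
        rows.extend([i] * len(ns))
        cols.extend(ns)
    if not rows:
        return 0.0
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(p_idx), len(t_idx))).tocsr()
    match = maximum_bipartite_matching(graph, perm_type="column")
    m = int(np.count_nonzero(match >= 0))
    precision = m / len(p_idx)
    recall = m / len(t_idx)
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def boundary_f_measure(predicted, truth, tolerance_px: float = 2.0,
                       n_thresholds: int = 21) -> float:
    """Boundary F-measure with tolerance-limited bipartite matching.

    ``predicted`` is either a label map (integer) or a boundary-posterior map
    (floats in [0, 1]); for a posterior map the maximum F over a threshold
    sweep is returned.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValidationError("shape mismatch between prediction and truth")
    truth_mask = _boundary_mask(truth)
    if np.issubdtype(predicted.dtype, np.integer):
        return _match_f(_boundary_mask(predicted), truth_mask, tolerance_px)
    best = 0.0
    for t in np.linspace(0.0, 1.0, n_thresholds)[:-1]:
        best = max(best, _match_f(predicted > t, truth_mask, tolerance_px))
    return best
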