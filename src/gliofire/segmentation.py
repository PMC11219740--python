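"""Multilevel-threshold segmentation optimized by the firefly algorithm.

A candidate solution is a vector of K intensity thresholds on the 8-bit
scale; each brain pixel joins the threshold it is nearest to in absolute
intensity difference.  The resulting intensity clusters are decomposed
into spatially connected segments: an 8-connected component whose area
exceeds ``min_region_fraction`` of the brain area becomes a unique
segment, while the remaining small components of a cluster share one
residual segment so that every brain pixel stays covered.

Segmentation quality is the composite score

    fitness = (D_w + E_y) / (alpha + D_b)

with D_w the mean within-segment absolute deviation from the segment's
mean intensity, D_b the mean over segments of the minimum center-to-
center intensity gap, and E_y the mean Shannon entropy (bits) of the
per-segment 256-bin intensity histograms.  Lower is better: homogeneous,
low-entropy segments with well-separated centers.

The firefly swarm minimizes this score.  A quarter of the initial
population is seeded with 1-D K-Means centers of the brain intensities
(distinct sub-seeds per member); the rest is uniform on [0, 255]^K.
Every threshold vector is kept sorted ascending, which removes the K!
permutation symmetry of the encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .preprocessing import ForegroundResult

__all__ = [
    "FFOConfig",
    "FitnessParts",
    "Segment",
    "SegmentSet",
    "quantize_intensities",
    "assign_clusters",
    "decompose_regions",
    "intra_cluster_distance",
    "inter_cluster_distance",
    "segment_entropy",
    "fitness",
    "kmeans_seed",
    "init_population",
    "firefly_move",
    "optimize_segmentation",
    "segment_image",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class FFOConfig:
    """Firefly-search settings.  Population 150 / 500 iterations / K = 5
    are the full-scale study settings; tests and the worked examples use
    scaled-down swarms."""

    population_size: int = 150
    iterations: int = 500
    K: int = 5
    kmeans_fraction: float = 0.25
    beta0: float = 1.0
    gamma: float = 1.0
    alpha_rand: float = 0.2
    alpha_decay: float = 0.98
    min_region_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.kmeans_fraction <= 1.0:
            raise ValueError("kmeans_fraction must lie in [0, 1]")


@dataclass
class Segment:
    id: int
    intensities: np.ndarray  # uint8 pixel values of the segment
    residual: bool = False

    @property
    def area(self) -> int:
        return int(self.intensities.size)

    @property
    def center(self) -> float:
        return float(self.intensities.mean())


@dataclass
class SegmentSet:
    segments: list[Segment]
    label_image: np.ndarray  # int; 0 outside brain, 1..L segment ids

    @property
    def L(self) -> int:
        return len(self.segments)


@dataclass
class FitnessParts:
    d_w: float
    d_b: float
    e_y: float
    alpha: float
    value: float


def quantize_intensities(fg: ForegroundResult) -> np.ndarray:
    """8-bit quantization of the foreground image (thresholds live on 0..255)."""
    return np.clip(np.rint(fg.fg_image * 255.0), 0, 255).astype(np.int64)


def canonicalize(thresholds: np.ndarray) -> np.ndarray:
    """Sorted-ascending copy clipped to [0, 255]."""
    return np.sort(np.clip(np.asarray(thresholds, dtype=float), 0.0, 255.0))


def assign_clusters(fg: ForegroundResult, thresholds: np.ndarray) -> np.ndarray:
    """Label each brain pixel with its nearest threshold (1..K; 0 = background).

    Ties break toward the lowest threshold index, which also makes
    duplicate thresholds inert.
    """
    if not fg.brain_mask.any():
        raise ValueError("empty brain mask")
    s = canonicalize(thresholds)
    q = quantize_intensities(fg)
    # nearest-threshold assignment for all 256 gray levels at once
    levels = np.arange(256, dtype=float)
    lut = np.argmin(np.abs(levels[:, None] - s[None, :]), axis=1) + 1
    labels = np.zeros(q.shape, dtype=np.int64)
    labels[fg.brain_mask] = lut[q[fg.brain_mask]]
    return labels


def decompose_regions(
    labels: np.ndarray,
    image_q: np.ndarray,
    brain_area: int,
    min_fraction: float = 0.05,
) -> SegmentSet:
    """Split intensity clusters into spatial segments.

    Per cluster, 8-connected components larger than
    ``min_fraction * brain_area`` each become a unique segment; the
    remaining small components of that cluster share one residual
    segment, so coverage of the brain is preserved.
    """
    min_area = min_fraction * brain_area
    seg_label = np.zeros(labels.shape, dtype=np.int64)
    segments: list[Segment] = []
    next_id = 1
    for k in np.unique(labels[labels > 0]):
        cluster = labels == k
        comp, n = ndimage.label(cluster, structure=_EIGHT)
        if n == 0:
            continue
        areas = np.bincount(comp.ravel())[1:]
        big = np.nonzero(areas > min_area)[0] + 1
        small = np.nonzero(areas <= min_area)[0] + 1
        for b in big:
            m = comp == b
            seg_label[m] = next_id
            segments.append(Segment(next_id, image_q[m].astype(np.uint8)))
            next_id += 1
        if small.size:
            m = np.isin(comp, small)
            seg_label[m] = next_id
            segments.append(Segment(next_id, image_q[m].astype(np.uint8), residual=True))
            next_id += 1
    return SegmentSet(segments=segments, label_image=seg_label)


def intra_cluster_distance(cs: SegmentSet) -> float:
    """D_w: mean over segments of the mean |pixel - center| deviation."""
    if cs.L == 0:
        raise ValueError("empty segment set")
    devs = [np.abs(s.intensities.astype(float) - s.center).mean() for s in cs.segments]
    return float(np.mean(devs))


def inter_cluster_distance(cs: SegmentSet) -> float:
    """D_b: mean over segments of the minimum gap to any other center.

    Defined as 0 for a single segment, which (being in the denominator)
    penalizes degenerate single-segment solutions.
    """
    if cs.L == 0:
        raise ValueError("empty segment set")
    if cs.L == 1:
        return 0.0
    centers = np.array([s.center for s in cs.segments])
    diff = np.abs(centers[:, None] - centers[None, :])
    np.fill_diagonal(diff, np.inf)
    return float(diff.min(axis=1).mean())


def segment_entropy(cs: SegmentSet) -> float:
    """E_y: mean Shannon entropy (bits) of per-segment 256-bin histograms."""
    if cs.L == 0:
        raise ValueError("empty segment set")
    ents = []
    for s in cs.segments:
        p = np.bincount(s.intensities, minlength=256) / s.area
        nz = p[p > 0]
        ents.append(float(-(nz * np.log2(nz)).sum()))
    return float(np.mean(ents))


def fitness(
    fg: ForegroundResult,
    thresholds: np.ndarray,
    alpha: float = 1.0,
    min_region_fraction: float = 0.05,
) -> FitnessParts:
    """Composite segmentation score (D_w + E_y) / (alpha + D_b); lower is better."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    labels = assign_clusters(fg, thresholds)
    cs = decompose_regions(labels, quantize_intensities(fg), fg.brain_area, min_region_fraction)
    return _score(cs, alpha)


def _score(cs: SegmentSet, alpha: float) -> FitnessParts:
    d_w = intra_cluster_distance(cs)
    d_b = inter_cluster_distance(cs)
    e_y = segment_entropy(cs)
    return FitnessParts(d_w=d_w, d_b=d_b, e_y=e_y, alpha=alpha, value=(d_w + e_y) / (alpha + d_b))


class _Evaluator:
    """Fitness of a threshold vector, vectorized for the swarm's hot loop.

    Produces values identical to ``fitness`` (assign + decompose + the
    three criteria) but computes all per-segment statistics with a
    single component labeling and bincount reductions.
    """

    def __init__(self, fg: ForegroundResult, alpha: float, min_fraction: float):
        from skimage.measure import label as _sklabel

        self._label = _sklabel
        self.alpha = alpha
        self.min_area = min_fraction * fg.brain_area
        self.q = quantize_intensities(fg)
        self.mask = fg.brain_mask
        self.brain_q = self.q[self.mask].astype(np.float64)

    def __call__(self, thresholds: np.ndarray) -> float:
        s = canonicalize(thresholds)
        levels = np.arange(256, dtype=float)
        lut = np.argmin(np.abs(levels[:, None] - s[None, :]), axis=1) + 1
        labels = np.zeros(self.q.shape, dtype=np.int64)
        labels[self.mask] = lut[self.q[self.mask]]
        # one pass: connected components of equal-valued cluster regions
        comp = self._label(labels, background=0, connectivity=2)
        comp_flat = comp.ravel()
        lab_flat = labels.ravel()
        ncomp = comp_flat.max()
        areas = np.bincount(comp_flat, minlength=ncomp + 1)
        cluster_of = np.zeros(ncomp + 1, dtype=np.int64)
        cluster_of[comp_flat] = lab_flat
        # unique ids for large components; one residual id per cluster
        seg_of = np.zeros(ncomp + 1, dtype=np.int64)
        big = np.nonzero(areas > self.min_area)[0]
        big = big[big > 0]
        nseg = big.size
        seg_of[big] = np.arange(nseg)
        small = np.nonzero((areas > 0) & (areas <= self.min_area))[0]
        small = small[small > 0]
        if small.size:
            res_clusters, res_idx = np.unique(cluster_of[small], return_inverse=True)
            seg_of[small] = nseg + res_idx
            nseg += res_clusters.size
        seg = seg_of[comp[self.mask]]
        q = self.brain_q
        n_i = np.bincount(seg, minlength=nseg).astype(np.float64)
        centers = np.bincount(seg, weights=q, minlength=nseg) / n_i
        d_w = float((np.bincount(seg, weights=np.abs(q - centers[seg]), minlength=nseg) / n_i).mean())
        if nseg == 1:
            d_b = 0.0
        else:
            diff = np.abs(centers[:, None] - centers[None, :])
            np.fill_diagonal(diff, np.inf)
            d_b = float(diff.min(axis=1).mean())
        hist = np.bincount(seg * 256 + self.q[self.mask], minlength=nseg * 256).reshape(nseg, 256)
        p = hist / n_i[:, None]
        logp = np.zeros_like(p)
        np.log2(p, where=p > 0, out=logp)
        e_y = float(-(p * logp).sum(axis=1).mean())
        return (d_w + e_y) / (self.alpha + d_b)


def kmeans_seed(fg: ForegroundResult, K: int, seed: int = 0) -> np.ndarray:
    """Threshold vector from 1-D K-Means centers of the brain intensities.

    Degenerate inputs with fewer than K distinct gray levels return the
    available levels padded with slightly jittered copies, so the result
    is always a valid (sorted, length-K) vector.
    """
    vals = quantize_intensities(fg)[fg.brain_mask].astype(float)
    uniq = np.unique(vals)
    rng = np.random.default_rng(seed)
    if uniq.size < K:
        pad = rng.uniform(-0.5, 0.5, K - uniq.size) + np.resize(uniq, K - uniq.size)
        return canonicalize(np.concatenate([uniq, pad]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(vals.reshape(-1, 1))
    return canonicalize(km.cluster_centers_.ravel())


def init_population(fg: ForegroundResult, cfg: FFOConfig) -> list[np.ndarray]:
    """K-Means-seeded quarter (distinct sub-seeds) plus uniform-random rest."""
    n_seeded = int(np.floor(cfg.population_size * cfg.kmeans_fraction))
    ss = np.random.SeedSequence(cfg.seed)
    sub_seeds = ss.generate_state(max(n_seeded, 1) + 1) % (2**31 - 1)
    pop = [kmeans_seed(fg, cfg.K, int(sub_seeds[i])) for i in range(n_seeded)]
    rng = np.random.default_rng(int(sub_seeds[-1]))
    for _ in range(cfg.population_size - n_seeded):
        pop.append(canonicalize(rng.uniform(0.0, 255.0, cfg.K)))
    return pop


def firefly_move(
    x_i: np.ndarray,
    x_j: np.ndarray,
    f_i: float,
    f_j: float,
    cfg: FFOConfig,
    rng: np.random.Generator,
    alpha_rand: float | None = None,
) -> np.ndarray:
    """Move firefly i toward the brighter (lower-fitness) firefly j.

    Standard attraction rule on coordinates normalized to [0, 1]:
    ``u_i += beta0 * exp(-gamma r^2) (u_j - u_i) + alpha * eps`` with
    eps ~ U(-0.5, 0.5); the result is rescaled, clamped to [0, 255] and
    re-sorted.
    """
    a = cfg.alpha_rand if alpha_rand is None else alpha_rand
    u_i = np.asarray(x_i, dtype=float) / 255.0
    u_j = np.asarray(x_j, dtype=float) / 255.0
    r2 = float(np.sum((u_i - u_j) ** 2))
    beta = cfg.beta0 * np.exp(-cfg.gamma * r2)
    u_new = u_i + beta * (u_j - u_i) + a * rng.uniform(-0.5, 0.5, u_i.size)
    return canonicalize(np.clip(u_new, 0.0, 1.0) * 255.0)


def optimize_segmentation(
    fg: ForegroundResult,
    cfg: FFOConfig,
    alpha: float = 1.0,
) -> tuple[np.ndarray, list[float]]:
    """Elitist firefly search for the threshold vector minimizing the fitness.

    Returns the best vector ever evaluated and the best-so-far fitness
    trace (one entry per iteration, non-increasing).  Deterministic for
    a fixed ``cfg.seed``.
    """
    ev = _Evaluator(fg, alpha, cfg.min_region_fraction)
    pop = init_population(fg, cfg)
    fit = np.array([ev(x) for x in pop])
    best_idx = int(np.argmin(fit))
    best_x, best_f = pop[best_idx].copy(), float(fit[best_idx])
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF1FE]).generate_state(1)[0])
    trace: list[float] = []
    a = cfg.alpha_rand
    for _ in range(cfg.iterations):
        order = np.argsort(fit)  # brightest first; stable tie-break
        for i in range(len(pop)):
            for j in order:
                if fit[j] < fit[i]:
                    pop[i] = firefly_move(pop[i], pop[j], float(fit[i]), float(fit[j]), cfg, rng, a)
        fit = np.array([ev(x) for x in pop])
        it_best = int(np.argmin(fit))
        if fit[it_best] < best_f:
            best_f, best_x = float(fit[it_best]), pop[it_best].copy()
        else:
            # elitism: re-inject the global best over the current worst
            worst = int(np.argmax(fit))
            pop[worst] = best_x.copy()
            fit[worst] = best_f
        a *= cfg.alpha_decay
        trace.append(best_f)
    return best_x, trace


def segment_image(fg: ForegroundResult, cfg: FFOConfig, alpha: float = 1.0) -> SegmentSet:
    """End-to-end segmentation: optimize thresholds, then decompose regions."""
    best, _ = optimize_segmentation(fg, cfg, alpha=alpha)
    labels = assign_clusters(fg, best)
    return decompose_regions(labels, quantize_intensities(fg), fg.brain_area, cfg.min_region_fraction)
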