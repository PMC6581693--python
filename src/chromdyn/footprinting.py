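"""Bivariate transcription-factor footprinting from cut-site profiles.

For each motif, cut-site counts around all genomic occurrences are
aggregated into a library-normalized average profile per condition.  Two
scalar summaries per condition follow:

* flanking accessibility (FA): mean normalized cuts/bp in the window
  flanks, reporting local chromatin opening;
* footprint depth (FPD): ``log2((flank mean + eps) / (interior mean +
  eps))`` — a bound factor protects its motif from transposase insertion,
  deepening the footprint.

Condition contrasts (dFA, dFPD) for all motifs are then classified by a
bagplot — the bivariate box-plot analog built on Tukey halfspace depth:
the bag is the convex hull of the half of the points with greatest depth,
the fence is the bag inflated about the depth median, and points beyond
the fence are the significant movers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval


@dataclass
class CutProfile:
    """Aggregate cut-density profile for one motif in one condition.

    ``per_bp_counts`` has length ``2 * window_halfwidth + motif_width`` and
    is in cuts per occurrence per bp, scaled to a library of 1e7 cuts.
    """

    motif_id: str
    condition: str
    window_halfwidth: int
    motif_width: int
    per_bp_counts: np.ndarray
    n_occurrences: int
    libsize: float
    n_skipped: int = 0

    def __post_init__(self) -> None:
        expected = 2 * self.window_halfwidth + self.motif_width
        if len(self.per_bp_counts) != expected:
            raise ValueError(
                f"profile length {len(self.per_bp_counts)} != 2*{self.window_halfwidth}"
                f" + {self.motif_width}"
            )
        if (np.asarray(self.per_bp_counts) < 0).any():
            raise ValueError("negative cut counts")


@dataclass
class FootprintStat:
    """Per-motif bivariate footprint contrast between two conditions."""

    motif_id: str
    fa_a: float
    fa_b: float
    fpd_a: float
    fpd_b: float
    delta_fa: float
    delta_fpd: float
    classification: str | None = None


def aggregate_cuts(
    occurrences: pd.DataFrame,
    cut_counts: pd.DataFrame,
    condition: str,
    libsize: float,
    motif_width: int,
    window_halfwidth: int,
    restrict_to: list[GenomicInterval] | None = None,
) -> dict[str, CutProfile]:
    """Average cut profiles per motif, strand-aware and library-normalized.

    ``occurrences`` is indexed by occurrence id with columns motif_id,
    chrom, start, end, strand; ``cut_counts`` is occurrence x window
    position.  Minus-strand occurrence rows are reversed before averaging
    so profiles are in motif orientation.  Occurrences missing from the cut
    table are skipped and counted in ``n_skipped``.  With ``restrict_to``,
    only occurrences whose midpoint falls inside one of the given intervals
    (e.g. an atlas subset) contribute.
    """
    length = 2 * window_halfwidth + motif_width
    if cut_counts.shape[1] != length:
        raise ValueError(
            f"cut table has {cut_counts.shape[1]} positions, expected {length}"
        )
    keep_mask = pd.Series(True, index=occurrences.index)
    if restrict_to is not None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in restrict_to:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        mids = (occurrences["start"] + occurrences["end"]) // 2
        for occ_id in occurrences.index:
            spans = by_chrom.get(occurrences.at[occ_id, "chrom"], ())
            mid = mids[occ_id]
            keep_mask[occ_id] = any(s <= mid < e for s, e in spans)

    scale = 1e7 / float(libsize)
    profiles: dict[str, CutProfile] = {}
    for motif_id, grp in occurrences[keep_mask].groupby("motif_id", sort=True):
        present = grp.index.intersection(cut_counts.index)
        n_skipped = len(grp) - len(present)
        if n_skipped:
            warnings.warn(
                f"{motif_id}: {n_skipped} occurrences outside the cut table, skipped"
            )
        if len(present) == 0:
            continue
        block = cut_counts.loc[present].to_numpy(dtype=float)
        minus = (grp.loc[present, "strand"] == "-").to_numpy()
        block[minus] = block[minus, ::-1]
        mean_profile = block.mean(axis=0) * scale
        profiles[str(motif_id)] = CutProfile(
            motif_id=str(motif_id),
            condition=condition,
            window_halfwidth=window_halfwidth,
            motif_width=motif_width,
            per_bp_counts=mean_profile,
            n_occurrences=len(present),
            libsize=float(libsize),
            n_skipped=n_skipped,
        )
    return profiles


def footprint_stats(
    profile_a: CutProfile,
    profile_b: CutProfile,
    flank_margin: int = 10,
    epsilon: float = 0.1,
) -> FootprintStat:
    """FA/FPD per condition and their contrasts for one motif.

    The interior is the central ``motif_width`` bp; flanks are positions
    farther than ``motif_width/2 + flank_margin`` from the window center.
    """
    if (
        profile_a.window_halfwidth != profile_b.window_halfwidth
        or profile_a.motif_width != profile_b.motif_width
    ):
        raise ValueError("profiles have mismatching windows")
    h, w = profile_a.window_halfwidth, profile_a.motif_width
    length = 2 * h + w
    center = (length - 1) / 2.0
    pos = np.arange(length)
    interior = np.zeros(length, dtype=bool)
    interior[h : h + w] = True
    flank = np.abs(pos - center) > (w / 2.0 + flank_margin)
    if not flank.any():
        raise ValueError("window too small: no flank positions beyond the margin")

    def fa_fpd(profile: np.ndarray) -> tuple[float, float]:
        fa = float(profile[flank].mean())
        inner = float(profile[interior].mean())
        fpd = float(np.log2((fa + epsilon) / (inner + epsilon)))
        return fa, fpd

    fa_a, fpd_a = fa_fpd(np.asarray(profile_a.per_bp_counts, dtype=float))
    fa_b, fpd_b = fa_fpd(np.asarray(profile_b.per_bp_counts, dtype=float))
    if fa_a > 0 and fa_b > 0:
        delta_fa = float(np.log2(fa_b / fa_a))
    else:
        delta_fa = float(np.log2((fa_b + epsilon) / (fa_a + epsilon)))
    return FootprintStat(
        motif_id=profile_a.motif_id,
        fa_a=fa_a,
        fa_b=fa_b,
        fpd_a=fpd_a,
        fpd_b=fpd_b,
        delta_fa=delta_fa,
        delta_fpd=fpd_b - fpd_a,
    )


# ---------------------------------------------------------------------------
# Tukey halfspace depth and the bagplot


def tukey_depths(points: np.ndarray, max_exact: int = 2000, seed: int = 0) -> np.ndarray:
    """Halfspace depth of every point within the 2-D point cloud.

    Exact rotational-sweep computation (O(n log n) per point) up to
    ``max_exact`` points; beyond that, the minimum over 1024 random
    projection directions, which upper-bounds the exact depth.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if n > max_exact:
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0, 2 * np.pi, size=1024)
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        proj = pts @ dirs.T  # n x directions
        depths = np.full(n, n, dtype=int)
        for d in range(dirs.shape[0]):
            col = proj[:, d]
            counts = (col[None, :] >= col[:, None]).sum(axis=1)
            depths = np.minimum(depths, counts)
        return depths

    depths = np.empty(n, dtype=int)
    two_pi = 2 * np.pi
    for i in range(n):
        v = pts - pts[i]
        nonzero = (v[:, 0] != 0) | (v[:, 1] != 0)
        th = np.arctan2(v[nonzero, 1], v[nonzero, 0])
        m = th.size
        if m == 0:
            depths[i] = n
            continue
        th = np.sort(th)
        ext = np.concatenate([th, th + two_pi])
        # largest number of direction angles inside an open semicircle
        upper = np.searchsorted(ext, th + np.pi, side="left")
        max_open = int((upper - np.arange(m)).max())
        depths[i] = n - max_open
    return depths


@dataclass
class BagplotResult:
    classification: pd.Series  # {bag, fence, outlier}
    depths: pd.Series
    depth_median: np.ndarray
    bag_polygon: np.ndarray | None
    fence_polygon: np.ndarray | None
    degenerate: bool = False


def _collinear(pts: np.ndarray, tol: float = 1e-12) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[-1] <= tol * max(s[0], 1.0))


def _fallback_1d(points: np.ndarray, index, fence_factor: float) -> BagplotResult:
    labels = np.full(len(points), "bag", dtype=object)
    for axis in range(2):
        x = points[:, axis]
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        in_bag = (x >= q1) & (x <= q3)
        lo = med - fence_factor * max(med - q1, 0)
        hi = med + fence_factor * max(q3 - med, 0)
        out = (x < lo) | (x > hi)
        labels[~in_bag & (labels == "bag")] = "fence"
        labels[out] = "outlier"
    depth = tukey_depths(points) if len(points) else np.array([], dtype=int)
    return BagplotResult(
        classification=pd.Series(labels, index=index, name="classification"),
        depths=pd.Series(depth, index=index, name="depth"),
        depth_median=np.median(points, axis=0),
        bag_polygon=None,
        fence_polygon=None,
        degenerate=True,
    )


def bagplot_classify(
    points: pd.DataFrame | np.ndarray,
    fence_factor: float = 3.0,
) -> BagplotResult:
    """Classify (dFA, dFPD) points as bag, fence or outlier.

    The bag is the convex hull of the ceil(n/2) deepest points by Tukey
    halfspace depth; the fence scales the bag by ``fence_factor`` about the
    depth median (the centroid of the deepest points).  Collinear inputs
    fall back to 1-D quartile fences on each axis, flagged ``degenerate``.
    """
    if isinstance(points, pd.DataFrame):
        index = points.index
        pts = points.to_numpy(dtype=float)[:, :2]
    else:
        pts = np.asarray(points, dtype=float)
        index = pd.RangeIndex(len(pts))
    n = len(pts)
    if n < 10:
        raise ValueError("bagplot needs at least 10 points")

    if np.allclose(pts, pts[0]):
        return BagplotResult(
            classification=pd.Series(["bag"] * n, index=index, name="classification"),
            depths=pd.Series(np.full(n, n), index=index, name="depth"),
            depth_median=pts[0].copy(),
            bag_polygon=None,
            fence_polygon=None,
            degenerate=True,
        )
    if _collinear(pts):
        return _fallback_1d(pts, index, fence_factor)

    depths = tukey_depths(pts)
    deepest = depths == depths.max()
    depth_median = pts[deepest].mean(axis=0)

    k = int(np.ceil(n / 2))
    order = np.lexsort((np.arange(n), -depths))  # depth desc, stable
    bag_idx = order[:k]
    bag_pts = pts[bag_idx]

    from scipy.spatial import QhullError, ConvexHull

    try:
        hull = ConvexHull(bag_pts)
    except QhullError:
        return _fallback_1d(pts, index, fence_factor)
    bag_poly = bag_pts[hull.vertices]
    fence_poly = depth_median + fence_factor * (bag_poly - depth_median)

    from shapely.geometry import Point, Polygon

    bag_shape = Polygon(bag_poly)
    fence_shape = Polygon(fence_poly)
    labels = []
    for p in pts:
        point = Point(p)
        if bag_shape.covers(point):
            labels.append("bag")
        elif fence_shape.covers(point):
            labels.append("fence")
        else:
            labels.append("outlier")
    return BagplotResult(
        classification=pd.Series(labels, index=index, name="classification"),
        depths=pd.Series(depths, index=index, name="depth"),
        depth_median=depth_median,
        bag_polygon=bag_poly,
        fence_polygon=fence_poly,
    )


def footprint_table(
    profiles_a: dict[str, CutProfile],
    profiles_b: dict[str, CutProfile],
    flank_margin: int = 10,
    epsilon: float = 0.1,
    fence_factor: float = 3.0,
) -> tuple[pd.DataFrame, BagplotResult]:
    """Footprint contrasts for all shared motifs plus bagplot classification."""
    motifs = sorted(set(profiles_a) & set(profiles_b))
    stats = [
        footprint_stats(
            profiles_a[m], profiles_b[m], flank_margin=flank_margin, epsilon=epsilon
        )
        for m in motifs
    ]
    table = pd.DataFrame(
        {
            "fa_a": [s.fa_a for s in stats],
            "fa_b": [s.fa_b for s in stats],
            "fpd_a": [s.fpd_a for s in stats],
            "fpd_b": [s.fpd_b for s in stats],
            "delta_fa": [s.delta_fa for s in stats],
            "delta_fpd": [s.delta_fpd for s in stats],
        },
        index=pd.Index(motifs, name="motif_id"),
    )
    bag = bagplot_classify(table[["delta_fa", "delta_fpd"]], fence_factor=fence_factor)
    table["classification"] = bag.classification
    return table, bag
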