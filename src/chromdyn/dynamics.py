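"""Temporal dynamics of count features: normalization, differential tests,
fuzzy c-means profile clustering and per-cluster motif enrichment.

The differential-accessibility test is a negative-binomial exact test with
a single method-of-moments dispersion shared across features (floored at
1e-4).  This is a documented approximation to the full empirical-Bayes
machinery of dedicated count-model packages: with merged replicates there
is one library per condition, so feature-wise dispersion estimation is not
identifiable, and a robust common dispersion captures the overdispersion
that matters for the pairwise filters downstream.

Fuzzy c-means is the classic Bezdek alternating-update algorithm with a
fuzzifier exponent ``m`` and multiple random restarts; clustering always
operates on explicitly z-scored temporal profiles, so every centroid lives
in z-profile space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CountTable, GenomicInterval


@dataclass
class NormalizedMatrix:
    """Counts-per-million and log2 CPM, library sizes from the full table."""

    cpm: pd.DataFrame
    log_cpm: pd.DataFrame
    pseudocount: float


def cpm_normalize(counts: CountTable, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Library-size scale each column to counts per million."""
    libsizes = counts.library_sizes.astype(float)
    if (libsizes <= 0).any():
        bad = libsizes.index[libsizes <= 0][0]
        raise ValueError(f"zero library size in column {bad!r}")
    cpm = counts.counts.astype(float) / libsizes * 1e6
    log_cpm = np.log2(cpm + pseudocount)
    return NormalizedMatrix(cpm=cpm, log_cpm=log_cpm, pseudocount=pseudocount)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    cummin = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(cummin, 1.0)
    return out


def nb_exact_test(ya: int, yb: int, dispersion: float) -> float:
    """Two-sided NB exact test of equal means given library-adjusted counts.

    Conditions on the sum ``s = ya + yb``: under the null both counts are
    NB with the same mean (taken as s/2) and the given dispersion, and the
    p-value is the total conditional probability of all splits of ``s`` no
    more likely than the observed one.
    """
    s = int(ya) + int(yb)
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    mu = s / 2.0
    if dispersion < 1e-12:
        logp = stats.poisson.logpmf(k, mu) + stats.poisson.logpmf(s - k, mu)
    else:
        size = 1.0 / dispersion
        prob = size / (size + mu)
        logp = stats.nbinom.logpmf(k, size, prob) + stats.nbinom.logpmf(s - k, size, prob)
    weights = np.exp(logp - logp.max())
    observed = weights[int(ya)]
    p = weights[weights <= observed * (1 + 1e-12)].sum() / weights.sum()
    return float(min(p, 1.0))


_CHI2_1_MEDIAN = 0.45493642311957174  # median of the chi-square(1) law


def moment_dispersion(ya: np.ndarray, yb: np.ndarray, floor: float = 1e-4) -> float:
    """Robust method-of-moments common dispersion from two count vectors.

    Per feature, (ya - yb)^2 / 2 estimates the NB variance m + phi*m^2 and
    is approximately chi-square(1)-scaled around it, so phi is chosen to
    make the median of the standardized squared differences equal the
    chi-square(1) median.  The median resists the truly differential
    minority of features.
    """
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    m = (ya + yb) / 2.0
    ok = m > 0
    if not ok.any():
        return floor
    half_sq = (ya[ok] - yb[ok]) ** 2 / 2.0
    m = m[ok]

    def median_ratio(phi: float) -> float:
        return float(np.median(half_sq / (m + phi * m**2)))

    lo, hi = floor, 10.0
    if median_ratio(lo) <= _CHI2_1_MEDIAN:
        return floor
    if median_ratio(hi) >= _CHI2_1_MEDIAN:
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if median_ratio(mid) > _CHI2_1_MEDIAN:
            lo = mid
        else:
            hi = mid
    return float(max(0.5 * (lo + hi), floor))


def differential_features(
    counts: CountTable,
    groups: dict[str, str] | None = None,
    min_cpm: float = 4.0,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Pairwise NB exact tests with CPM, fold and BH-q filters.

    ``groups`` maps sample columns to condition names; replicate columns of
    a condition are summed (merged-library convention).  A feature passes
    when its maximum CPM over conditions reaches ``min_cpm`` and at least
    one condition pair shows fold >= ``min_fold`` together with BH q <
    ``alpha`` for that same pair.

    ``dispersion`` overrides the moment estimate with a known common NB
    dispersion; the estimate assumes most features are non-differential,
    so supply the platform's dispersion when that assumption fails.

    Returns a frame indexed by feature with max_pairwise_fold, p, q,
    passes, direction and the best pair.
    """
    df = counts.counts
    if groups:
        merged = {}
        for col, cond in groups.items():
            merged.setdefault(cond, []).append(col)
        df = pd.DataFrame({cond: df[cols].sum(axis=1) for cond, cols in merged.items()})
    conditions = list(df.columns)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")

    libsizes = df.sum(axis=0).astype(float)
    if (libsizes <= 0).any():
        raise ValueError("a condition has zero total counts")
    cpm = df.astype(float) / libsizes * 1e6
    max_cpm = cpm.max(axis=1)

    n = df.shape[0]
    best_p = np.ones(n)
    best_q = np.ones(n)
    best_fold = np.ones(n)
    best_pair = np.array([""] * n, dtype=object)
    direction = np.array([""] * n, dtype=object)
    passes_pairwise = np.zeros(n, dtype=bool)

    mean_lib = float(libsizes.mean())
    for i in range(len(conditions)):
        for j in range(i + 1, len(conditions)):
            a, b = conditions[i], conditions[j]
            ya = np.rint(df[a].to_numpy() * mean_lib / libsizes[a]).astype(np.int64)
            yb = np.rint(df[b].to_numpy() * mean_lib / libsizes[b]).astype(np.int64)
            phi = moment_dispersion(ya, yb) if dispersion is None else max(dispersion, 1e-4)
            p = np.array([nb_exact_test(x, y, phi) for x, y in zip(ya, yb)])
            q = bh_adjust(p)
            fold_ab = (cpm[b] + pseudocount) / (cpm[a] + pseudocount)
            fold = np.maximum(fold_ab, 1.0 / fold_ab).to_numpy()
            pair_pass = (fold >= min_fold) & (q < alpha)
            passes_pairwise |= pair_pass

            better = p < best_p
            best_p[better] = p[better]
            best_q[better] = q[better]
            best_fold[better] = fold[better]
            best_pair[better] = f"{a}:{b}"
            direction[better] = np.where(fold_ab[better] >= 1, "up", "down")

    max_fold = np.ones(n)
    for i in range(len(conditions)):
        for j in range(len(conditions)):
            if i == j:
                continue
            f = (
                (cpm[conditions[j]] + pseudocount) / (cpm[conditions[i]] + pseudocount)
            ).to_numpy()
            max_fold = np.maximum(max_fold, f)

    passes = (max_cpm.to_numpy() >= min_cpm) & passes_pairwise
    return pd.DataFrame(
        {
            "max_cpm": max_cpm.to_numpy(),
            "max_pairwise_fold": max_fold,
            "p": best_p,
            "q": best_q,
            "best_pair": best_pair,
            "direction": direction,
            "passes": passes,
        },
        index=df.index,
    )


def differential_expression(
    counts: CountTable,
    pairs: list[tuple[str, str]],
    min_fold: float = 1.2,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Paired differential expression with a consistent-direction rescue rule.

    Per gene, the per-pair log2 CPM difference (treated minus control)
    feeds a paired t-test.  A gene is differential when |mean fold| >
    ``min_fold`` (strict) and p < ``alpha``; genes failing the p cut are
    rescued when every replicate pair changes in the same strict direction
    and the mean fold still clears ``min_fold``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 replicate pairs")
    for c, t in pairs:
        if c not in counts.counts.columns or t not in counts.counts.columns:
            raise ValueError(f"pair ({c}, {t}) references unknown columns")
    norm = cpm_normalize(counts, pseudocount=pseudocount)
    diffs = np.stack(
        [(norm.log_cpm[t] - norm.log_cpm[c]).to_numpy() for c, t in pairs], axis=1
    )  # genes x pairs
    mean_log2 = diffs.mean(axis=1)
    with np.errstate(invalid="ignore"):
        tstat, p = stats.ttest_1samp(diffs, 0.0, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    fold = 2.0 ** np.abs(mean_log2)
    primary = (fold > min_fold) & (p < alpha)
    same_sign = (diffs > 0).all(axis=1) | (diffs < 0).all(axis=1)
    rescue = ~primary & same_sign & (fold > min_fold)
    return pd.DataFrame(
        {
            "mean_log2_fold": mean_log2,
            "fold": fold,
            "p": p,
            "de": primary | rescue,
            "rescue": rescue,
            "direction": np.where(mean_log2 > 0, "up", "down"),
        },
        index=counts.counts.index,
    )


def zscore_profiles(
    norm: NormalizedMatrix | pd.DataFrame, condition_order: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature z-score of the condition-mean log profile.

    Population standard deviation; constant profiles map to the zero
    vector rather than NaN.
    """
    df = norm.log_cpm if isinstance(norm, NormalizedMatrix) else norm
    if condition_order is not None:
        df = df[condition_order]
    if df.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=df.index, columns=df.columns)


@dataclass
class ProfileClustering:
    """Fuzzy membership matrix with centroids and hard/merged labels."""

    membership: pd.DataFrame  # features x clusters
    centroids: pd.DataFrame  # clusters x conditions
    fuzzifier: float
    objective: float
    hard_label: pd.Series
    merged_label: pd.Series | None = None
    merge_map: dict[int, int] | None = None


def _fcm_single(
    x: np.ndarray, c: int, m: float, tol: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    n = x.shape[0]
    centroids = x[rng.choice(n, size=c, replace=False)].astype(float)
    u = np.full((n, c), 1.0 / c)
    power = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 0.0)
        zero = d2 <= 1e-300
        u_new = np.zeros_like(u)
        any_zero = zero.any(axis=1)
        if any_zero.any():
            rows = np.where(any_zero)[0]
            for r in rows:
                cols = np.where(zero[r])[0]
                u_new[r, cols[0]] = 1.0
        nz = ~any_zero
        if nz.any():
            ratio = d2[nz] ** (power / 2.0)
            inv = 1.0 / ratio
            u_new[nz] = inv / inv.sum(axis=1, keepdims=True)
        change = np.abs(u_new - u).max()
        u = u_new
        um = u**m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        if change < tol:
            break
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    objective = float((u**m * d2).sum())
    return u, centroids, objective


def fuzzy_cmeans(
    z_profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    n_init: int = 5,
) -> ProfileClustering:
    """Fuzzy c-means on z-scored profiles, best objective of ``n_init`` restarts."""
    if c < 2:
        raise ValueError("c must be >= 2")
    x = z_profiles.to_numpy(dtype=float)
    if x.shape[0] <= c:
        raise ValueError("need more profiles than clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_init):
        u, centroids, objective = _fcm_single(x, c, m, tol, max_iter, rng)
        if best is None or objective < best[2]:
            best = (u, centroids, objective)
    u, centroids, objective = best  # type: ignore[misc]
    membership = pd.DataFrame(u, index=z_profiles.index, columns=range(c))
    hard = pd.Series(
        np.argmax(u, axis=1), index=z_profiles.index, name="hard_label"
    )
    return ProfileClustering(
        membership=membership,
        centroids=pd.DataFrame(centroids, columns=z_profiles.columns),
        fuzzifier=m,
        objective=objective,
        hard_label=hard,
    )


def merge_clusters(
    clustering: ProfileClustering,
    target_K: int = 4,
    mapping: dict[int, int] | None = None,
) -> ProfileClustering:
    """Collapse fine fuzzy clusters into ``target_K`` groups.

    With an explicit ``mapping`` (cluster -> group) it is applied verbatim;
    otherwise clusters agglomerate by average linkage on one minus the
    Pearson correlation of their centroids.  This automates the manual
    inspection step of merging many fine temporal clusters into a few
    broad patterns.
    """
    c = clustering.centroids.shape[0]
    if mapping is not None:
        missing = set(range(c)) - set(mapping)
        if missing:
            raise ValueError(f"mapping does not cover clusters {sorted(missing)}")
        merge_map = dict(mapping)
    else:
        if target_K > c:
            raise ValueError("target_K exceeds number of clusters")
        if target_K == c:
            merge_map = {k: k for k in range(c)}
        else:
            from scipy.cluster.hierarchy import fcluster, linkage
            from scipy.spatial.distance import pdist

            cent = clustering.centroids.to_numpy(dtype=float)
            # correlation distance is undefined for constant centroids;
            # jitter-free guard: treat constant rows as zero-correlation
            dist = pdist(cent, metric="correlation")
            dist = np.nan_to_num(dist, nan=1.0)
            tree = linkage(dist, method="average")
            flat = fcluster(tree, t=target_K, criterion="maxclust")
            merge_map = {k: int(flat[k]) - 1 for k in range(c)}
    merged = clustering.hard_label.map(merge_map).rename("merged_label")
    return ProfileClustering(
        membership=clustering.membership,
        centroids=clustering.centroids,
        fuzzifier=clustering.fuzzifier,
        objective=clustering.objective,
        hard_label=clustering.hard_label,
        merged_label=merged,
        merge_map=merge_map,
    )


NEG_LOG10_CAP = 320.0


def _peaks_with_occurrence(
    peaks: list[GenomicInterval], occurrences: list[GenomicInterval]
) -> int:
    from collections import defaultdict

    occ_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[GenomicInterval]] = defaultdict(list)
    for occ in occurrences:
        grouped[occ.chrom].append(occ)
    for chrom, ivs in grouped.items():
        occ_by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    k = 0
    for peak in peaks:
        pair = occ_by_chrom.get(peak.chrom)
        if pair is None:
            continue
        starts, ends = pair
        if ((starts < peak.end) & (ends > peak.start)).any():
            k += 1
    return k


def cluster_motif_enrichment(
    cluster_peaksets: dict[object, list[GenomicInterval]],
    motif_occurrences: dict[str, list[GenomicInterval]],
    background_peaks: list[GenomicInterval],
    z_normalize: bool = True,
) -> pd.DataFrame:
    """Binomial motif enrichment per cluster, z-normalized per motif.

    For each motif and cluster, k peaks of the cluster contain at least one
    occurrence; the background rate is the fraction of background peaks
    containing one, and p = P(X >= k | n, rate).  The returned matrix holds
    -log10 p (capped at 320 to absorb underflow) z-normalized across
    clusters within each motif row; empty clusters yield NaN columns.
    """
    if not background_peaks:
        raise ValueError("background peak set is empty")
    clusters = list(cluster_peaksets)
    neg_log10 = pd.DataFrame(index=list(motif_occurrences), columns=clusters, dtype=float)
    for motif, occs in motif_occurrences.items():
        bg_k = _peaks_with_occurrence(background_peaks, occs)
        rate = bg_k / len(background_peaks)
        for cl in clusters:
            peaks = cluster_peaksets[cl]
            if not peaks:
                neg_log10.loc[motif, cl] = np.nan
                continue
            k = _peaks_with_occurrence(peaks, occs)
            p = stats.binom.sf(k - 1, len(peaks), rate) if rate > 0 else (0.0 if k else 1.0)
            p = max(float(p), 10.0**-NEG_LOG10_CAP)
            neg_log10.loc[motif, cl] = min(-np.log10(p), NEG_LOG10_CAP)
    if not z_normalize:
        return neg_log10.astype(float)
    values = neg_log10.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)
    z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    z = np.where(np.isnan(values), np.nan, z)
    return pd.DataFrame(z, index=neg_log10.index, columns=clusters)
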