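"""Consolidation of peak sets into a union atlas and peak-to-gene assignment.

The operations mirror the standard ATAC-seq post-processing chain: keep
peaks reproducible between replicates (reciprocal >= 50% overlap), merge
condition peak sets whose summits lie within a distance threshold, label
each atlas peak as promoter / intragenic / intergenic, and assign every
peak to its nearest TSS.

Conventions, fixed once for the whole package:

* reciprocal overlap uses ``>= min_frac`` of *both* interval lengths;
* merging is single-linkage on summit-to-summit distance (midpoint when no
  summit is recorded) with a strict ``< max_gap`` rule; the merged peak
  stores the rounded mean of its member anchors as its summit, which makes
  the operation idempotent;
* promoter precedence over intragenic over intergenic, with the promoter
  window expressed in TSS-oriented coordinates;
* nearest-gene distance is measured peak-center to TSS, signed positive
  downstream in gene orientation, ties broken by lexicographic gene id.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CountTable, GeneModel, GenomicInterval


@dataclass
class PeakAtlas:
    """A consolidated peak set with genomic context annotation."""

    peaks: list[GenomicInterval]
    partition: pd.Series  # peak name -> {promoter, intragenic, intergenic}
    nearest_gene: pd.DataFrame  # peak name -> gene_id, distance
    counts: CountTable | None = None
    provenance: list[tuple[str, ...]] | None = None


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append(iv)
    return out


def concordant_peaks(
    rep1: Sequence[GenomicInterval],
    rep2: Sequence[GenomicInterval],
    min_frac: float = 0.5,
) -> list[GenomicInterval]:
    """Peaks of ``rep1`` with a reciprocal-overlap partner in ``rep2``.

    A partner must overlap by at least ``min_frac`` of the length of *both*
    peaks.  Returns the retained rep1 peaks in their original order.
    """
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    rep2_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in _by_chrom(rep2).items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        rep2_by_chrom[chrom] = (starts, ends)

    kept = []
    for iv in rep1:
        pair = rep2_by_chrom.get(iv.chrom)
        if pair is None:
            continue
        starts, ends = pair
        overlap = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        lengths2 = ends - starts
        ok = (overlap >= min_frac * iv.width) & (overlap >= min_frac * lengths2)
        if ok.any():
            kept.append(iv)
    return kept


def merge_union(
    condition_peaksets: Sequence[Sequence[GenomicInterval]],
    max_gap: int = 100,
    condition_names: Sequence[str] | None = None,
) -> tuple[list[GenomicInterval], list[tuple[str, ...]]]:
    """Single-linkage merge of peaks whose anchors lie closer than ``max_gap``.

    Peaks from all input sets are pooled; chains of peaks with consecutive
    anchor (summit, else midpoint) distances strictly below ``max_gap``
    collapse into one interval spanning the extremes.  The merged summit is
    the rounded mean of the member anchors, so cluster summits stay at
    least ``max_gap`` apart and re-merging the result is a no-op.

    Returns the merged intervals (sorted by chrom, start) and, parallel to
    them, the tuple of source condition names contributing to each.
    """
    if not condition_peaksets:
        raise ValueError("need at least one peak set")
    if condition_names is None:
        condition_names = [f"set{i}" for i in range(len(condition_peaksets))]

    tagged: list[tuple[GenomicInterval, str]] = []
    for name, peakset in zip(condition_names, condition_peaksets):
        tagged.extend((iv, name) for iv in peakset)

    merged: list[GenomicInterval] = []
    provenance: list[tuple[str, ...]] = []
    by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = defaultdict(list)
    for iv, src in tagged:
        by_chrom[iv.chrom].append((iv, src))

    idx = 0
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].anchor, t[0].start))
        cluster: list[tuple[GenomicInterval, str]] = []

        def _flush() -> None:
            nonlocal idx
            if not cluster:
                return
            ivs = [t[0] for t in cluster]
            start = min(iv.start for iv in ivs)
            end = max(iv.end for iv in ivs)
            summit = int(round(float(np.mean([iv.anchor for iv in ivs])))) - start
            summit = min(max(summit, 0), end - start - 1)
            merged.append(
                GenomicInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=f"merged{idx:06d}",
                    summit_offset=summit,
                )
            )
            provenance.append(tuple(sorted({t[1] for t in cluster})))
            idx += 1

        prev_anchor: int | None = None
        for item in items:
            anchor = item[0].anchor
            if prev_anchor is not None and anchor - prev_anchor < max_gap:
                cluster.append(item)
            else:
                _flush()
                cluster = [item]
            prev_anchor = anchor
        _flush()
    return merged, provenance


def partition_atlas(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (2000, 500),
) -> pd.Series:
    """Label each peak promoter / intragenic / intergenic by its center.

    A peak is a promoter peak when its center falls within
    ``[TSS - upstream, TSS + downstream)`` in TSS-oriented coordinates of
    any gene; otherwise intragenic when the center lies inside any gene
    body; otherwise intergenic.
    """
    if not genes:
        raise ValueError("gene list is empty")
    upstream, downstream = promoter_window
    genes_by_chrom = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chrom].append(g)

    labels = []
    names = []
    for i, peak in enumerate(peaks):
        center = peak.midpoint
        label = "intergenic"
        for g in genes_by_chrom.get(peak.chrom, ()):
            oriented = center - g.tss if g.strand == "+" else g.tss - center
            if -upstream <= oriented < downstream:
                label = "promoter"
                break
        if label != "promoter":
            for g in genes_by_chrom.get(peak.chrom, ()):
                if g.body_start <= center < g.body_end:
                    label = "intragenic"
                    break
        labels.append(label)
        names.append(peak.name if peak.name is not None else f"peak{i}")
    return pd.Series(labels, index=names, name="partition")


def assign_nearest_gene(
    peaks: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Nearest TSS per peak center with signed, orientation-aware distance.

    The sign is positive downstream of the TSS in gene orientation and
    negative upstream.  Equidistant ties go to the lexicographically
    smaller gene id.  Peaks on chromosomes without genes get gene_id None
    and NaN distance.
    """
    if not genes:
        raise ValueError("gene list is empty")
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    arrays = {}
    for chrom, gl in by_chrom.items():
        gl_sorted = sorted(gl, key=lambda g: g.gene_id)
        arrays[chrom] = (
            np.array([g.tss for g in gl_sorted]),
            np.array([1 if g.strand == "+" else -1 for g in gl_sorted]),
            [g.gene_id for g in gl_sorted],
        )

    rows = []
    for i, peak in enumerate(peaks):
        name = peak.name if peak.name is not None else f"peak{i}"
        entry = arrays.get(peak.chrom)
        if entry is None:
            rows.append({"peak_id": name, "gene_id": None, "distance": np.nan})
            continue
        tss, orient, ids = entry
        center = peak.midpoint
        dist = np.abs(center - tss)
        best = int(np.argmin(dist))  # argmin takes first = smallest gene_id on ties
        signed = int((center - tss[best]) * orient[best])
        rows.append({"peak_id": name, "gene_id": ids[best], "distance": signed})
    return pd.DataFrame(rows).set_index("peak_id")


def intersect_with_atlas(
    query_peaks: Sequence[GenomicInterval],
    atlas_peaks: Sequence[GenomicInterval],
    max_gap: int = 250,
) -> list[GenomicInterval]:
    """Query peaks whose summit lies within ``max_gap`` bp of an atlas summit."""
    anchors: dict[str, np.ndarray] = {}
    for chrom, ivs in _by_chrom(atlas_peaks).items():
        anchors[chrom] = np.sort(np.array([iv.anchor for iv in ivs]))
    kept = []
    for iv in query_peaks:
        arr = anchors.get(iv.chrom)
        if arr is None or arr.size == 0:
            continue
        pos = iv.anchor
        j = np.searchsorted(arr, pos)
        near = min(
            abs(pos - arr[j - 1]) if j > 0 else np.inf,
            abs(arr[j] - pos) if j < arr.size else np.inf,
        )
        if near <= max_gap:
            kept.append(iv)
    return kept


def build_atlas(
    condition_peaksets: Sequence[Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    counts: CountTable | None = None,
    max_gap: int = 100,
    promoter_window: tuple[int, int] = (2000, 500),
    condition_names: Sequence[str] | None = None,
) -> PeakAtlas:
    """Merge condition peak sets and annotate the union atlas."""
    merged, provenance = merge_union(
        condition_peaksets, max_gap=max_gap, condition_names=condition_names
    )
    partition = partition_atlas(merged, genes, promoter_window=promoter_window)
    nearest = assign_nearest_gene(merged, genes)
    return PeakAtlas(
        peaks=merged,
        partition=partition,
        nearest_gene=nearest,
        counts=counts,
        provenance=provenance,
    )
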