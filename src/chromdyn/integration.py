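"""Cross-assay statistics: accessibility-by-expression cluster concordance,
direct-target calling, and stage-marker overlap proportions.

The concordance procedure asks, for an accessibility cluster Ai, an
expression cluster Rj and a TSS distance bin of half-width b: of the K
genes whose TSS lies within +-b of any Ai peak center, how many fall in
Rj?  The exact upper-tail hypergeometric over the annotated gene universe
replaces the randomized "expected set" estimate that the same quantity is
usually simulated with; a resampling variant is kept behind a flag for
fidelity checks.  Each bin is its own K-set (cumulative half-widths), and
p-values are reported as -log10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GeneModel, GenomicInterval

DEFAULT_BINS_KB = (10, 25, 50, 75, 100, 150, 200, 250)


def genes_near_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    half_width: int,
) -> set[str]:
    """Gene ids whose TSS lies within +-half_width of any peak center."""
    centers: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.midpoint)
    for chrom, c in by_chrom.items():
        centers[chrom] = np.sort(np.asarray(c))
    hits = set()
    for g in genes:
        arr = centers.get(g.chrom)
        if arr is None:
            continue
        j = np.searchsorted(arr, g.tss)
        near = min(
            g.tss - arr[j - 1] if j > 0 else np.inf,
            arr[j] - g.tss if j < arr.size else np.inf,
        )
        if near <= half_width:
            hits.add(g.gene_id)
    return hits


def hypergeom_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n); one-sided enrichment."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def distance_binned_enrichment(
    atac_clusters: Mapping[object, Sequence[GenomicInterval]],
    rna_clusters: Mapping[object, Sequence[str]],
    genes: Sequence[GeneModel],
    bins_kb: Sequence[float] = DEFAULT_BINS_KB,
    universe: Sequence[str] | None = None,
    method: str = "exact",
    n_resamples: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric concordance grid over clusters and TSS distance bins.

    Returns one row per (atac_cluster, rna_cluster, bin) with columns
    observed, N, K, n, p, neg_log10_p.  Bins are half-widths in kb, each
    evaluated independently (a gene can count in several bins).  With
    ``method="randomized"``, p is estimated by drawing ``n_resamples``
    random gene sets of size n from the universe — the quantity the exact
    tail computes in closed form.
    """
    if universe is None:
        universe = [g.gene_id for g in genes]
    universe_set = set(universe)
    N = len(universe_set)
    for rj, members in rna_clusters.items():
        missing = sorted(set(members) - universe_set)
        if missing:
            raise ValueError(
                f"expression cluster {rj!r} has genes outside the universe: "
                f"{missing[:10]}"
            )
    rng = np.random.default_rng(seed)
    universe_list = sorted(universe_set)

    rows = []
    for ai, peaks in atac_clusters.items():
        for b_kb in bins_kb:
            half = int(b_kb * 1000)
            kset = genes_near_peaks(peaks, genes, half) & universe_set
            K = len(kset)
            for rj, members in rna_clusters.items():
                member_set = set(members)
                n = len(member_set)
                x = len(kset & member_set)
                if method == "exact":
                    p = hypergeom_tail(x, N, K, n)
                elif method == "randomized":
                    draws = np.array(
                        [
                            len(kset.intersection(rng.choice(universe_list, n, replace=False)))
                            for _ in range(n_resamples)
                        ]
                    )
                    p = float((1 + (draws >= x).sum()) / (1 + n_resamples))
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append(
                    {
                        "atac_cluster": ai,
                        "rna_cluster": rj,
                        "bin_kb": b_kb,
                        "observed": x,
                        "N": N,
                        "K": K,
                        "n": n,
                        "p": p,
                        "neg_log10_p": -np.log10(max(p, 1e-320)),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class DirectTargetSummary:
    n_direct: int
    n_activated: int
    n_repressed: int
    percent_activated: int  # rounded to nearest integer percent


def call_direct_targets(
    bound_genes: Sequence[str],
    de_results: pd.DataFrame,
) -> tuple[pd.DataFrame, DirectTargetSummary]:
    """Bound-and-differential genes with activated/repressed classification.

    ``de_results`` is the knockdown differential-expression table (index
    gene, columns ``de`` and ``direction`` with "down"/"up" meaning change
    in the knockdown).  A direct target down in the knockdown is classified
    activated — depleting the factor lowers the genes it activates — and
    conversely for repressed.
    """
    bound = set(bound_genes)
    de = de_results[de_results["de"]]
    direct = sorted(bound & set(de.index))
    records = []
    for g in direct:
        direction = de.loc[g, "direction"]
        records.append(
            {
                "gene_id": g,
                "de_direction": "down_in_kd" if direction == "down" else "up_in_kd",
                "class": "activated" if direction == "down" else "repressed",
            }
        )
    table = (
        pd.DataFrame(records).set_index("gene_id")
        if records
        else pd.DataFrame(columns=["de_direction", "class"])
    )
    n_act = int((table["class"] == "activated").sum()) if len(table) else 0
    n_rep = len(table) - n_act
    percent = int(round(100.0 * n_act / len(table))) if len(table) else 0
    return table, DirectTargetSummary(
        n_direct=len(table),
        n_activated=n_act,
        n_repressed=n_rep,
        percent_activated=percent,
    )


def summarize_direct_targets(n_direct: int, n_activated: int) -> DirectTargetSummary:
    """Summary arithmetic from pre-tabulated direct-target counts."""
    if not 0 <= n_activated <= n_direct:
        raise ValueError("activated count must lie within the direct-target count")
    percent = int(round(100.0 * n_activated / n_direct)) if n_direct else 0
    return DirectTargetSummary(
        n_direct=n_direct,
        n_activated=n_activated,
        n_repressed=n_direct - n_activated,
        percent_activated=percent,
    )


def stage_marker_overlap(
    regulon: Sequence[str],
    stage_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-stage regulated proportion and the regulon's composition by stage.

    ``proportion_of_stage`` is |regulon ∩ stage| / |stage| (NaN for empty
    stage sets); ``share_of_regulon`` distributes the regulon members found
    in any stage set across stages.
    """
    reg = set(regulon)
    overlaps = {name: len(reg & set(members)) for name, members in stage_sets.items()}
    staged_total = sum(overlaps.values())
    rows = []
    for name, members in stage_sets.items():
        size = len(set(members))
        rows.append(
            {
                "stage": name,
                "stage_size": size,
                "overlap": overlaps[name],
                "proportion_of_stage": overlaps[name] / size if size else np.nan,
                "share_of_regulon": overlaps[name] / staged_total if staged_total else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("stage")
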