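"""Single-cell RNA-seq quality control, normalization and co-expression
statistics.

The processing order is fixed: QC on raw counts (median absolute deviation
fences on library size and detected genes), the low-expression gene filter
on QC-passing cells, then size factors and CPM on the filtered matrix.
Size factors are the actual library sizes centered to unit mean over
QC-passing cells.

Co-expression works on the binary detection matrix (count > 0): per-cell
set scores are z-transformed over the pooled cell population; gene-gene
similarity uses JSI = 1 - JD^2 (JD the Jaccard distance of detection
vectors) or the Matthews correlation coefficient of the 2x2 detection
table.  Regulon activity is the area under the rank-recovery curve within
the top fraction of each cell's gene ranking, so it depends only on
within-cell ranks.

Z-scores throughout use the population standard deviation (divide by n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CountTable

MAD_NORMAL_SCALE = 1.4826


@dataclass
class CellMatrix:
    """Cells x genes counts with QC flags and derived layers."""

    counts: pd.DataFrame
    condition: pd.Series
    qc_pass: pd.Series | None = None
    size_factor: pd.Series | None = None
    cpm: pd.DataFrame | None = None
    pseudotime: pd.Series | None = None

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts > 0).astype(np.int8)


def _mad(x: np.ndarray, scale: bool) -> float:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return float(mad * (MAD_NORMAL_SCALE if scale else 1.0))


def qc_cells(
    counts: pd.DataFrame, n_mads: float = 3.0, mad_scale: bool = True
) -> pd.Series:
    """MAD-fence cell QC on library size and detected-gene count.

    A cell fails when its library size drops below ``median - n_mads*MAD``,
    its detected genes drop below the analogous fence, or its library size
    exceeds ``median + n_mads*MAD`` (doublet-like).  All fences are strict
    inequalities, so a dataset of identical cells (MAD = 0) passes intact.
    """
    if counts.shape[0] < 10:
        raise ValueError("need at least 10 cells for MAD-based QC")
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    genes = (counts > 0).sum(axis=1).to_numpy(dtype=float)
    lib_med, lib_mad = np.median(lib), _mad(lib, mad_scale)
    gene_med, gene_mad = np.median(genes), _mad(genes, mad_scale)
    fail = (
        (lib < lib_med - n_mads * lib_mad)
        | (genes < gene_med - n_mads * gene_mad)
        | (lib > lib_med + n_mads * lib_mad)
    )
    return pd.Series(~fail, index=counts.index, name="qc_pass")


def filter_genes(
    counts: pd.DataFrame, qc_pass: pd.Series | None = None, min_mean: float = 0.05
) -> pd.Index:
    """Genes whose mean raw count over QC-passing cells reaches ``min_mean``."""
    sub = counts if qc_pass is None else counts.loc[qc_pass[qc_pass].index]
    means = sub.mean(axis=0)
    return counts.columns[means.to_numpy() >= min_mean]


def normalize_cells(
    counts: pd.DataFrame, qc_pass: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors (library size centered to unit mean) and CPM.

    Returns (size_factor, cpm) for the QC-passing cells only.
    """
    sub = counts if qc_pass is None else counts.loc[qc_pass[qc_pass].index]
    lib = sub.sum(axis=1).astype(float)
    if (lib <= 0).any():
        raise ValueError("cell with zero library size after filtering")
    sf = lib / lib.mean()
    effective = sf * lib.mean()
    cpm = sub.div(effective, axis=0) * 1e6
    return sf.rename("size_factor"), cpm


def hvg_select(
    cpm: pd.DataFrame,
    fdr: float = 0.05,
    span: float = 0.3,
) -> tuple[pd.Index, pd.DataFrame]:
    """Highly variable genes by mean-variance trend decomposition.

    On log2(CPM + 1), the technical trend is a running median of variance
    against mean smoothed by lowess; the biological component is total
    minus trend.  P-values come from the scaled chi-square law
    ``var * (n - 1) / trend(mean) ~ chi2(n - 1)`` (upper tail), BH-adjusted;
    selected genes need biological variance > 0 and q < ``fdr``.
    """
    if cpm.shape[1] < 50:
        raise ValueError("need at least 50 genes to fit a mean-variance trend")
    y = np.log2(cpm.to_numpy(dtype=float) + 1.0)
    n = y.shape[0]
    mean = y.mean(axis=0)
    total = y.var(axis=0, ddof=1)

    order = np.argsort(mean, kind="stable")
    window = max(31, int(span * len(mean)) | 1)
    half = window // 2
    sorted_var = total[order]
    running = np.empty_like(sorted_var)
    for i in range(len(sorted_var)):
        lo, hi = max(0, i - half), min(len(sorted_var), i + half + 1)
        running[i] = np.median(sorted_var[lo:hi])

    from statsmodels.nonparametric.smoothers_lowess import lowess

    smoothed = lowess(
        running, mean[order], frac=span, it=0, return_sorted=False
    )
    trend = np.empty_like(total)
    trend[order] = np.maximum(smoothed, 1e-8)

    biological = total - trend
    p = stats.chi2.sf(total * (n - 1) / trend, df=n - 1)
    from .dynamics import bh_adjust

    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean": mean,
            "total": total,
            "technical": trend,
            "biological": biological,
            "p": p,
            "q": q,
        },
        index=cpm.columns,
    )
    selected = cpm.columns[(biological > 0) & (q < fdr)]
    return selected, table


def coexpression_score(
    binary: pd.DataFrame,
    gene_set: list[str],
    condition: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-cell z-scored count of detected set genes.

    The z-transform pools all cells (population sd).  When ``condition`` is
    given, a per-condition summary with equal condition weights (mean and
    median of z per condition) is returned alongside; the pooled z-scores
    themselves are never re-weighted.
    """
    present = [g for g in gene_set if g in binary.columns]
    s = (
        binary[present].sum(axis=1).astype(float)
        if present
        else pd.Series(0.0, index=binary.index)
    )
    sd = float(s.std(ddof=0))
    if sd == 0:
        if len(gene_set) > 0:
            warnings.warn("co-expression scores are constant; z set to 0")
        z = pd.Series(0.0, index=binary.index, name="z")
    else:
        z = ((s - s.mean()) / sd).rename("z")
    summary = None
    if condition is not None:
        summary = (
            pd.DataFrame({"z": z, "condition": condition})
            .groupby("condition", observed=True)["z"]
            .agg(["mean", "median", "count"])
        )
    return z, summary


@dataclass
class CoexpressionMatrix:
    statistic: str  # "JSI" or "MCC"
    values: pd.DataFrame
    order: list[str] = field(default_factory=list)
    flagged: list[tuple[str, str]] = field(default_factory=list)


def _reference_order_cluster(matrix: pd.DataFrame) -> list[str]:
    """Average-linkage (Euclidean) leaf order of the similarity matrix rows."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    values = np.nan_to_num(matrix.to_numpy(dtype=float), nan=0.0)
    if len(matrix) < 3:
        return list(matrix.index)
    tree = linkage(values, method="average", metric="euclidean")
    return [matrix.index[i] for i in leaves_list(tree)]


def jsi_matrix(
    binary: pd.DataFrame,
    gene_list: list[str],
    reference_order: list[str] | None = None,
) -> CoexpressionMatrix:
    """Pairwise JSI = 1 - JD^2 of gene detection vectors.

    An empty union (neither gene ever detected together with the other)
    defines JD = 1, hence JSI = 0, and the pair is flagged.  Row order
    comes from hierarchical clustering unless a reference order (from the
    reference condition) is supplied, in which case it is reused as a pure
    permutation.
    """
    b = binary[gene_list].to_numpy(dtype=np.int64)
    inter = b.T @ b
    n_det = b.sum(axis=0)
    union = n_det[:, None] + n_det[None, :] - inter
    flagged = []
    with np.errstate(divide="ignore", invalid="ignore"):
        jd = np.where(union > 0, 1.0 - inter / np.where(union > 0, union, 1), 1.0)
    for i in range(len(gene_list)):
        for j in range(i, len(gene_list)):
            if union[i, j] == 0:
                flagged.append((gene_list[i], gene_list[j]))
    jsi = 1.0 - jd**2
    df = pd.DataFrame(jsi, index=gene_list, columns=gene_list)
    order = reference_order if reference_order is not None else _reference_order_cluster(df)
    df = df.loc[order, order]
    return CoexpressionMatrix(statistic="JSI", values=df, order=list(order), flagged=flagged)


def mcc_matrix(
    binary: pd.DataFrame,
    gene_list: list[str],
    reference_order: list[str] | None = None,
) -> CoexpressionMatrix:
    """Pairwise Matthews correlation of detection vectors.

    A zero margin in the 2x2 detection table (a gene detected in all or no
    cells) defines MCC = 0 for affected pairs, flagged.  Reference ordering
    is by the first principal component of the matrix unless supplied.
    """
    b = binary[gene_list].to_numpy(dtype=np.float64)
    n = b.shape[0]
    a11 = b.T @ b
    pos = b.sum(axis=0)
    a10 = pos[:, None] - a11
    a01 = pos[None, :] - a11
    a00 = n - a11 - a10 - a01
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(
            (a11 + a10) * (a11 + a01) * (a00 + a10) * (a00 + a01)
        )
        mcc = np.where(denom > 0, (a11 * a00 - a10 * a01) / np.where(denom > 0, denom, 1), 0.0)
    flagged = []
    zero_margin = (pos == 0) | (pos == n)
    for i, gi in enumerate(gene_list):
        if zero_margin[i]:
            flagged.append((gi, "*"))
    np.fill_diagonal(mcc, np.where(zero_margin, 0.0, 1.0))
    df = pd.DataFrame(mcc, index=gene_list, columns=gene_list)
    if reference_order is None:
        from sklearn.decomposition import PCA

        if len(gene_list) >= 2:
            scores = PCA(n_components=1, random_state=0).fit_transform(df.to_numpy())
            order = [g for _, g in sorted(zip(scores[:, 0], gene_list))]
        else:
            order = list(gene_list)
    else:
        order = list(reference_order)
    df = df.loc[order, order]
    return CoexpressionMatrix(statistic="MCC", values=df, order=order, flagged=flagged)


def regulon_auc(
    cpm: pd.DataFrame,
    regulon: list[str],
    top_fraction: float = 0.05,
    seed: int | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-cell regulon activity as area under the rank-recovery curve.

    Genes are ranked per cell by descending expression (ties broken by one
    seeded global shuffle); the recovery curve counts regulon genes within
    the top k for k = 1..ceil(top_fraction * G), and the AUC is normalized
    by its maximum possible value.  Cells are marked active when AUC
    exceeds the threshold — Otsu's method on the AUC histogram by default,
    or a manual override.
    """
    genes = list(cpm.columns)
    members = np.isin(genes, list(regulon))
    if not members.any():
        raise ValueError("regulon has no genes in the expression matrix")
    G = len(genes)
    K = int(np.ceil(top_fraction * G))
    if K < 1:
        raise ValueError("top_fraction too small for the gene universe")
    R = int(members.sum())

    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(G)
    x = cpm.to_numpy(dtype=float)
    n_cells = x.shape[0]
    aucs = np.empty(n_cells)
    max_auc = float(np.minimum(np.arange(1, K + 1), R).sum())
    for i in range(n_cells):
        order = np.lexsort((tiebreak, -x[i]))
        hits = members[order[:K]]
        curve = np.cumsum(hits)
        aucs[i] = curve.sum() / max_auc

    if threshold is None:
        if np.allclose(aucs, aucs[0]):
            threshold = float(aucs[0])
        else:
            from skimage.filters import threshold_otsu

            threshold = float(threshold_otsu(aucs))
    active = aucs > threshold
    return pd.DataFrame(
        {"auc": aucs, "active": active, "threshold": threshold}, index=cpm.index
    )


def pseudotime_rank(
    cpm: pd.DataFrame,
    hvgs: list[str],
    condition: pd.Series | None = None,
    condition_order: list[str] | None = None,
) -> pd.Series:
    """Rank-style pseudotime: min-max rescaled first principal component.

    Computed on z-scored log2(CPM + 1) over the HVGs; the sign is oriented
    so that correlation with the condition order (when given) is positive.
    This is deliberately simple plumbing, not a graph-based trajectory
    method: it assumes an approximately 1-D expression gradient.
    """
    if len(hvgs) < 2:
        raise ValueError("need at least 2 HVGs")
    y = np.log2(cpm[list(hvgs)].to_numpy(dtype=float) + 1.0)
    sd = y.std(axis=0)
    if (sd == 0).all():
        raise ValueError("degenerate expression: no variance across cells")
    keep = sd > 0
    z = (y[:, keep] - y[:, keep].mean(axis=0)) / sd[keep]
    from sklearn.decomposition import PCA

    pc1 = PCA(n_components=1, svd_solver="full").fit_transform(z)[:, 0]
    if pc1.max() == pc1.min():
        raise ValueError("degenerate first principal component")
    t = (pc1 - pc1.min()) / (pc1.max() - pc1.min())
    if condition is not None:
        if condition_order is None:
            if isinstance(condition.dtype, pd.CategoricalDtype):
                condition_order = list(condition.cat.categories)
            else:
                # appearance order of the experiment's time points
                condition_order = list(pd.unique(condition))
        codes = pd.Categorical(
            condition, categories=condition_order, ordered=True
        ).codes
        r = np.corrcoef(t, codes)[0, 1]
        if r < 0:
            t = 1.0 - t
    return pd.Series(t, index=cpm.index, name="pseudotime")


def regulon_trajectory(
    binary: pd.DataFrame,
    regulon: list[str],
    pseudotime: pd.Series,
    driver: str | pd.Series,
) -> pd.DataFrame:
    """Per-cell detected regulon fraction along pseudotime, split by driver.

    ``driver`` is a gene name (stratified by its detection) or a boolean
    per-cell series.  Empty strata yield empty sub-frames, not errors.
    """
    present = [g for g in regulon if g in binary.columns]
    frac = binary[present].mean(axis=1).astype(float) if present else pd.Series(
        0.0, index=binary.index
    )
    sd = float(frac.std(ddof=0))
    z = (frac - frac.mean()) / sd if sd > 0 else frac * 0.0
    if isinstance(driver, str):
        stratum = binary[driver] > 0
    else:
        stratum = driver.astype(bool).reindex(binary.index)
    return pd.DataFrame(
        {
            "pseudotime": pseudotime.reindex(binary.index),
            "fraction": frac,
            "z": z,
            "driver_positive": stratum,
        }
    )


def pseudobulk(
    counts: pd.DataFrame,
    condition: pd.Series,
    qc_pass: pd.Series | None = None,
) -> CountTable:
    """Sum counts over QC-passing cells per condition (genes x conditions)."""
    sub = counts if qc_pass is None else counts.loc[qc_pass[qc_pass].index]
    cond = condition.reindex(sub.index)
    levels = list(pd.unique(condition.dropna()))
    agg = {}
    for level in levels:
        cells = cond[cond == level].index
        if len(cells) == 0:
            raise ValueError(f"condition {level!r} has no QC-passing cells")
        agg[level] = sub.loc[cells].sum(axis=0)
    return CountTable(pd.DataFrame(agg))
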