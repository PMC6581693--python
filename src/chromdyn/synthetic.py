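"""Seeded synthetic datasets with the statistical structure each stage assumes.

The generators emulate a three-condition stem-cell differentiation time
course (naive ESC, day-1 and day-2 epiblast-like cells): region count
matrices with four planted temporal archetypes, transposase cut profiles
with planted motif footprints, paired knockdown-versus-control bulk
expression with planted direct-target effects, and negative-binomial
single-cell counts with planted QC outliers, regulons and a 1-D
differentiation trajectory.

Every generator is a pure function of its :class:`SimulationConfig`; calling
it twice with the same config yields identical output.  Counts are negative
binomial parameterized by mean ``mu`` and dispersion ``phi`` with variance
``mu + phi * mu**2``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import CountTable, GeneModel, GenomicInterval

ARCHETYPES = ("up_up", "down_down", "transient_up", "transient_down")

#: per-archetype log2 multiplier applied at condition t = 0, 1, 2, ...
_ARCHETYPE_PATTERNS = {
    "up_up": lambda t: t,
    "down_down": lambda t: -t,
    "transient_up": lambda t: 1.0 if t == 1 else 0.0,
    "transient_down": lambda t: -1.0 if t == 1 else 0.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a toy genome (2 chromosomes x 10 Mb, 400 genes,
    2,000 peaks, 3 conditions, 300 cells per condition) on which every
    stage of the pipeline runs in seconds.
    """

    seed: int = 0
    # genome / gene universe
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 400
    n_regulons: int = 2
    regulon_size: int = 40
    dynamic_gene_fraction: float = 0.25
    # expression dynamics are mostly monotone along differentiation;
    # transient programs are the minority
    gene_archetype_fractions: tuple[float, float, float, float] = (
        0.4,
        0.4,
        0.1,
        0.1,
    )
    # accessibility
    n_peaks: int = 2000
    n_conditions: int = 3
    condition_names: tuple[str, ...] = ("esc", "d1", "d2")
    archetype_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    effect_fold: float = 2.5
    peak_width: int = 300
    peak_gene_max_dist: int = 15_000
    peak_archetype_concordance: float = 0.8
    baseline_log_mean: float = math.log(200.0)
    baseline_log_sd: float = 0.8
    nb_dispersion: float = 0.02
    # cut profiles / footprinting
    n_motifs: int = 60
    n_footprint_motifs: int = 10
    motif_width: int = 10
    window_halfwidth: int = 50
    occurrences_per_motif: int = 1000
    cuts_per_bp: float = 2.0
    footprint_depletion: float = 0.25
    footprint_fa_gain: float = 1.5
    footprint_motifs: tuple[tuple[int, tuple[float, ...]], ...] | None = None
    # bounded per-(motif, condition) systematic bias, drawn uniformly on a
    # disk of this log2 radius in (cut rate, interior/flank ratio) space;
    # emulates the composition biases that dominate motif-to-motif scatter
    # at genome-scan aggregation depth
    motif_log2_wobble: float = 0.07
    # single cells
    n_cells_per_condition: int = 300
    outlier_cell_fraction: float = 0.05
    sc_mean_count: float = 10.0
    sc_dispersion: float = 0.3
    sc_lowly_expressed_fraction: float = 0.05
    regulon_basal: float = 0.02
    regulon_activation: float = 0.3
    # knockdown bulk RNA
    n_replicate_pairs: int = 3
    knockdown_fold: float = 2.0
    bulk_log_mean: float = math.log(5000.0)
    bulk_log_sd: float = 1.0
    bulk_pair_dispersion: float = 0.002
    n_bound_null_genes: int = 50

    def __post_init__(self) -> None:
        if abs(sum(self.archetype_fractions) - 1.0) > 1e-9:
            raise ValueError("archetype_fractions must sum to 1")
        if self.nb_dispersion < 0 or self.sc_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_conditions != len(self.condition_names):
            raise ValueError("condition_names must match n_conditions")
        if self.window_halfwidth * 2 < self.motif_width + 20:
            raise ValueError("cut window must cover motif width + 20 bp")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per generator."""
    key = zlib.crc32(stream.encode()) % (2**31)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial draws with variance mean + dispersion * mean^2.

    A dispersion of zero (or effectively zero) degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    out[positive] = rng.negative_binomial(size, p[positive])
    return out


# ---------------------------------------------------------------------------
# gene universe


def simulate_gene_universe(config: SimulationConfig) -> pd.DataFrame:
    """Gene models plus the latent truth shared across assays.

    Columns: chrom, start, end, strand, archetype (temporal pattern or
    ``flat``), regulon (index or -1), regulon_direction, is_driver.
    The first gene of each regulon is its driver transcription factor.
    """
    rng = _rng(config, "genes")
    n = config.n_genes
    chroms = np.array(
        [f"chr{i + 1}" for i in rng.integers(0, config.n_chroms, size=n)]
    )
    starts = rng.integers(10_000, config.chrom_length - 110_000, size=n)
    lengths = rng.integers(2_000, 100_000, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    archetype = np.full(n, "flat", dtype=object)
    n_dynamic = int(round(config.dynamic_gene_fraction * n))
    dynamic_idx = rng.choice(n, size=n_dynamic, replace=False)
    counts = _fraction_counts(config.gene_archetype_fractions, n_dynamic)
    labels = np.repeat(ARCHETYPES, counts)
    archetype[dynamic_idx] = rng.permutation(labels)

    regulon = np.full(n, -1, dtype=int)
    direction = np.full(n, "none", dtype=object)
    is_driver = np.zeros(n, dtype=bool)
    free = rng.permutation(n)
    pos = 0
    for r in range(config.n_regulons):
        members = free[pos : pos + config.regulon_size]
        pos += config.regulon_size
        regulon[members] = r
        direction[members] = "activated" if r % 2 == 0 else "repressed"
        is_driver[members[0]] = True
        # regulon expression is driven by its TF, not an independent
        # temporal program
        archetype[members] = "flat"

    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "archetype": archetype,
            "regulon": regulon,
            "regulon_direction": direction,
            "is_driver": is_driver,
        },
        index=pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id"),
    )


def gene_models_from_universe(universe: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(
            gene_id=str(gid),
            chrom=row["chrom"],
            strand=row["strand"],
            body_start=int(row["start"]),
            body_end=int(row["end"]),
        )
        for gid, row in universe.iterrows()
    ]


def _fraction_counts(fractions: Sequence[float], total: int) -> list[int]:
    counts = [int(math.floor(f * total)) for f in fractions]
    i = 0
    while sum(counts) < total:
        counts[i % len(counts)] += 1
        i += 1
    return counts


# ---------------------------------------------------------------------------
# accessibility


def archetype_means(
    archetype: str, baseline: float, effect_fold: float, n_conditions: int
) -> np.ndarray:
    """Expected counts per condition for one region."""
    pattern = _ARCHETYPE_PATTERNS.get(archetype, lambda t: 0.0)
    log2fc = np.array([pattern(t) for t in range(n_conditions)], dtype=float)
    return baseline * effect_fold**log2fc


def simulate_accessibility(
    config: SimulationConfig, universe: pd.DataFrame | None = None
) -> tuple[list[GenomicInterval], CountTable, pd.Series, pd.DataFrame]:
    """Peak intervals, per-condition NB counts and true archetype labels.

    Each peak is placed near the TSS of a gene from the universe and
    inherits that gene's temporal archetype with probability
    ``peak_archetype_concordance`` (flat genes contribute background
    peaks), so that accessibility clusters and expression clusters planted
    by :func:`simulate_single_cells` genuinely co-vary.

    Returns (intervals, counts, labels, universe).
    """
    if universe is None:
        universe = simulate_gene_universe(config)
    rng = _rng(config, "accessibility")
    n = config.n_peaks
    gene_pick = rng.integers(0, len(universe), size=n)
    offsets = rng.integers(-config.peak_gene_max_dist, config.peak_gene_max_dist, size=n)

    tss = np.where(
        universe["strand"].to_numpy() == "+",
        universe["start"].to_numpy(),
        universe["end"].to_numpy() - 1,
    )
    centers = np.clip(
        tss[gene_pick] + offsets, config.peak_width, config.chrom_length - config.peak_width
    )
    chroms = universe["chrom"].to_numpy()[gene_pick]

    gene_arch = universe["archetype"].to_numpy()[gene_pick]
    concordant = rng.random(n) < config.peak_archetype_concordance
    random_arch = np.array(ARCHETYPES, dtype=object)[rng.integers(0, 4, size=n)]
    labels = np.where(
        concordant & (gene_arch != "flat"), gene_arch, random_arch
    ).astype(object)

    baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    )
    means = np.stack(
        [
            archetype_means(a, b, config.effect_fold, config.n_conditions)
            for a, b in zip(labels, baselines)
        ]
    )
    counts = nb_sample(rng, means, config.nb_dispersion)

    half = config.peak_width // 2
    intervals = [
        GenomicInterval(
            chrom=chroms[i],
            start=int(centers[i] - half),
            end=int(centers[i] + half),
            name=f"peak{i:05d}",
            summit_offset=half,
        )
        for i in range(n)
    ]
    ids = [iv.name for iv in intervals]
    table = CountTable(
        pd.DataFrame(counts, index=ids, columns=list(config.condition_names))
    )
    truth = pd.Series(labels, index=ids, name="archetype")
    return intervals, table, truth, universe


# ---------------------------------------------------------------------------
# cut profiles


@dataclass
class CutProfileSim:
    """Per-occurrence cut counts for every motif and condition."""

    occurrences: pd.DataFrame  # occurrence_id -> motif_id, chrom, start, end, strand
    cut_counts: dict[str, pd.DataFrame]  # condition -> occurrence_id x position
    libsizes: dict[str, float]
    truth: pd.DataFrame  # motif_id -> planted, depletion, fa_gain
    window_halfwidth: int
    motif_width: int


def simulate_cut_profiles(config: SimulationConfig) -> CutProfileSim:
    """Multinomial cut-site counts around motif occurrences.

    Planted motifs carry an interior depletion (a protein-protected
    footprint) and a flanking-accessibility gain in every condition after
    the first; null motifs are flat in all conditions.
    """
    rng = _rng(config, "cuts")
    w, h = config.motif_width, config.window_halfwidth
    length = 2 * h + w
    interior = np.zeros(length, dtype=bool)
    interior[h : h + w] = True

    if config.footprint_motifs is not None:
        motif_specs = [(width, effects, config.footprint_fa_gain) for width, effects in config.footprint_motifs]
    else:
        # planted effects span a range of occupancies: factors differ in how
        # strongly they protect their motif and open the flanks
        motif_specs = []
        n_planted = config.n_footprint_motifs
        for m in range(config.n_motifs):
            planted = m < n_planted
            frac = m / max(n_planted - 1, 1) if planted else 0.0
            depletion = config.footprint_depletion * (0.6 + 0.8 * frac)
            gain = 1.0 + (config.footprint_fa_gain - 1.0) * (0.5 + frac)
            effects = tuple(
                depletion if (planted and t > 0) else 1.0
                for t in range(config.n_conditions)
            )
            motif_specs.append((w, effects, gain if planted else 1.0))

    occ_rows = []
    profiles: dict[str, list[np.ndarray]] = {c: [] for c in config.condition_names}
    truth_rows = []
    for m, (width, effects, fa_gain) in enumerate(motif_specs):
        motif_id = f"motif{m:03d}"
        planted = any(e != 1.0 for e in effects)
        truth_rows.append(
            {
                "motif_id": motif_id,
                "planted": planted,
                "depletion": min(effects),
                "fa_gain": fa_gain,
            }
        )
        n_occ = config.occurrences_per_motif
        chrom_idx = rng.integers(0, config.n_chroms, size=n_occ)
        starts = rng.integers(h + 1, config.chrom_length - width - h - 1, size=n_occ)
        strands = np.where(rng.random(n_occ) < 0.5, "+", "-")
        for o in range(n_occ):
            occ_rows.append(
                {
                    "occurrence_id": f"{motif_id}_occ{o:04d}",
                    "motif_id": motif_id,
                    "chrom": f"chr{chrom_idx[o] + 1}",
                    "start": int(starts[o]),
                    "end": int(starts[o]) + width,
                    "strand": strands[o],
                }
            )
        for t, cond in enumerate(config.condition_names):
            depletion = effects[t] if t < len(effects) else effects[-1]
            gain = fa_gain if (planted and t > 0) else 1.0
            # condition-contrast bias relative to the first condition,
            # uniform on a disk of bounded log2 radius
            radius = config.motif_log2_wobble * math.sqrt(rng.uniform())
            angle = rng.uniform(0.0, 2.0 * math.pi)
            if t == 0:
                radius = 0.0
            fa_wobble = 2.0 ** (radius * math.cos(angle))
            fpd_wobble = 2.0 ** (radius * math.sin(angle))
            weights = np.ones(length)
            weights[interior] = depletion * fpd_wobble
            prob = weights / weights.sum()
            total_mean = config.cuts_per_bp * length * gain * fa_wobble
            totals = rng.poisson(total_mean, size=n_occ)
            counts = rng.multinomial(totals, prob)
            # genome orientation: minus-strand occurrences store the window
            # reversed, so aggregation must flip them back
            minus = strands == "-"
            counts[minus] = counts[minus, ::-1]
            profiles[cond].append(counts)

    occurrences = pd.DataFrame(occ_rows).set_index("occurrence_id")
    cut_counts = {}
    libsizes = {}
    for cond in config.condition_names:
        matrix = np.concatenate(profiles[cond], axis=0)
        df = pd.DataFrame(
            matrix, index=occurrences.index, columns=np.arange(length) - h
        )
        cut_counts[cond] = df
        libsizes[cond] = float(matrix.sum())
    truth = pd.DataFrame(truth_rows).set_index("motif_id")
    return CutProfileSim(
        occurrences=occurrences,
        cut_counts=cut_counts,
        libsizes=libsizes,
        truth=truth,
        window_halfwidth=h,
        motif_width=w,
    )


# ---------------------------------------------------------------------------
# single cells


@dataclass
class SingleCellSim:
    counts: pd.DataFrame  # cells x genes
    cells: pd.DataFrame  # condition, t_true, driver_on, outlier_type
    universe: pd.DataFrame


def simulate_single_cells(
    config: SimulationConfig, universe: pd.DataFrame | None = None
) -> SingleCellSim:
    """NB single-cell counts with planted QC outliers, regulons and a trajectory.

    Per-cell trajectory position t in [0, 1] is monotone in condition
    index.  Activated-regulon genes switch on only in cells whose driver
    TF is itself on (probability increasing along the trajectory), with
    expression scaling in t; elsewhere they sit at the basal rate.  Planted
    outliers are low-depth cells (library far below median - 4 MAD) and
    doublet-like cells (far above median + 4 MAD); normal cells draw their
    depth from a bounded log-uniform band so the MAD fences separate the
    two populations cleanly.
    """
    if universe is None:
        universe = simulate_gene_universe(config)
    rng = _rng(config, "cells")
    n_genes = len(universe)
    n_cond = config.n_conditions
    n_per = config.n_cells_per_condition
    n_cells = n_cond * n_per

    condition = np.repeat(np.arange(n_cond), n_per)
    t_true = (condition + rng.random(n_cells)) / n_cond

    # per-gene baseline rates; a slice of genes is nearly silent so the
    # low-expression filter has something to remove
    gene_scale = np.exp(rng.normal(0.0, 0.8, size=n_genes))
    gene_scale *= config.sc_mean_count / gene_scale.mean()
    n_low = int(config.sc_lowly_expressed_fraction * n_genes)
    low_idx = rng.choice(n_genes, size=n_low, replace=False)
    gene_scale[low_idx] *= 0.005

    # temporal modulation follows the gene archetype (shared with ATAC
    # truth), interpolated continuously along the trajectory: differentiation
    # is a continuum and the conditions are snapshots of it
    arch = universe["archetype"].to_numpy()
    pattern_values = np.zeros((n_genes, n_cond))
    for a, pattern in _ARCHETYPE_PATTERNS.items():
        rows = arch == a
        pattern_values[rows] = [pattern(t) for t in range(n_cond)]
    tau = t_true * (n_cond - 1)
    lo = np.floor(tau).astype(int).clip(0, n_cond - 2)
    frac = tau - lo
    log2fc_cells = (
        pattern_values[:, lo] * (1.0 - frac) + pattern_values[:, lo + 1] * frac
    ).T  # cells x genes
    mean = gene_scale[None, :] * config.effect_fold**log2fc_cells

    # regulon program: driver turns on with probability t, members scale in t
    regulon = universe["regulon"].to_numpy()
    is_driver = universe["is_driver"].to_numpy()
    driver_on = np.zeros((n_cells, config.n_regulons), dtype=bool)
    for r in range(config.n_regulons):
        driver_on[:, r] = rng.random(n_cells) < t_true
    for r in range(config.n_regulons):
        members = (regulon == r) & ~is_driver
        factor = np.where(
            driver_on[:, r],
            config.regulon_basal + config.regulon_activation * t_true,
            config.regulon_basal,
        )
        mean[:, members] = mean[:, members] * factor[:, None]
        driver_col = (regulon == r) & is_driver
        mean[:, driver_col] = np.where(
            driver_on[:, r][:, None], 5.0 * config.sc_mean_count, 0.01
        )

    # library depth: bounded band for normal cells, extreme planted outliers
    depth = 2.0 ** rng.uniform(-0.4, 0.4, size=n_cells)
    outlier_type = np.full(n_cells, "none", dtype=object)
    n_out = int(round(config.outlier_cell_fraction * n_cells))
    if n_out:
        out_idx = rng.choice(n_cells, size=n_out, replace=False)
        half = n_out // 2
        low_cells, high_cells = out_idx[:half], out_idx[half:]
        depth[low_cells] = 0.05
        depth[high_cells] = 4.0
        outlier_type[low_cells] = "low_depth"
        outlier_type[high_cells] = "doublet"

    # sequencing depth is an experimental property: rescale every cell's
    # expected total so that biology (condition programs, regulon firing)
    # shifts transcriptome composition, not library size
    mean *= gene_scale.sum() / mean.sum(axis=1, keepdims=True)
    counts = nb_sample(rng, depth[:, None] * mean, config.sc_dispersion)

    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "condition": [config.condition_names[c] for c in condition],
            "condition_index": condition,
            "t_true": t_true,
            "outlier_type": outlier_type,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    for r in range(config.n_regulons):
        cells[f"driver_on_{r}"] = driver_on[:, r]
    return SingleCellSim(
        counts=pd.DataFrame(counts, index=cell_ids, columns=universe.index),
        cells=cells,
        universe=universe,
    )


# ---------------------------------------------------------------------------
# knockdown bulk RNA


@dataclass
class KnockdownSim:
    counts: CountTable  # genes x (control_i, kd_i) pairs
    pairs: list[tuple[str, str]]
    truth: pd.DataFrame  # gene -> de_direction, bound
    universe: pd.DataFrame


def simulate_knockdown(
    config: SimulationConfig, universe: pd.DataFrame | None = None
) -> KnockdownSim:
    """Paired control/knockdown bulk counts with planted direct targets.

    Depleting the driver lowers its activated regulon (planted direction
    ``down_in_kd``) and raises the repressed regulon (``up_in_kd``).  The
    planted bound set is every regulon member plus ``n_bound_null_genes``
    unaffected genes, emulating binding events with no expression
    consequence.  Pair-to-pair noise is the residual dispersion of a paired
    design (the shared biological component cancels within a pair).
    """
    if universe is None:
        universe = simulate_gene_universe(config)
    if config.n_replicate_pairs < 2:
        raise ValueError("need at least 2 replicate pairs")
    rng = _rng(config, "knockdown")
    n = len(universe)

    direction = np.full(n, "none", dtype=object)
    reg_dir = universe["regulon_direction"].to_numpy()
    is_driver = universe["is_driver"].to_numpy()
    direction[(reg_dir == "activated") & ~is_driver] = "down_in_kd"
    direction[(reg_dir == "repressed") & ~is_driver] = "up_in_kd"
    kd_factor = np.ones(n)
    kd_factor[direction == "down_in_kd"] = 1.0 / config.knockdown_fold
    kd_factor[direction == "up_in_kd"] = config.knockdown_fold

    bound = universe["regulon"].to_numpy() >= 0
    unbound_null = np.flatnonzero(~bound & (direction == "none"))
    extra = rng.choice(
        unbound_null, size=min(config.n_bound_null_genes, unbound_null.size), replace=False
    )
    bound = bound.copy()
    bound[extra] = True

    columns: dict[str, np.ndarray] = {}
    pairs = []
    for p in range(config.n_replicate_pairs):
        pair_base = np.exp(
            rng.normal(config.bulk_log_mean, config.bulk_log_sd, size=n)
        )
        ctrl = nb_sample(rng, pair_base, config.bulk_pair_dispersion)
        kd = nb_sample(rng, pair_base * kd_factor, config.bulk_pair_dispersion)
        columns[f"control_{p + 1}"] = ctrl
        columns[f"kd_{p + 1}"] = kd
        pairs.append((f"control_{p + 1}", f"kd_{p + 1}"))

    counts = CountTable(pd.DataFrame(columns, index=universe.index))
    truth = pd.DataFrame(
        {"de_direction": direction, "bound": bound}, index=universe.index
    )
    return KnockdownSim(counts=counts, pairs=pairs, truth=truth, universe=universe)


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same study with every planted effect switched off."""
    return replace(
        config,
        effect_fold=1.0,
        footprint_depletion=1.0,
        footprint_fa_gain=1.0,
        n_footprint_motifs=0,
        knockdown_fold=1.0,
        outlier_cell_fraction=0.0,
    )
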