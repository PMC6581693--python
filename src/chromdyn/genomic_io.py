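"""Reading and writing of the genomic text formats the pipeline touches.

All coordinates are stored 0-based half-open (BED convention).  The only
1-based dialect accepted is GTF gene records, which are converted on read.
Chromosome names are compared as exact strings; an optional ``normalize``
flag strips a leading ``chr`` prefix at the boundary but is off by default,
because silent aliasing hides real mismatches between inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A line or cell of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a coordinate or count invariant."""


@dataclass
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates.

    ``summit_offset`` is the offset of a point source (e.g. a peak summit)
    relative to ``start``; when absent, downstream operations anchor on the
    interval midpoint.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"unknown strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValidationError(
                f"summit offset {self.summit_offset} outside interval of length "
                f"{self.end - self.start}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit position when known, otherwise the midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.midpoint


@dataclass
class GeneModel:
    """Gene-level annotation reduced to what peak assignment needs."""

    gene_id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )
        if self.body_end <= self.body_start:
            raise ValidationError(f"gene {self.gene_id}: empty body")

    @property
    def tss(self) -> int:
        """Transcription start site: body start on +, last base on -."""
        return self.body_start if self.strand == "+" else self.body_end - 1


@dataclass
class CountTable:
    """A features x samples table of non-negative counts.

    Library sizes are the column sums computed on the full feature set and
    are cached at construction so that subsetting rows later does not
    silently change the normalization denominator.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("count table is empty")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate row id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate column id {dup!r}")
        values = df.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("non-finite count value")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        if self.library_sizes is None:
            self.library_sizes = df.sum(axis=0)

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_rows(self, row_ids: Sequence[str]) -> "CountTable":
        """Row subset that keeps the original library sizes."""
        return CountTable(self.counts.loc[list(row_ids)], self.library_sizes)


def _normalize_chrom(chrom: str, normalize: bool) -> str:
    if normalize and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def read_bed(path: str | Path, normalize_chrom: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak into a list of intervals, in file order.

    The narrowPeak 10th column (point-source offset) is mapped to
    ``summit_offset``; a value of -1 means "no summit" and is dropped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            summit: int | None = None
            if len(fields) >= 10:  # narrowPeak
                try:
                    summit_val = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer summit") from exc
                if summit_val >= 0:
                    summit = summit_val
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=_normalize_chrom(fields[0], normalize_chrom),
                        start=start,
                        end=end,
                        strand=strand,
                        score=score,
                        name=name,
                        summit_offset=summit,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3/BED6/narrowPeak depending on populated fields.

    Round trip with :func:`read_bed` preserves coordinates, names, scores,
    strands and summit offsets bit-exactly for conforming files.
    """
    intervals = list(intervals)
    any_summit = any(iv.summit_offset is not None for iv in intervals)
    any_meta = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if any_meta or any_summit:
                cols += [
                    iv.name if iv.name is not None else ".",
                    _format_score(iv.score) if iv.score is not None else ".",
                    iv.strand,
                ]
            if any_summit:
                # narrowPeak: signalValue/pValue/qValue placeholders, then summit
                cols += [
                    _format_score(iv.score) if iv.score is not None else "0",
                    "-1",
                    "-1",
                    str(iv.summit_offset) if iv.summit_offset is not None else "-1",
                ]
            fh.write("\t".join(cols) + "\n")


def read_gene_models(
    path: str | Path, normalize_chrom: bool = False
) -> list[GeneModel]:
    """Read a gene table (6-column TSV) or GTF-lite gene records.

    The TSV dialect has a header ``gene_id chrom start end strand`` with
    0-based half-open body coordinates.  GTF records (detected by 9
    tab-separated columns with ``gene`` in the feature field) are 1-based
    closed and are converted on read.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()

    def _add(gene: GeneModel, lineno: int) -> None:
        if gene.gene_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        genes.append(gene)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 9 and fields[2]:  # GTF-lite
                if fields[2] != "gene":
                    continue
                attrs = fields[8]
                gene_id = None
                for chunk in attrs.split(";"):
                    chunk = chunk.strip()
                    if chunk.startswith("gene_id"):
                        gene_id = chunk.split(None, 1)[1].strip().strip('"')
                        break
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: gene record without gene_id")
                try:
                    start_1based, end_closed = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                _add(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=_normalize_chrom(fields[0], normalize_chrom),
                        strand=fields[6],
                        body_start=start_1based - 1,
                        body_end=end_closed,
                    ),
                    lineno,
                )
            else:
                if lineno == 1 and fields[0].lower() in ("gene_id", "gene"):
                    continue  # header row
                if len(fields) < 5:
                    raise ParseError(f"{path}:{lineno}: expected >=5 columns")
                try:
                    start, end = int(fields[2]), int(fields[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                try:
                    _add(
                        GeneModel(
                            gene_id=fields[0],
                            chrom=_normalize_chrom(fields[1], normalize_chrom),
                            strand=fields[4],
                            body_start=start,
                            body_end=end,
                        ),
                        lineno,
                    )
                except ValidationError as exc:
                    if "duplicate" in str(exc):
                        raise
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.body_start}\t{g.body_end}\t{g.strand}\n")


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (rows = features, columns = samples)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty table") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed rows: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty table")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: missing cell at row {row!r}, column {col!r}")
        df[col] = converted
    return CountTable(df)


def write_count_table(table: CountTable | pd.DataFrame, path: str | Path) -> None:
    df = table.counts if isinstance(table, CountTable) else table
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_mtx_counts(
    mtx_path: str | Path,
    row_path: str | Path,
    col_path: str | Path,
) -> CountTable:
    """Read MatrixMarket counts with row/column id sidecar files.

    Rows of the MTX are features (genes) and columns are cells, the usual
    single-cell export convention; the returned table keeps that orientation.
    """
    from scipy.io import mmread

    matrix = mmread(mtx_path).toarray()
    rows = [l.strip().split("\t")[0] for l in open(row_path) if l.strip()]
    cols = [l.strip().split("\t")[0] for l in open(col_path) if l.strip()]
    if matrix.shape != (len(rows), len(cols)):
        raise ValidationError(
            f"matrix shape {matrix.shape} does not match sidecars "
            f"({len(rows)} rows, {len(cols)} columns)"
        )
    return CountTable(pd.DataFrame(matrix, index=rows, columns=cols))
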