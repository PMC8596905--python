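"""Cell-by-bin read-depth matrices with genomic bin annotations.

The segmentation engine consumes two matrices of shape ``(m bins, n cells)``:
the raw read counts ``Y`` and a matched normalized (expected-diploid) matrix
``Y_hat``.  Bins are fixed-width genomic windows; coordinates are held 1-based
inclusive internally and converted from BED (0-based half-open) on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Input data violates a structural contract."""


class DimensionMismatchError(ValidationError):
    """Matrix and annotation dimensions disagree."""


RAW = "raw"
NORMALIZED = "normalized"


@dataclass(frozen=True)
class BinAnnotation:
    """One fixed-width genomic window.

    Coordinates are 1-based inclusive; ``index`` is the 0-based ordinal of the
    bin in the genome-wide bin list.
    """

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"bin {self.index} on {self.chrom}: start {self.start} > end {self.end}"
            )


@dataclass
class ReadDepthMatrix:
    """Raw or normalized read counts, bins x cells.

    Parameters
    ----------
    values
        Non-negative array of shape ``(m, n)``.  Raw matrices must be
        integer-valued; normalized matrices are real.
    bins
        One :class:`BinAnnotation` per row, sorted and non-overlapping within
        each chromosome.
    cell_ids
        One id per column.
    kind
        ``"raw"`` or ``"normalized"``.
    """

    values: np.ndarray
    bins: list[BinAnnotation]
    cell_ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"matrix must be 2-D, got shape {self.values.shape}")
        m, n = self.values.shape
        if len(self.bins) != m:
            raise DimensionMismatchError(
                f"matrix has {m} rows but {len(self.bins)} bin annotations"
            )
        if len(self.cell_ids) != n:
            raise DimensionMismatchError(
                f"matrix has {n} columns but {len(self.cell_ids)} cell ids"
            )
        if self.kind not in (RAW, NORMALIZED):
            raise ValidationError(f"kind must be 'raw' or 'normalized', got {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite entries")
        if (self.values < 0).any():
            raise ValidationError("matrix contains negative entries")
        if self.kind == RAW and not np.allclose(self.values, np.round(self.values)):
            raise ValidationError("raw matrix contains non-integer entries")
        self._check_bin_order()

    def _check_bin_order(self) -> None:
        seen: set[str] = set()
        last_chrom = None
        prev_end = 0
        for b in self.bins:
            if b.chrom != last_chrom:
                if b.chrom in seen:
                    raise ValidationError(
                        f"bins of chromosome {b.chrom} are not contiguous"
                    )
                seen.add(b.chrom)
                last_chrom = b.chrom
            elif b.start <= prev_end:
                raise ValidationError(
                    f"bins on {b.chrom} overlap or are unsorted near {b.start}"
                )
            prev_end = b.end

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for b in self.bins:
            if not out or out[-1] != b.chrom:
                out.append(b.chrom)
        return out

    def bin_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "index": [b.index for b in self.bins],
            }
        )


def _bins_from_frame(df: pd.DataFrame) -> list[BinAnnotation]:
    return [
        BinAnnotation(str(c), int(s), int(e), i)
        for i, (c, s, e) in enumerate(zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]))
    ]


def read_bins(path: str | Path) -> list[BinAnnotation]:
    """Read a 3-column BED file; 0-based half-open becomes 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: BED file needs >= 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3].copy()
    df.iloc[:, 1] = df.iloc[:, 1].astype(int) + 1  # BED start -> 1-based
    return _bins_from_frame(df)


def write_bins(bins: Sequence[BinAnnotation], path: str | Path) -> None:
    """Write bins as BED (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\n")


def read_matrix(
    path: str | Path,
    bins_path: str | Path,
    kind: str,
    cells_path: str | Path | None = None,
) -> ReadDepthMatrix:
    """Load a counts matrix plus its bin annotations.

    ``path`` may be a dense TSV (header row of cell ids, one row per bin) or a
    MatrixMarket ``.mtx`` coordinate file, in which case ``cells_path`` (one
    cell id per line) is required.
    """
    bins = read_bins(bins_path)
    path = Path(path)
    if path.suffix == ".mtx":
        if cells_path is None:
            raise ValidationError("MTX input requires a companion cells file")
        mm = scipy.io.mmread(path)
        if scipy.sparse.issparse(mm):
            mm = mm.toarray()
        values = np.asarray(mm, dtype=float)
        cell_ids = [ln.strip() for ln in open(cells_path) if ln.strip()]
    else:
        df = pd.read_csv(path, sep="\t", header=0)
        cell_ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    if values.shape[0] != len(bins):
        raise DimensionMismatchError(
            f"matrix {path} has {values.shape[0]} rows but bins file has {len(bins)} rows"
        )
    return ReadDepthMatrix(values, bins, cell_ids, kind)


def write_matrix(mat: ReadDepthMatrix, path: str | Path) -> None:
    """Write the dense TSV dialect (header of cell ids, one row per bin)."""
    vals = mat.values
    if mat.kind == RAW:
        vals = vals.astype(int)
    pd.DataFrame(vals, columns=mat.cell_ids).to_csv(path, sep="\t", index=False)


def slice_chromosome(mat: ReadDepthMatrix, chrom: str) -> ReadDepthMatrix:
    """Return the contiguous block of bins on ``chrom`` (cells unchanged)."""
    idx = [i for i, b in enumerate(mat.bins) if b.chrom == chrom]
    if not idx:
        raise KeyError(
            f"chromosome {chrom!r} not present; available: {mat.chromosomes}"
        )
    sl = slice(idx[0], idx[-1] + 1)
    return ReadDepthMatrix(mat.values[sl].copy(), mat.bins[sl], list(mat.cell_ids), mat.kind)


def concat_chromosomes(parts: Iterable[ReadDepthMatrix]) -> ReadDepthMatrix:
    """Vertically re-concatenate per-chromosome slices (inverse of slicing)."""
    parts = list(parts)
    values = np.vstack([p.values for p in parts])
    bins = [b for p in parts for b in p.bins]
    return ReadDepthMatrix(values, bins, list(parts[0].cell_ids), parts[0].kind)


def normalize_baseline(
    raw: ReadDepthMatrix,
    normal_cells: Sequence[str] | None = None,
    eps: float = 1e-8,
) -> ReadDepthMatrix:
    """Rank-1 diploid baseline: per-bin reference level x per-cell library size.

    ``Y_hat[i, j] = b_i * s_j`` with ``b_i`` the mean raw count of bin *i*
    over the baseline cells (``normal_cells`` if given, else all cells) and
    ``s_j`` the cell-*j* total count divided by the mean total of the baseline
    cells.  This is a deliberately simple stand-in for model-based cross-cell
    normalization; externally normalized matrices may be supplied instead.
    """
    if raw.kind != RAW:
        raise ValidationError("normalize_baseline expects a raw matrix")
    col_tot = raw.values.sum(axis=0)
    row_tot = raw.values.sum(axis=1)
    if (row_tot == 0).any():
        i = int(np.argmax(row_tot == 0))
        b = raw.bins[i]
        raise ValidationError(f"bin {i} ({b.chrom}:{b.start}-{b.end}) has zero count in every cell")
    if (col_tot == 0).any():
        j = int(np.argmax(col_tot == 0))
        raise ValidationError(f"cell {raw.cell_ids[j]!r} has zero total count")
    if normal_cells is not None:
        missing = set(normal_cells) - set(raw.cell_ids)
        if missing:
            raise ValidationError(f"unknown normal cells: {sorted(missing)}")
        cols = [raw.cell_ids.index(c) for c in normal_cells]
    else:
        cols = list(range(raw.n))
    b = raw.values[:, cols].mean(axis=1)
    s = col_tot / col_tot[cols].mean()
    values = np.maximum(np.outer(b, s), eps)
    return ReadDepthMatrix(values, list(raw.bins), list(raw.cell_ids), NORMALIZED)
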