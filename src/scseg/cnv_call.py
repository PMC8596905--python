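"""Integer copy-number calling from a segmentation.

For every segment and cell the copy number is ``round(2 X / X_hat)`` of the
segment-level mean raw and normalized depths, clamped to ``[0, cn_cap]`` and
broadcast to all bins of the segment, yielding a cell-by-bin integer matrix
that is piecewise constant per segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth_matrix import (
    BinAnnotation,
    ReadDepthMatrix,
    ValidationError,
    slice_chromosome,
)
from .mbic_core import MBICParams, Segmentation, rounded_cn, segment_stat


@dataclass
class CNVMatrix:
    """Integer copy number per bin per cell, with the segmentation used.

    ``overflow`` marks entries whose uncapped rounded copy number exceeded
    ``cn_cap`` (reported clamped, e.g. ">= 10" in heatmaps).
    """

    values: np.ndarray
    bins: list[BinAnnotation]
    cell_ids: list[str]
    segments: list[Segmentation]
    overflow: np.ndarray

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def call_copy_number(
    raw: ReadDepthMatrix,
    norm: ReadDepthMatrix,
    segs: Sequence[Segmentation],
    params: MBICParams | None = None,
) -> CNVMatrix:
    """Copy-number matrix from segment-level mean depth ratios.

    Every chromosome of the input must be covered by exactly one
    segmentation; within each segment the call is constant across bins.
    """
    params = params or MBICParams()
    by_chrom: dict[str, Segmentation] = {}
    for seg in segs:
        if seg.chrom in by_chrom:
            raise ValidationError(f"chromosome {seg.chrom} covered by two segmentations")
        by_chrom[seg.chrom] = seg
    missing = [c for c in raw.chromosomes if c not in by_chrom]
    extra = [c for c in by_chrom if c not in raw.chromosomes]
    if missing or extra:
        raise ValidationError(
            f"segmentations do not match matrix chromosomes (missing {missing}, extra {extra})"
        )
    values = np.zeros(raw.values.shape, dtype=int)
    overflow = np.zeros(raw.values.shape, dtype=bool)
    offset = 0
    for chrom in raw.chromosomes:
        sub_raw = slice_chromosome(raw, chrom)
        sub_norm = slice_chromosome(norm, chrom)
        seg = by_chrom[chrom]
        bounds = seg.segment_bounds(sub_raw.m)
        covered = sum(b - a + 1 for a, b in bounds)
        if covered != sub_raw.m:
            raise ValidationError(
                f"{chrom}: segmentation covers {covered} bins, matrix has {sub_raw.m}"
            )
        for a, b in bounds:
            stat = segment_stat(sub_raw, sub_norm, a, b)
            c_raw = rounded_cn(stat.X_row, stat.Xhat_row)
            c = np.clip(c_raw, 0, params.cn_cap)
            values[offset + a : offset + b + 1] = c
            overflow[offset + a : offset + b + 1] = c_raw > params.cn_cap
        offset += sub_raw.m
    return CNVMatrix(values, list(raw.bins), list(raw.cell_ids), list(segs), overflow)


def aggregate_by_group(cnv: CNVMatrix, labels: Mapping[str, str]) -> pd.DataFrame:
    """Mean copy number per group per bin (groups as rows)."""
    unlabeled = [c for c in cnv.cell_ids if c not in labels]
    if unlabeled:
        raise ValidationError(f"unlabeled cells: {unlabeled[:5]}")
    groups = sorted({labels[c] for c in cnv.cell_ids})
    rows = {
        g: cnv.values[:, [i for i, c in enumerate(cnv.cell_ids) if labels[c] == g]].mean(axis=1)
        for g in groups
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(cnv.m))


def write_cnv(cnv: CNVMatrix, path: str | Path) -> None:
    """Dense TSV of integers, header row of cell ids, one row per bin."""
    pd.DataFrame(cnv.values, columns=cnv.cell_ids).to_csv(path, sep="\t", index=False)


def cnv_long_table(cnv: CNVMatrix) -> pd.DataFrame:
    """Long-format (cell, chrom, start, end, cn) table for downstream tools."""
    rows = []
    for j, cell in enumerate(cnv.cell_ids):
        for i, b in enumerate(cnv.bins):
            rows.append((cell, b.chrom, b.start, b.end, int(cnv.values[i, j])))
    return pd.DataFrame(rows, columns=["cell", "chrom", "start", "end", "cn"])
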