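"""Exact segmentation by dynamic programming.

The optimal shared segmentation of one chromosome's ``m`` bins is found by a
classic changepoint recursion: ``L(k, i)``, the best generalized
log-likelihood of partitioning bins ``0..i`` into ``k`` segments, satisfies

    L(k, i) = max_{i'} [ L(k-1, i') + l(i'+1, i) ]

with ``l(a, b)`` the single-segment log-likelihood table.  The
model-complexity penalty depends only on the segment count ``k``, so it is
constant within each DP layer and can be added afterwards:
``beta(k, i) = L(k, i) - log C(m, k-1) - (k-1)(kappa1 - kappa2)``.  The
optimal segment count is ``k* = argmax_k beta(k, m-1)`` and the turning
points are recovered from the back-pointer table ``T``.

Cost: ``O(m^2 n)`` to build ``l`` with prefix sums plus ``O(m^2 K)`` for the
recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .depth_matrix import ReadDepthMatrix, ValidationError, slice_chromosome
from .mbic_core import MBICParams, Segmentation, mbic_penalty

DEFAULT_MAX_SEGMENTS = 15


@dataclass
class DPTables:
    """Filled DP state for one chromosome.

    l_table : (m, m) single-segment log-likelihoods, ``l_table[i, j]`` for
        bins ``i..j`` inclusive; ``-inf`` below the diagonal.
    L : (K, m) best log-likelihood, row ``k-1`` for ``k`` segments.
    beta : (K, m) ``L`` plus the layer penalty.
    T : (K, m) back-pointers; ``T[k-1, i]`` is the last bin of the left part
        in the optimal ``k``-split of bins ``0..i`` (``-1`` sentinel for
        ``k = 1``).
    """

    l_table: np.ndarray
    L: np.ndarray
    beta: np.ndarray
    T: np.ndarray
    K: int


def build_l_table(
    raw: ReadDepthMatrix, norm: ReadDepthMatrix, params: MBICParams | None = None
) -> np.ndarray:
    """Single-segment log-likelihood ``l[i, j]`` for every bin range.

    Uses prefix sums over bins so each of the ``O(m^2)`` entries costs
    ``O(n)``.  Requires strictly positive normalized counts.
    """
    params = params or MBICParams()
    if raw.values.shape != norm.values.shape:
        raise ValidationError("raw and normalized matrices differ in shape")
    m, n = raw.values.shape
    if m == 0:
        raise ValidationError("empty chromosome")
    if (norm.values <= 0).any():
        raise ValidationError("normalized matrix must be strictly positive")
    P = np.vstack([np.zeros(n), np.cumsum(raw.values, axis=0)])
    Phat = np.vstack([np.zeros(n), np.cumsum(norm.values, axis=0)])
    l = np.full((m, m), -np.inf)
    half_floor = params.log_floor / 2.0
    for i in range(m):
        lens = np.arange(1, m - i + 1, dtype=float)[:, None]
        X = (P[i + 1:] - P[i]) / lens
        Xhat = (Phat[i + 1:] - Phat[i]) / lens
        c = np.floor(2.0 * X / Xhat + 0.5)
        ratio = np.where(c > 0, c / 2.0, half_floor)
        terms = Xhat * (1.0 - c / 2.0) + X * np.log(ratio)
        l[i, i:] = (lens[:, 0]) * terms.sum(axis=1)
    return l


def dp_fill(l_table: np.ndarray, params: MBICParams | None = None, K: int | None = None) -> DPTables:
    """Fill the ``L``/``beta``/``T`` tables for segment counts 1..K.

    Ties in the transition argmax are broken toward the smallest split
    position, making the output deterministic.
    """
    params = params or MBICParams()
    m = l_table.shape[0]
    if K is None:
        K = min(m, DEFAULT_MAX_SEGMENTS)
    if K > m:
        raise ValidationError(f"K={K} exceeds bin count m={m}")
    if K < 1:
        raise ValidationError("K must be >= 1")
    L = np.full((K, m), -np.inf)
    T = np.full((K, m), -1, dtype=int)
    L[0] = l_table[0]
    for k in range(2, K + 1):
        lo = k - 2  # smallest admissible split position (left part has k-1 bins)
        for i in range(k - 1, m):
            vals = L[k - 2, lo:i] + l_table[lo + 1 : i + 1, i]
            best = int(np.argmax(vals))  # first max -> smallest i'
            L[k - 1, i] = vals[best]
            T[k - 1, i] = lo + best
    beta = np.full((K, m), -np.inf)
    for k in range(1, K + 1):
        pen = mbic_penalty(m, k, params)
        row = L[k - 1]
        beta[k - 1] = np.where(np.isfinite(row), row + pen, -np.inf)
    return DPTables(l_table=l_table, L=L, beta=beta, T=T, K=K)


def backtrack(tables: DPTables, m: int | None = None, chrom: str = "chr") -> Segmentation:
    """Select ``k* = argmax_k beta(k, m-1)`` and walk the back-pointers.

    Ties in ``k*`` are broken toward fewer segments.
    """
    if m is None:
        m = tables.l_table.shape[0]
    final = tables.beta[:, m - 1]
    kstar = int(np.argmax(final)) + 1  # first max -> smallest k
    tps: list[int] = []
    cur = m - 1
    for k in range(kstar, 1, -1):
        tp = int(tables.T[k - 1, cur])
        tps.append(tp)
        cur = tp
    tps.reverse()
    return Segmentation(
        chrom=chrom,
        turning_points=tps,
        n_segments=kstar,
        mbic=float(final[kstar - 1]),
        loglik=float(tables.L[kstar - 1, m - 1]),
    )


def segment_chromosome(
    raw: ReadDepthMatrix,
    norm: ReadDepthMatrix,
    params: MBICParams | None = None,
    K: int | None = None,
) -> Segmentation:
    """Optimal segmentation of a single-chromosome matrix pair."""
    chroms = raw.chromosomes
    if len(chroms) != 1:
        raise ValidationError(
            f"segment_chromosome expects one chromosome, got {chroms}"
        )
    params = (params or MBICParams()).resolved(raw.n)
    l = build_l_table(raw, norm, params)
    tables = dp_fill(l, params, K)
    return backtrack(tables, raw.m, chrom=chroms[0])


def segment_genome(
    raw: ReadDepthMatrix,
    norm: ReadDepthMatrix,
    params: MBICParams | None = None,
    K: int | None = None,
) -> list[Segmentation]:
    """Independent per-chromosome segmentation, in bin-annotation order."""
    out = []
    for chrom in raw.chromosomes:
        out.append(
            segment_chromosome(
                slice_chromosome(raw, chrom), slice_chromosome(norm, chrom), params, K
            )
        )
    return out


def segments_to_frame(segs: list[Segmentation], raw: ReadDepthMatrix):
    """Tabular export: one row per segment with bin and bp coordinates."""
    import pandas as pd

    rows = []
    for seg in segs:
        sub = slice_chromosome(raw, seg.chrom)
        for si, (a, b) in enumerate(seg.segment_bounds(sub.m)):
            rows.append(
                {
                    "chrom": seg.chrom,
                    "segment_index": si,
                    "start_bin": a,
                    "end_bin": b,
                    "start_bp": sub.bins[a].start,
                    "end_bp": sub.bins[b].end,
                    "mbic_of_chrom": seg.mbic,
                }
            )
    return pd.DataFrame(rows)
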