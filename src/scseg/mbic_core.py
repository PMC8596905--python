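"""Simplified modified-BIC scoring of a shared segmentation.

A segmentation of the ``m`` ordered bins of one chromosome into ``l``
contiguous segments is scored by

    beta(S) = log(L_tau / L_0) - log C(m, l-1) - (l-1) * (kappa1 - kappa2)

where ``log(L_tau / L_0)`` is the generalized log-likelihood ratio of the
segmented Poisson model against the unsegmented (everywhere-diploid) null.
For segment ``s_k`` with per-cell means ``X`` (raw) and ``X_hat``
(normalized), and rounded copy number ``c = round(2 X / X_hat)`` shared by
all bins of the segment, each cell contributes

    |s_k| * [ X_hat * (1 - c/2) + X * log(c/2) ]

i.e. the per-bin Poisson log-likelihood ratio summed over the ``|s_k|`` bins
of the segment.  A segment in which every cell rounds to the diploid state
``c = 2`` contributes exactly zero, so splits that change no cell's copy
state are never rewarded and the combinatorial penalty decides against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .depth_matrix import ReadDepthMatrix, ValidationError


@dataclass(frozen=True)
class MBICParams:
    """Scoring constants.

    kappa1, kappa2
        Pre-defined penalty constants; only their difference enters the
        score.  Each added segment grants every cell a fresh copy-number
        state, so the per-breakpoint charge must scale with the cell count
        to act as a BIC-type complexity penalty; ``kappa1 = None`` (the
        default) therefore resolves to ``n / 2`` — one half per effective
        per-cell parameter — when a matrix is at hand (see
        :meth:`resolved`).  Pass explicit floats to override.
    cn_cap
        Largest copy number reported by the caller (likelihood uses the
        uncapped rounded value).
    log_floor
        Effective copy-number floor substituted for ``c = 0`` inside the log
        term, keeping homozygous deletions finitely but strongly penalized.
    """

    kappa1: float | None = None
    kappa2: float = 0.0
    cn_cap: int = 10
    log_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.kappa1 is not None and not np.isfinite(self.kappa1):
            raise ValidationError("kappa1 must be finite")
        if not np.isfinite(self.kappa2):
            raise ValidationError("kappa2 must be finite")
        if self.cn_cap < 2:
            raise ValidationError("cn_cap must be >= 2")
        if self.log_floor <= 0:
            raise ValidationError("log_floor must be > 0")

    def resolved(self, n_cells: int) -> "MBICParams":
        """Fill the cell-count-scaled default ``kappa1 = n_cells / 2``."""
        if self.kappa1 is not None:
            return self
        from dataclasses import replace

        return replace(self, kappa1=n_cells / 2.0)

    @property
    def kappa_diff(self) -> float:
        if self.kappa1 is None:
            raise ValidationError(
                "kappa1 is unresolved; call MBICParams.resolved(n_cells) first"
            )
        return self.kappa1 - self.kappa2


@dataclass
class SegmentStat:
    """Per-cell mean raw and normalized depth over one bin range (inclusive)."""

    start_bin: int
    end_bin: int
    X_row: np.ndarray
    Xhat_row: np.ndarray

    def __post_init__(self) -> None:
        if self.start_bin > self.end_bin:
            raise ValidationError("start_bin > end_bin")
        self.X_row = np.asarray(self.X_row, dtype=float)
        self.Xhat_row = np.asarray(self.Xhat_row, dtype=float)
        if self.X_row.shape != self.Xhat_row.shape:
            raise ValidationError("X_row and Xhat_row differ in length")
        if (self.Xhat_row <= 0).any():
            raise ValidationError("Xhat_row entries must be > 0")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class Segmentation:
    """Shared segmentation of one chromosome.

    ``turning_points`` holds the 0-based index of the LAST bin of every
    non-final segment, strictly increasing and all below ``m - 1``.
    """

    chrom: str
    turning_points: list[int]
    n_segments: int
    mbic: float
    loglik: float

    def __post_init__(self) -> None:
        tps = list(self.turning_points)
        if tps != sorted(set(tps)):
            raise ValidationError("turning points must be strictly increasing")
        if self.n_segments != len(tps) + 1:
            raise ValidationError("n_segments must equal len(turning_points) + 1")

    def segment_bounds(self, m: int) -> list[tuple[int, int]]:
        """Inclusive (start_bin, end_bin) pairs covering bins 0..m-1."""
        edges = [-1, *self.turning_points, m - 1]
        return [(edges[i] + 1, edges[i + 1]) for i in range(len(edges) - 1)]


def segment_stat(
    raw: ReadDepthMatrix, norm: ReadDepthMatrix, start_bin: int, end_bin: int
) -> SegmentStat:
    """Arithmetic per-cell means of raw/normalized counts over a bin range."""
    if raw.values.shape != norm.values.shape:
        raise ValidationError("raw and normalized matrices differ in shape")
    m = raw.m
    if not (0 <= start_bin <= end_bin < m):
        raise IndexError(f"bin range [{start_bin}, {end_bin}] out of bounds for m={m}")
    sl = slice(start_bin, end_bin + 1)
    return SegmentStat(
        start_bin, end_bin, raw.values[sl].mean(axis=0), norm.values[sl].mean(axis=0)
    )


def rounded_cn(X, Xhat, cn_cap: int | None = None):
    """Integer copy number ``round(2 X / X_hat)``, half away from zero.

    Vectorized; clamps to ``[0, cn_cap]`` when a cap is given.
    """
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    if (Xhat <= 0).any():
        raise ValidationError("normalized means must be > 0")
    c = np.floor(2.0 * X / Xhat + 0.5).astype(int)
    if cn_cap is not None:
        c = np.clip(c, 0, cn_cap)
    return c if c.ndim else int(c)


def _loglik_terms(X: np.ndarray, Xhat: np.ndarray, params: MBICParams) -> np.ndarray:
    """Per-cell, per-bin log-likelihood-ratio terms for one segment."""
    c = np.floor(2.0 * X / Xhat + 0.5)  # uncapped
    ratio = np.where(c > 0, c / 2.0, params.log_floor / 2.0)
    return Xhat * (1.0 - c / 2.0) + X * np.log(ratio)


def segment_loglik(stat: SegmentStat, params: MBICParams | None = None) -> float:
    """Generalized log-likelihood ratio contribution of one segment.

    Sums the per-cell term ``X_hat (1 - c/2) + X log(c/2)`` over cells and
    multiplies by the segment length in bins (the term is constant across the
    segment's bins under the shared rounded copy number ``c``).  Exactly zero
    when every cell is diploid (``c = 2``).
    """
    params = params or MBICParams()
    return float(stat.n_bins * _loglik_terms(stat.X_row, stat.Xhat_row, params).sum())


def mbic_penalty(m: int, ell: int, params: MBICParams | None = None) -> float:
    """Model-complexity penalty ``-log C(m, l-1) - (l-1)(kappa1 - kappa2)``."""
    params = params or MBICParams()
    if not 1 <= ell <= m:
        raise ValidationError(f"segment count {ell} outside [1, {m}]")
    log_binom = gammaln(m + 1) - gammaln(ell) - gammaln(m - ell + 2)
    return float(-log_binom - (ell - 1) * params.kappa_diff)


def score_segmentation(
    raw: ReadDepthMatrix,
    norm: ReadDepthMatrix,
    seg: Segmentation | list[int],
    params: MBICParams | None = None,
) -> float:
    """Score a segmentation by the simplified modified BIC (to be maximized).

    Accepts a :class:`Segmentation` or a bare turning-point list.  This is a
    direct evaluation of the objective, independent of the dynamic-programming
    engine, and serves as its scoring oracle.
    """
    params = (params or MBICParams()).resolved(raw.n)
    m = raw.m
    tps = seg.turning_points if isinstance(seg, Segmentation) else list(seg)
    if any(t < 0 or t >= m - 1 for t in tps):
        raise ValidationError(f"turning points {tps} invalid for m={m}")
    edges = [-1, *tps, m - 1]
    ll = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        ll += segment_loglik(segment_stat(raw, norm, a + 1, b), params)
    return ll + mbic_penalty(m, len(tps) + 1, params)
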