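"""Synthetic single-cell copy-number data with known ground truth.

Emulates the standard in-silico design for benchmarking shared-breakpoint
callers: one chromosome of fixed-width bins, a majority population of diploid
cells plus a handful of tumor subclones, each subclone carrying its own
integer copy-number profile over a common set of planted segments.  Counts
are simulated at the matrix level: a cell's expected depth in a bin is
``(cn / 2) * depth * bin_effect * cell_factor`` and the matched normalized
matrix is the corresponding diploid expectation, so ``2 * raw / norm`` is an
unbiased copy-number estimate.

Noise is applied at (cell, segment)-block granularity: each block is
independently replaced by a wrong copy number with probability
``noise_rate``, so the expected fraction of perturbed matrix entries equals
``noise_rate`` while the perturbations remain piecewise constant on the
planted segments (they change a cell's profile, not the set of shared
boundary positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .depth_matrix import NORMALIZED, RAW, BinAnnotation, ReadDepthMatrix, ValidationError


@dataclass(frozen=True)
class SimParams:
    """Simulation design.

    n_cells, n_bins
        Matrix size; defaults give the 100-cell x 70-bin single-chromosome
        design.
    n_clones
        Tumor subclones (excluding the normal population).
    normal_fraction
        Fraction of cells that are diploid everywhere.
    n_segments
        Planted segments shared by all clones (``n_segments - 1`` turning
        points).
    noise_rate
        Probability that a (cell, segment) block carries a wrong copy
        number; equals the expected fraction of perturbed entries.
    mean_depth_per_bin
        Expected raw reads per bin for a diploid cell with unit size factor
        (default 100, shallow whole-genome coverage at 500 kb bins).
    dispersion
        Variance-to-mean ratio of the count distribution: 1 = Poisson
        (default), 0 = deterministic rounding of the mean, >1 overdispersed
        (negative binomial), (0, 1) underdispersed (binomial thinning).
    seed
        Seeds all randomness; two streams are derived from it (truth,
        counts).
    """

    n_cells: int = 100
    n_bins: int = 70
    n_clones: int = 4
    normal_fraction: float = 0.5
    n_segments: int = 7
    noise_rate: float = 0.1
    mean_depth_per_bin: float = 100.0
    dispersion: float = 1.0
    seed: int = 0
    cn_max: int = 10
    clone_cn_max: int = 6
    chrom: str = "chr22"
    bin_width: int = 500_000
    cell_factor_sigma: float = 0.1
    bin_effect_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValidationError(f"noise_rate {self.noise_rate} outside [0, 1]")
        if not 0.0 <= self.normal_fraction <= 1.0:
            raise ValidationError(f"normal_fraction {self.normal_fraction} outside [0, 1]")
        if self.n_segments > self.n_bins:
            raise ValidationError("n_segments exceeds n_bins")
        if self.n_segments < 1 or self.n_bins < 1 or self.n_cells < 1:
            raise ValidationError("n_segments, n_bins, n_cells must be >= 1")
        if self.n_clones < 0:
            raise ValidationError("n_clones must be >= 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.mean_depth_per_bin <= 0:
            raise ValidationError("mean_depth_per_bin must be > 0")
        if self.cn_max < 3:
            raise ValidationError("cn_max must be >= 3")
        if not 3 <= self.clone_cn_max <= self.cn_max:
            raise ValidationError("clone_cn_max must be in [3, cn_max]")


@dataclass
class SyntheticTruth:
    """Planted ground truth: copy numbers, clone map, boundary positions."""

    cnv: np.ndarray  # (n_bins, n_cells) integers
    clone_of: dict[str, str]
    turning_points: list[int]
    params: SimParams
    cell_ids: list[str] = field(default_factory=list)
    bins: list[BinAnnotation] = field(default_factory=list)
    clone_profiles: dict[str, np.ndarray] = field(default_factory=dict)


def _make_bins(params: SimParams) -> list[BinAnnotation]:
    w = params.bin_width
    return [
        BinAnnotation(params.chrom, i * w + 1, (i + 1) * w, i)
        for i in range(params.n_bins)
    ]


def generate_truth(params: SimParams) -> SyntheticTruth:
    """Draw planted boundaries, clone profiles, cell assignments, and noise.

    Normal cells are diploid everywhere.  Each tumor clone carries an
    integer copy number in ``{1..clone_cn_max}`` per planted segment,
    changing state at every planted boundary (the shared boundaries are the
    union of clone breakpoints, and the pre-defined profiles are designed so
    each boundary is a real copy-state change), with at least one
    non-diploid segment per clone.  Planted segments span at least two bins
    where the bin budget allows.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, 0])
    m, n = params.n_bins, params.n_cells
    n_seg = params.n_segments
    min_len = 2 if m >= 2 * n_seg else 1
    lengths = min_len + rng.multinomial(m - min_len * n_seg, [1.0 / n_seg] * n_seg)
    tps = (np.cumsum(lengths)[:-1] - 1).tolist()
    edges = [-1, *tps, m - 1]
    seg_slices = [slice(edges[i] + 1, edges[i + 1] + 1) for i in range(n_seg)]

    n_normal = int(round(params.normal_fraction * n))
    if params.n_clones == 0:
        n_normal = n
    clone_names = [f"clone{c + 1}" for c in range(params.n_clones)]
    sizes = np.zeros(params.n_clones, dtype=int)
    if params.n_clones:
        base, rem = divmod(n - n_normal, params.n_clones)
        sizes[:] = base
        sizes[:rem] += 1

    profiles: dict[str, np.ndarray] = {}
    choices = np.arange(1, params.clone_cn_max + 1)
    for name in clone_names:
        prof = np.empty(n_seg, dtype=int)
        prof[0] = rng.choice(choices if n_seg > 1 else choices[choices != 2])
        for s in range(1, n_seg):
            prof[s] = rng.choice(choices[choices != prof[s - 1]])
        if np.all(prof == 2):  # only possible when n_seg == 1, handled above
            prof[0] = rng.choice(choices[choices != 2])
        profiles[name] = prof

    cell_ids = [f"cell{j:04d}" for j in range(n)]
    clone_of: dict[str, str] = {}
    seg_cn = np.full((n_seg, n), 2, dtype=int)  # per-(segment, cell) copy number
    j = n_normal
    for name, size in zip(clone_names, sizes):
        for jj in range(j, j + size):
            seg_cn[:, jj] = profiles[name]
            clone_of[cell_ids[jj]] = name
        j += size
    for jj in range(n_normal):
        clone_of[cell_ids[jj]] = "normal"

    if params.noise_rate > 0:
        noisy = rng.random((n_seg, n)) < params.noise_rate
        all_cn = np.arange(0, params.cn_max + 1)
        for s, jj in zip(*np.nonzero(noisy)):
            cur = seg_cn[s, jj]
            seg_cn[s, jj] = rng.choice(all_cn[all_cn != cur])

    cnv = np.empty((m, n), dtype=int)
    for s, sl in enumerate(seg_slices):
        cnv[sl] = seg_cn[s]
    return SyntheticTruth(
        cnv=cnv,
        clone_of=clone_of,
        turning_points=tps,
        params=params,
        cell_ids=cell_ids,
        bins=_make_bins(params),
        clone_profiles=profiles,
    )


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Counts with mean ``mu`` and variance ``dispersion * mu``."""
    if dispersion == 0.0:
        return np.round(mu)
    if dispersion == 1.0:
        return rng.poisson(mu).astype(float)
    if dispersion > 1.0:
        size = np.maximum(mu, 1e-12) / (dispersion - 1.0)
        return rng.negative_binomial(size, 1.0 / dispersion).astype(float)
    # underdispersed: binomial thinning
    ntrials = np.maximum(1, np.round(mu / (1.0 - dispersion))).astype(int)
    p = np.clip(mu / ntrials, 0.0, 1.0)
    return rng.binomial(ntrials, p).astype(float)


def simulate_counts(truth: SyntheticTruth) -> tuple[ReadDepthMatrix, ReadDepthMatrix]:
    """Raw counts plus the matching diploid-expectation normalized matrix.

    ``E[raw[i, j]] = (cn[i, j] / 2) * depth * b_i * s_j`` with log-normal bin
    effects ``b_i`` and cell size factors ``s_j``; ``norm[i, j] = depth * b_i
    * s_j`` so that ``E[2 raw / norm]`` equals the planted copy number.
    Deterministic given ``truth.params.seed``.
    """
    p = truth.params
    rng = np.random.default_rng([p.seed, 1])
    m, n = truth.cnv.shape
    b = np.exp(rng.normal(0.0, p.bin_effect_sigma, size=m))
    s = np.exp(rng.normal(0.0, p.cell_factor_sigma, size=n))
    base = p.mean_depth_per_bin * np.outer(b, s)
    raw_vals = _sample_counts(rng, (truth.cnv / 2.0) * base, p.dispersion)
    raw = ReadDepthMatrix(raw_vals, truth.bins, list(truth.cell_ids), RAW)
    norm = ReadDepthMatrix(base, list(truth.bins), list(truth.cell_ids), NORMALIZED)
    return raw, norm


GridAxis = Literal["normal_fraction", "n_clones", "n_segments"]


def scenario_grid(
    base: SimParams, axis: GridAxis, values: list
) -> list[tuple[SimParams, SyntheticTruth]]:
    """One truth per value of one design axis, other parameters fixed.

    Per-scenario seeds are derived deterministically from ``base.seed``.
    """
    if axis not in ("normal_fraction", "n_clones", "n_segments"):
        raise ValidationError(f"unknown grid axis {axis!r}")
    if not values:
        raise ValidationError("scenario_grid needs at least one value")
    out = []
    for i, v in enumerate(values):
        seed = int((base.seed * 1_000_003 + 7_919 * (i + 1)) % (2**31))
        p = replace(base, **{axis: v}, seed=seed)
        out.append((p, generate_truth(p)))
    return out
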