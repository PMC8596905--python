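"""Brute-force reference segmentation by exhaustive enumeration.

Scores every possible turning-point subset directly with the objective from
:mod:`scseg.mbic_core` — no recursion, no prefix sums — and is therefore an
independent check of the dynamic-programming engine on small instances
(feasible up to ``m`` around 15).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .depth_matrix import ReadDepthMatrix, ValidationError
from .mbic_core import MBICParams, mbic_penalty, segment_loglik, segment_stat


def exhaustive_best(
    raw: ReadDepthMatrix,
    norm: ReadDepthMatrix,
    params: MBICParams | None = None,
    K: int | None = None,
) -> tuple[dict[int, float], tuple[int, ...], float]:
    """Enumerate all segmentations with up to ``K`` segments.

    Returns ``(best_beta_by_k, best_turning_points, best_beta)`` where
    ``best_beta_by_k[k]`` is the maximal score over all segmentations into
    exactly ``k`` segments.  Single-segment log-likelihoods are evaluated
    naively (direct means over the bin range) and cached; each candidate
    segmentation is then a sum of cached terms plus the penalty.
    """
    params = (params or MBICParams()).resolved(raw.n)
    m = raw.m
    if m > 20:
        raise ValidationError("exhaustive enumeration is limited to m <= 20")
    if K is None:
        K = m
    K = min(K, m)

    cache: dict[tuple[int, int], float] = {}

    def seg_ll(a: int, b: int) -> float:
        key = (a, b)
        if key not in cache:
            cache[key] = segment_loglik(segment_stat(raw, norm, a, b), params)
        return cache[key]

    best_by_k: dict[int, float] = {}
    best_tps: tuple[int, ...] = ()
    best_beta = -np.inf
    for k in range(1, K + 1):
        pen = mbic_penalty(m, k, params)
        top = -np.inf
        top_tps: tuple[int, ...] = ()
        for tps in combinations(range(m - 1), k - 1):
            edges = (-1, *tps, m - 1)
            ll = sum(seg_ll(edges[i] + 1, edges[i + 1]) for i in range(k))
            if ll > top:
                top = ll
                top_tps = tps
        best_by_k[k] = top + pen
        if best_by_k[k] > best_beta:
            best_beta = best_by_k[k]
            best_tps = top_tps
    return best_by_k, best_tps, float(best_beta)
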