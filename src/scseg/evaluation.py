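"""Benchmarking utilities: boundary accuracy, profile agreement, clustering.

Covers the standard evaluation battery for single-cell copy-number callers:
precision/recall of recovered turning points against planted ones, Pearson
correlation and RMSE of a called profile against a reference, agglomerative
clustering of cells on their copy-number vectors with external indices
(adjusted Rand, normalized mutual information, pair-counting Jaccard), and
Gini-coefficient flagging of aneuploid cells from coverage inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import pair_confusion_matrix

from .cnv_call import CNVMatrix
from .depth_matrix import ReadDepthMatrix, ValidationError


@dataclass
class EvalReport:
    """Flat bundle of evaluation metrics; serialize with ``to_dict``."""

    tp_precision: float | None = None
    tp_recall: float | None = None
    pearson: float | None = None
    rmse: float | None = None
    ari: float | None = None
    nmi: float | None = None
    ji: float | None = None
    labels: dict | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def turning_point_accuracy(
    found: Sequence[int], planted: Sequence[int], tolerance: int = 0
) -> tuple[float, float]:
    """Greedy one-to-one matching of boundary positions within ``tolerance``.

    Precision is matched/|found|, recall matched/|planted|; an empty side
    scores 1.0 on its own ratio (no false positives / nothing to miss).
    """
    found = sorted(found)
    planted = sorted(planted)
    matched = 0
    i = j = 0
    while i < len(found) and j < len(planted):
        d = found[i] - planted[j]
        if abs(d) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    precision = matched / len(found) if found else 1.0
    recall = matched / len(planted) if planted else 1.0
    return precision, recall


def cnv_agreement(est, ref) -> tuple[float, float]:
    """Pearson r and RMSE between two aligned copy-number vectors.

    Pairs with a missing (NaN) value on either side are dropped.  Pearson is
    undefined for a constant vector and reported as NaN; RMSE is always
    computed.
    """
    est = np.asarray(est, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if est.shape != ref.shape:
        raise ValidationError(f"length mismatch: {est.size} vs {ref.size}")
    keep = ~(np.isnan(est) | np.isnan(ref))
    est, ref = est[keep], ref[keep]
    if est.size == 0:
        raise ValidationError("no shared bins")
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        return float("nan"), rmse
    r = float(stats.pearsonr(est, ref).statistic)
    return r, rmse


def cluster_cells(cnv: CNVMatrix | np.ndarray, k: int) -> dict[str, int] | np.ndarray:
    """Agglomerative (Ward, Euclidean) clustering of cells on CN vectors.

    Accepts a :class:`CNVMatrix` (returns a cell-id -> label dict) or a bare
    bins-x-cells array (returns a label array).  Deterministic.
    """
    if isinstance(cnv, CNVMatrix):
        X = cnv.values.T.astype(float)
        ids = cnv.cell_ids
    else:
        X = np.asarray(cnv, dtype=float).T
        ids = None
    if not 1 <= k <= X.shape[0]:
        raise ValidationError(f"k={k} outside [1, {X.shape[0]}]")
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    if ids is None:
        return labels
    return dict(zip(ids, (int(x) for x in labels)))


def clustering_indices(labels, truth_labels) -> tuple[float, float, float]:
    """Adjusted Rand, normalized mutual information, pair-counting Jaccard.

    The Jaccard index counts cell pairs: TP / (TP + FP + FN) over pairs
    co-clustered in either labeling.  All three are 1.0 for identical
    partitions (up to label permutation).
    """
    a = np.asarray(labels)
    b = np.asarray(truth_labels)
    if a.shape != b.shape:
        raise ValidationError(f"label length mismatch: {a.size} vs {b.size}")
    ari = float(adjusted_rand_score(b, a))
    nmi = float(normalized_mutual_info_score(b, a))
    C = pair_confusion_matrix(b, a)
    tp, fp, fn = C[1, 1] / 2, C[0, 1] / 2, C[1, 0] / 2
    ji = float(tp / (tp + fp + fn)) if (tp + fp + fn) > 0 else 1.0
    return ari, nmi, ji


def gini_coefficient(x) -> float:
    """Gini coefficient of a non-negative vector (0 = perfectly uniform)."""
    x = np.sort(np.asarray(x, dtype=float))
    if (x < 0).any():
        raise ValidationError("Gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValidationError("Gini undefined for an all-zero vector")
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks * x).sum()) / (n * total) - (n + 1) / n)


def gini_flag(
    source: ReadDepthMatrix | CNVMatrix | np.ndarray,
    cutoff: float = 0.12,
) -> dict[str, str]:
    """Flag cells as tumor/normal by bin-profile coverage inequality.

    A diploid cell's coverage is near-uniform across bins (Gini near 0);
    aneuploid genomes are unequal.  Cells with Gini above ``cutoff``
    (default 0.12) are flagged ``"tumor"``.
    """
    if isinstance(source, (ReadDepthMatrix, CNVMatrix)):
        values = source.values
        ids = source.cell_ids
    else:
        values = np.asarray(source, dtype=float)
        ids = [f"cell{j}" for j in range(values.shape[1])]
    out = {}
    for j, cid in enumerate(ids):
        g = gini_coefficient(values[:, j])
        out[cid] = "tumor" if g > cutoff else "normal"
    return out
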