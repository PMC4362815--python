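"""Pairwise overlap statistics, input-normalized signal correlation at
open-chromatin sites, and average-linkage clustering of datasets.

Overlap fractions are directional (fraction of set A sharing >= 1 bp
with set B).  Input normalization of per-site counts uses symmetric +1
pseudocounts on ChIP and input before per-million scaling.  Clustering
is agglomerative average linkage on distance 1 - Pearson r with
deterministic lexical tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import RegionSet, overlaps

__all__ = [
    "OverlapSummary",
    "SignalCorrelationMatrix",
    "overlap_summary",
    "input_normalize",
    "signal_correlation",
    "cluster_datasets",
    "linkage_newick",
]


@dataclass
class OverlapSummary:
    set_a: str
    set_b: str
    n_a: int
    n_a_overlapping_b: int
    fraction: float
    stratum: str = "all"


@dataclass
class SignalCorrelationMatrix:
    datasets: List[str]
    matrix: np.ndarray
    excluded: List[str]  # zero-variance datasets, dropped from the matrix


def overlap_summary(
    a: RegionSet, b: RegionSet, stratum: Optional[RegionSet] = None
) -> OverlapSummary:
    """Fraction of ``a`` intervals sharing >= 1 bp with ``b``.

    With ``stratum`` given, only ``a`` intervals overlapping the stratum
    are considered.  Raises on an empty (post-restriction) ``a``.
    """
    if len(a) == 0:
        raise ValueError("empty region set: overlap fraction undefined")
    if stratum is not None:
        flags, _ = overlaps(a, stratum)
        a = RegionSet(
            [iv for iv, f in zip(a, flags) if f], name=a.name, genome=a.genome
        )
        if len(a) == 0:
            raise ValueError("no intervals of a overlap the stratum")
    flags, frac = overlaps(a, b)
    return OverlapSummary(
        set_a=a.name,
        set_b=b.name,
        n_a=len(a),
        n_a_overlapping_b=int(flags.sum()),
        fraction=frac,
        stratum="all" if stratum is None else "within_open_chromatin",
    )


def input_normalize(
    chip_counts: np.ndarray,
    input_counts: np.ndarray,
    chip_lib: float,
    input_lib: float,
    log2: bool = False,
) -> np.ndarray:
    """Per-site ratio (chip + 1)/(input + 1) of RPM-scaled counts."""
    chip = (np.asarray(chip_counts, dtype=np.float64) + 1.0) / chip_lib * 1e6
    inp = (np.asarray(input_counts, dtype=np.float64) + 1.0) / input_lib * 1e6
    ratio = chip / inp
    return np.log2(ratio) if log2 else ratio


def signal_correlation(
    signals: "pd.DataFrame | np.ndarray",
    dataset_names: Optional[Sequence[str]] = None,
) -> SignalCorrelationMatrix:
    """Pearson correlation between datasets over sites.

    ``signals`` is a sites x datasets DataFrame or a 2-D array plus
    ``dataset_names``.  Zero-variance datasets are flagged and excluded.
    Requires >= 2 usable datasets and >= 3 sites.
    """
    if isinstance(signals, pd.DataFrame):
        names = list(signals.columns)
        values = signals.to_numpy(dtype=np.float64)
    else:
        values = np.asarray(signals, dtype=np.float64)
        names = list(dataset_names or [f"d{i}" for i in range(values.shape[1])])
    if values.shape[0] < 3:
        raise ValueError("need >= 3 sites")
    sds = values.std(axis=0)
    excluded = [n for n, sd in zip(names, sds) if sd == 0]
    keep = [i for i, sd in enumerate(sds) if sd > 0]
    if len(keep) < 2:
        raise ValueError("need >= 2 datasets with nonzero variance")
    kept_names = [names[i] for i in keep]
    corr = np.corrcoef(values[:, keep], rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return SignalCorrelationMatrix(
        datasets=kept_names, matrix=corr, excluded=excluded
    )


# average-linkage agglomeration; merges recorded as
# (cluster_a, cluster_b, height) where clusters are frozensets of labels
Merge = Tuple[frozenset, frozenset, float]


def cluster_datasets(
    corr: SignalCorrelationMatrix,
) -> Tuple[List[str], List[Merge]]:
    """Agglomerative average-linkage clustering on distance 1 - r.

    Ties break on the lexically smallest member label, so the merge
    order (and leaf order) is invariant to input permutation.  Returns
    (ordered leaf labels, merge list).
    """
    n = len(corr.datasets)
    if n < 2:
        raise ValueError("need >= 2 datasets to cluster")
    if np.isnan(corr.matrix).any():
        raise ValueError("correlation matrix contains missing entries")
    dist: Dict[Tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((corr.datasets[i], corr.datasets[j]))
            dist[(a, b)] = 1.0 - float(corr.matrix[i, j])

    def d(x: str, y: str) -> float:
        a, b = sorted((x, y))
        return dist[(a, b)]

    clusters: List[frozenset] = [frozenset([name]) for name in corr.datasets]
    order: Dict[frozenset, List[str]] = {c: sorted(c) for c in clusters}
    merges: List[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ci, cj = clusters[i], clusters[j]
                avg = float(
                    np.mean([d(x, y) for x in ci for y in cj])
                )
                key = (avg, min(min(ci), min(cj)), max(min(ci), min(cj)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (avg, _, _), i, j = best
        ci, cj = clusters[i], clusters[j]
        # put the lexically smaller cluster first in the leaf order
        first, second = (ci, cj) if min(ci) <= min(cj) else (cj, ci)
        merged = ci | cj
        order[merged] = order[first] + order[second]
        merges.append((first, second, avg))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    leaf_order = order[clusters[0]]
    return leaf_order, merges


def linkage_newick(merges: List[Merge]) -> str:
    """Render the merge list as a Newick string with merge heights."""
    reps: Dict[frozenset, str] = {}

    def rep(c: frozenset) -> str:
        if c in reps:
            return reps[c]
        if len(c) == 1:
            return next(iter(c))
        raise KeyError(c)

    for first, second, height in merges:
        text = f"({rep(first)},{rep(second)}):{height:.6g}"
        reps[first | second] = text
    if not merges:
        return ";"
    root = merges[-1][0] | merges[-1][1]
    return reps[root].rsplit(":", 1)[0] + ";"
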