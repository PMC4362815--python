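"""Treatment-specific binding-site calling from subpeak sets.

A treated subpeak is called differential iff it does not share >= 1 bp
with any control subpeak AND its smoothed fold change exceeds
mean + k_sd * sd over all treated subpeaks of the population.  Fold
change is computed on pseudocount-smoothed counts scaled per million
mapped reads; a pseudocount (default 10) is added to both raw counts
before scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, RegionSet, overlaps

__all__ = [
    "FoldChangeRecord",
    "DifferentialCallConfig",
    "fold_change",
    "fold_change_records",
    "call_differential_peaks",
]


def fold_change(
    count_treated: float,
    lib_treated: float,
    count_control: float,
    lib_control: float,
    smoothing: float = 10.0,
) -> float:
    """Smoothed RPM ratio treated/control.

    FC = ((count_treated + s) / lib_treated) /
         ((count_control + s) / lib_control); the per-million factors
    cancel.  The pseudocount guarantees a finite positive result.
    """
    if lib_treated <= 0 or lib_control <= 0:
        raise ValueError("library sizes must be > 0")
    if count_treated < 0 or count_control < 0:
        raise ValueError("counts must be >= 0")
    return ((count_treated + smoothing) / lib_treated) / (
        (count_control + smoothing) / lib_control
    )


@dataclass
class FoldChangeRecord:
    region: GenomicInterval
    count_treated: float
    count_control: float
    lib_treated: float
    lib_control: float
    smoothing: float = 10.0
    fold_change: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_change = fold_change(
            self.count_treated,
            self.lib_treated,
            self.count_control,
            self.lib_control,
            self.smoothing,
        )


@dataclass
class DifferentialCallConfig:
    peak_p_threshold: float = 9.0  # -log10 p cutoff on input subpeaks
    smoothing: float = 10.0
    k_sd: float = 1.0
    min_fold_change: Optional[float] = None  # optional hard floor, off by default

    def __post_init__(self) -> None:
        if self.peak_p_threshold <= 0 or self.smoothing <= 0 or self.k_sd <= 0:
            raise ValueError("config values must be strictly positive")


def fold_change_records(
    treated: RegionSet,
    counts_treated: Sequence[float],
    counts_control: Sequence[float],
    lib_treated: float,
    lib_control: float,
    smoothing: float = 10.0,
) -> List[FoldChangeRecord]:
    """Build one record per treated subpeak, in region-set order."""
    if len(counts_treated) != len(treated) or len(counts_control) != len(treated):
        raise ValueError("count vectors must cover every treated subpeak")
    return [
        FoldChangeRecord(
            region=iv,
            count_treated=ct,
            count_control=cc,
            lib_treated=lib_treated,
            lib_control=lib_control,
            smoothing=smoothing,
        )
        for iv, ct, cc in zip(treated, counts_treated, counts_control)
    ]


def call_differential_peaks(
    treated: RegionSet,
    control: RegionSet,
    fc: Sequence[FoldChangeRecord],
    cfg: DifferentialCallConfig = DifferentialCallConfig(),
) -> Tuple[RegionSet, pd.DataFrame]:
    """Apply the overlap-exclusion + fold-change rule.

    ``fc`` must carry one record per treated subpeak in set order.  The
    fold-change cutoff mean + k_sd * sd is computed over ALL treated
    subpeaks (before any exclusion).  Requires >= 2 treated subpeaks so
    the standard deviation is defined.
    """
    if len(treated) < 2:
        raise ValueError("need >= 2 treated subpeaks to estimate an sd")
    if len(fc) != len(treated):
        raise ValueError("fc must cover every treated subpeak")
    values = np.array([r.fold_change for r in fc], dtype=np.float64)
    cutoff = float(values.mean() + cfg.k_sd * values.std(ddof=1))
    overlap_flags, _ = overlaps(treated, control)
    rows = []
    kept: List[GenomicInterval] = []
    for iv, rec, ov in zip(treated, fc, overlap_flags):
        passes_fc = rec.fold_change > cutoff
        passes_floor = (
            cfg.min_fold_change is None or rec.fold_change > cfg.min_fold_change
        )
        called = (not ov) and passes_fc and passes_floor
        if ov:
            reason = "overlaps_control"
        elif not passes_fc:
            reason = "below_fc_cutoff"
        elif not passes_floor:
            reason = "below_fc_floor"
        else:
            reason = ""
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name or "",
                "count_treated": rec.count_treated,
                "count_control": rec.count_control,
                "lib_treated": rec.lib_treated,
                "lib_control": rec.lib_control,
                "smoothing": rec.smoothing,
                "fold_change": rec.fold_change,
                "fc_cutoff": cutoff,
                "overlaps_control": bool(ov),
                "called": called,
                "exclusion_reason": reason,
            }
        )
        if called:
            kept.append(
                GenomicInterval(
                    iv.chrom,
                    iv.start,
                    iv.end,
                    strand=iv.strand,
                    score=rec.fold_change,
                    summit=iv.summit,
                    name=iv.name,
                )
            )
    out = RegionSet(kept, name="differential_peaks", genome=treated.genome)
    return out, pd.DataFrame(rows)
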