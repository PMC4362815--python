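"""Differential expression across the treatment design and knockdown
dependence classification.

A gene is transformation-differential when the Welch t-test on log2
values (treatment vs vehicle, control-siRNA samples only) gives
p < 1e-4 AND |log2 fold change| > 0.5 — a strict conjunction.  Among
such genes, the effect is classified as knockdown-DEPENDENT when it is
abolished under the knockdown (non-significant AND |log2fc| < 0.5),
knockdown-INDEPENDENT when it persists at the same thresholds, and
ambiguous otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, RegionSet

__all__ = [
    "ExpressionMatrix",
    "DEGeneCall",
    "DependenceCall",
    "call_differential_genes",
    "classify_knockdown_dependence",
    "peak_density_profile",
    "P_THRESHOLD",
    "FC_THRESHOLD",
]

logger = logging.getLogger(__name__)

P_THRESHOLD = 1e-4
FC_THRESHOLD = 0.5

TREATED = "TAM"
VEHICLE = "EtOH"
CONTROL_SIRNA = "siSCM"
KNOCKDOWN_SIRNA = "siSTAT3"


class ExpressionMatrix:
    """Log2 expression values (genes x samples) with a design table.

    The design table has one row per sample with columns
    (sample_id, treatment, sirna, time, replicate).
    """

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame):
        required = {"sample_id", "treatment", "sirna", "time", "replicate"}
        missing = required - set(design.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        if set(values.columns) != set(design["sample_id"]):
            raise ValueError("value columns and design sample_ids differ")
        self.values = values
        self.design = design.copy()
        self.design["time"] = self.design["time"].astype(str)

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    def group(self, treatment: str, sirna: str, time: str) -> pd.DataFrame:
        sel = self.design[
            (self.design["treatment"] == treatment)
            & (self.design["sirna"] == sirna)
            & (self.design["time"] == str(time))
        ]
        return self.values[list(sel["sample_id"])]


@dataclass
class DEGeneCall:
    gene_id: str
    time: str
    log2fc: float
    p: float
    differential: bool
    direction: str  # "up" | "down" | "none"


@dataclass
class DependenceCall:
    gene_id: str
    time: str
    status: str  # "dependent" | "independent" | "ambiguous"
    log2fc_control: float
    log2fc_knockdown: Optional[float]
    p_knockdown: Optional[float]


def _welch(treated: np.ndarray, vehicle: np.ndarray) -> Tuple[float, float]:
    """(log2fc, two-sided Welch p).  Identical constant groups give p=1."""
    fc = float(treated.mean() - vehicle.mean())
    if treated.std(ddof=1) == 0 and vehicle.std(ddof=1) == 0:
        return fc, (1.0 if fc == 0 else 0.0)
    res = stats.ttest_ind(treated, vehicle, equal_var=False)
    return fc, float(res.pvalue)


def call_differential_genes(
    expr: ExpressionMatrix,
    time: str,
    sirna: str = CONTROL_SIRNA,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> List[DEGeneCall]:
    """Welch two-sample test per gene, treated vs vehicle, within one
    siRNA arm; differential iff p < p_threshold AND |log2fc| > fc_threshold."""
    treated = expr.group(TREATED, sirna, time)
    vehicle = expr.group(VEHICLE, sirna, time)
    calls: List[DEGeneCall] = []
    for gene in expr.gene_ids:
        t = treated.loc[gene].to_numpy(dtype=np.float64)
        v = vehicle.loc[gene].to_numpy(dtype=np.float64)
        t, v = t[~np.isnan(t)], v[~np.isnan(v)]
        if len(t) < 2 or len(v) < 2:
            logger.warning("gene %s skipped: <2 replicates in a group", gene)
            continue
        fc, p = _welch(t, v)
        differential = (p < p_threshold) and (abs(fc) > fc_threshold)
        direction = "up" if fc > 0 else ("down" if fc < 0 else "none")
        calls.append(DEGeneCall(gene, str(time), fc, p, differential, direction))
    return calls


def classify_knockdown_dependence(
    expr: ExpressionMatrix,
    de_calls: Sequence[DEGeneCall],
    knockdown_sirna: str = KNOCKDOWN_SIRNA,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> List[DependenceCall]:
    """Classify control-arm differential genes by whether the treatment
    effect survives the knockdown.

    dependent:   knockdown effect non-significant AND |log2fc| < fc_threshold
    independent: knockdown effect significant AND |log2fc| > fc_threshold
    ambiguous:   everything else (including missing knockdown data)
    """
    out: List[DependenceCall] = []
    for call in de_calls:
        if not call.differential:
            continue
        treated = expr.group(TREATED, knockdown_sirna, call.time)
        vehicle = expr.group(VEHICLE, knockdown_sirna, call.time)
        if call.gene_id not in treated.index or call.gene_id not in vehicle.index:
            logger.warning("gene %s missing under knockdown", call.gene_id)
            out.append(
                DependenceCall(call.gene_id, call.time, "ambiguous",
                               call.log2fc, None, None)
            )
            continue
        t = treated.loc[call.gene_id].to_numpy(dtype=np.float64)
        v = vehicle.loc[call.gene_id].to_numpy(dtype=np.float64)
        t, v = t[~np.isnan(t)], v[~np.isnan(v)]
        if len(t) < 2 or len(v) < 2:
            out.append(
                DependenceCall(call.gene_id, call.time, "ambiguous",
                               call.log2fc, None, None)
            )
            continue
        fc, p = _welch(t, v)
        abolished = (p >= p_threshold) and (abs(fc) < fc_threshold)
        persists = (p < p_threshold) and (abs(fc) > fc_threshold)
        status = (
            "dependent" if abolished else ("independent" if persists else "ambiguous")
        )
        out.append(
            DependenceCall(call.gene_id, call.time, status, call.log2fc, fc, p)
        )
    return out


def peak_density_profile(
    genes: Sequence[GeneModel],
    log2fc: Dict[str, float],
    diff_peaks: RegionSet,
    promoter_window: Tuple[int, int] = (-2500, 500),
    flank_bp: int = 50_000,
    rolling: int = 1000,
) -> pd.DataFrame:
    """Differential-peak density per gene, ranked by log2 fold change.

    Per gene: peaks-per-kbp with summit in the strand-aware promoter
    window (-2,500..+500 around the TSS by default) and in the +/-50 kbp
    flank excluding the promoter.  A centered rolling mean (window
    ``rolling``, truncated at the edges) is added over the ranked list.
    Genes are ranked by descending log2fc; genes without a fold change
    are dropped.
    """
    summits_by_chrom: Dict[str, np.ndarray] = {}
    for iv in diff_peaks:
        pos = iv.summit if iv.summit is not None else iv.midpoint
        summits_by_chrom.setdefault(iv.chrom, []).append(pos)  # type: ignore
    summits_by_chrom = {
        c: np.sort(np.asarray(v, dtype=np.int64))
        for c, v in summits_by_chrom.items()
    }

    def _count(chrom: str, lo: int, hi: int) -> int:
        arr = summits_by_chrom.get(chrom)
        if arr is None or lo >= hi:
            return 0
        return int(
            np.searchsorted(arr, hi, side="left")
            - np.searchsorted(arr, lo, side="left")
        )

    lo_w, hi_w = promoter_window
    rows = []
    for g in genes:
        if g.gene_id not in log2fc:
            continue
        if g.strand == "+":
            prom = (g.tss + lo_w, g.tss + hi_w + 1)
        else:
            prom = (g.tss - hi_w, g.tss - lo_w + 1)
        prom = (max(0, prom[0]), prom[1])
        flank = (max(0, g.tss - flank_bp), g.tss + flank_bp + 1)
        prom_n = _count(g.chrom, *prom)
        flank_n = _count(g.chrom, *flank) - _count(
            g.chrom, max(prom[0], flank[0]), min(prom[1], flank[1])
        )
        prom_kb = (prom[1] - prom[0]) / 1000.0
        flank_kb = ((flank[1] - flank[0]) - (prom[1] - prom[0])) / 1000.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "log2fc": log2fc[g.gene_id],
                "promoter_density": prom_n / prom_kb,
                "flank_density": flank_n / flank_kb,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(
        ["log2fc", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    for col in ("promoter_density", "flank_density"):
        df[f"{col}_rolling"] = (
            df[col].rolling(window=rolling, center=True, min_periods=1).mean()
        )
    return df


def collapse_probes(
    values: pd.DataFrame, probe_to_gene: pd.Series, pvals: pd.Series
) -> pd.DataFrame:
    """Collapse probes to genes keeping the lowest-p probe per gene."""
    order = pvals.sort_values(kind="mergesort")
    best: Dict[str, str] = {}
    for probe in order.index:
        gene = probe_to_gene.get(probe)
        if gene is not None and gene not in best:
            best[gene] = probe
    out = values.loc[list(best.values())].copy()
    out.index = list(best.keys())
    return out
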