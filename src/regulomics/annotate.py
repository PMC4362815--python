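"""Peak-to-gene annotation: nearest-TSS distances, genomic feature
classes, smoothed TSS-distance densities, binomial feature enrichment,
and basal-plus-extension regulatory domains.

Feature classes are assigned with the precedence
promoter > exon > UTR > intron > upstream (<=10 kb of a TSS) >
downstream (<=10 kb past a TTS) > distal intergenic, so every summit
gets exactly one class.  Signed distances are strand-adjusted: negative
means upstream of the gene's TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChromSizes, GeneModel, GenomicInterval, RegionSet

__all__ = [
    "TssAnnotation",
    "RegulatoryDomain",
    "FEATURE_CLASSES",
    "nearest_tss",
    "classify_feature",
    "tss_density",
    "feature_enrichment",
    "genome_feature_fractions",
    "regulatory_domains",
    "associate_regions",
    "regions_near_genes",
]

FEATURE_CLASSES = [
    "promoter",
    "exon",
    "utr",
    "intron",
    "upstream",
    "downstream",
    "distal_intergenic",
]

# -2,500 to +500 bp around the TSS, strand-adjusted
DEFAULT_PROMOTER_WINDOW = (-2500, 500)
UPSTREAM_BP = 10_000
DOWNSTREAM_BP = 10_000
BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


@dataclass
class TssAnnotation:
    summit: int
    chrom: str
    gene_id: Optional[str]
    distance: Optional[int]  # signed; negative = upstream of the TSS
    feature_class: str


@dataclass
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal: Tuple[int, int]
    domain: Tuple[int, int]


def _signed_distance(summit: int, gene: GeneModel) -> int:
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def nearest_tss(
    summits: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: Tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> List[TssAnnotation]:
    """Annotate each summit with its nearest-TSS gene and feature class.

    Minimal |distance| wins; ties break by gene_id lexical order.
    Summits on chromosomes without genes are annotated distal with a
    missing gene.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_tss: Dict[str, Tuple[np.ndarray, List[GeneModel]]] = {}
    for chrom, gs in by_chrom.items():
        gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        sorted_tss[chrom] = (
            np.array([g.tss for g in gs_sorted], dtype=np.int64),
            gs_sorted,
        )
    out: List[TssAnnotation] = []
    for iv in summits:
        pos = iv.summit if iv.summit is not None else iv.midpoint
        if iv.chrom not in sorted_tss:
            out.append(
                TssAnnotation(pos, iv.chrom, None, None, "distal_intergenic")
            )
            continue
        tss_arr, gs_sorted = sorted_tss[iv.chrom]
        i = int(np.searchsorted(tss_arr, pos))
        candidates: List[GeneModel] = []
        for j in (i - 1, i):
            if 0 <= j < len(gs_sorted):
                tssv = tss_arr[j]
                # expand runs of identical TSS values
                k = j
                while k >= 0 and tss_arr[k] == tssv:
                    candidates.append(gs_sorted[k])
                    k -= 1
                k = j + 1
                while k < len(gs_sorted) and tss_arr[k] == tssv:
                    candidates.append(gs_sorted[k])
                    k += 1
        best = min(candidates, key=lambda g: (abs(pos - g.tss), g.gene_id))
        dist = _signed_distance(pos, best)
        fclass = classify_feature(
            pos, iv.chrom, by_chrom.get(iv.chrom, []), promoter_window
        )
        out.append(TssAnnotation(pos, iv.chrom, best.gene_id, dist, fclass))
    return out


def classify_feature(
    summit: int,
    chrom: str,
    genes: Sequence[GeneModel],
    promoter_window: Tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> str:
    """Single feature class for a summit, by precedence."""
    lo_w, hi_w = promoter_window
    is_promoter = is_exon = is_intron = is_up = is_down = False
    for g in genes:
        if g.chrom != chrom:
            continue
        d = _signed_distance(summit, g)
        if lo_w <= d <= hi_w:
            is_promoter = True
        span_lo, span_hi = g.span
        if span_lo <= summit < span_hi:
            if any(s <= summit < e for s, e in g.exons):
                is_exon = True
            else:
                is_intron = True
        if -UPSTREAM_BP <= d < 0:
            is_up = True
        dd = summit - g.tts if g.strand == "+" else g.tts - summit
        if 0 < dd <= DOWNSTREAM_BP:
            is_down = True
    if is_promoter:
        return "promoter"
    if is_exon:
        return "exon"
    if is_intron:
        return "intron"
    if is_up:
        return "upstream"
    if is_down:
        return "downstream"
    return "distal_intergenic"


def tss_density(
    annotations: Sequence[TssAnnotation],
    bin_width: int = 500,
    window: int = 10_000,
    bandwidth: float = 500.0,
) -> pd.DataFrame:
    """Histogram + Gaussian-kernel density of signed TSS distances.

    Distances outside +/- ``window`` are dropped.  The density is
    evaluated at bin centers and renormalized so its trapezoid integral
    over the window equals 1.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    dists = np.array(
        [
            a.distance
            for a in annotations
            if a.distance is not None and abs(a.distance) <= window
        ],
        dtype=np.float64,
    )
    edges = np.arange(-window, window + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if len(dists) == 0:
        warnings.warn("no annotations within the window")
        return pd.DataFrame(
            {"bin_center": centers, "count": 0, "density": np.nan}
        )
    counts, _ = np.histogram(dists, bins=edges)
    kernel = np.exp(
        -0.5 * ((centers[:, None] - dists[None, :]) / bandwidth) ** 2
    ).sum(axis=1)
    integral = np.trapezoid(kernel, centers)
    density = kernel / integral
    return pd.DataFrame(
        {"bin_center": centers, "count": counts, "density": density}
    )


def feature_enrichment(observed_k: int, n: int, genome_fraction: float) -> float:
    """One-sided binomial tail P(X >= k), X ~ Binomial(n, genome_fraction)."""
    if not (0 <= observed_k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < genome_fraction < 1.0):
        raise ValueError("genome_fraction must be in (0, 1)")
    return float(stats.binom.sf(observed_k - 1, n, genome_fraction))


def _merge_pairs(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_pairs(
    a: List[Tuple[int, int]], b: List[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """a \\ b for merged, sorted half-open interval lists."""
    out: List[Tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def genome_feature_fractions(
    genes: Sequence[GeneModel],
    genome: ChromSizes,
    promoter_window: Tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> Dict[str, float]:
    """Fraction of the genome in each feature class, with the same
    precedence rules used for summit classification."""
    raw: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        c: {} for c in FEATURE_CLASSES
    }

    def _add(cls: str, chrom: str, s: int, e: int) -> None:
        s = max(0, s)
        e = min(genome[chrom], e)
        if s < e:
            raw[cls].setdefault(chrom, []).append((s, e))

    lo_w, hi_w = promoter_window
    for g in genes:
        if g.strand == "+":
            _add("promoter", g.chrom, g.tss + lo_w, g.tss + hi_w + 1)
            _add("upstream", g.chrom, g.tss - UPSTREAM_BP, g.tss)
            _add("downstream", g.chrom, g.tts + 1, g.tts + DOWNSTREAM_BP + 1)
        else:
            _add("promoter", g.chrom, g.tss - hi_w, g.tss - lo_w + 1)
            _add("upstream", g.chrom, g.tss + 1, g.tss + UPSTREAM_BP + 1)
            _add("downstream", g.chrom, g.tts - DOWNSTREAM_BP, g.tts)
        for s, e in g.exons:
            _add("exon", g.chrom, s, e)
        span_lo, span_hi = g.span
        body = _subtract_pairs([(span_lo, span_hi)], _merge_pairs(g.exons))
        for s, e in body:
            _add("intron", g.chrom, s, e)

    total_bp = sum(length for _, length in genome.items())
    fractions: Dict[str, float] = {}
    higher: Dict[str, List[Tuple[int, int]]] = {}
    assigned_bp = 0
    for cls in FEATURE_CLASSES[:-1]:
        cls_bp = 0
        for chrom in genome:
            merged = _merge_pairs(raw[cls].get(chrom, []))
            exclusive = _subtract_pairs(merged, higher.get(chrom, []))
            cls_bp += sum(e - s for s, e in exclusive)
            higher[chrom] = _merge_pairs(higher.get(chrom, []) + merged)
        fractions[cls] = cls_bp / total_bp
        assigned_bp += cls_bp
    fractions["distal_intergenic"] = (total_bp - assigned_bp) / total_bp
    return fractions


def regulatory_domains(
    genes: Sequence[GeneModel],
    genome: ChromSizes,
    basal_upstream: int = BASAL_UPSTREAM,
    basal_downstream: int = BASAL_DOWNSTREAM,
    max_extension: int = MAX_EXTENSION,
) -> List[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    Basal = [TSS - basal_upstream, TSS + basal_downstream) strand-adjusted
    (regardless of neighbors).  The domain extends each direction to the
    nearest other gene's basal edge or at most ``max_extension`` bp past
    the basal edge, whichever is closer, clipped to the chromosome.
    """
    basal: Dict[str, Tuple[int, int]] = {}
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - basal_upstream, g.tss + basal_downstream
        else:
            lo, hi = g.tss - basal_downstream + 1, g.tss + basal_upstream + 1
        basal[g.gene_id] = (max(0, lo), min(genome[g.chrom], hi))

    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: List[RegulatoryDomain] = []
    for g in genes:
        own_lo, own_hi = basal[g.gene_id]
        left_edge = 0
        right_edge = genome[g.chrom]
        for other in by_chrom[g.chrom]:
            if other.gene_id == g.gene_id:
                continue
            o_lo, o_hi = basal[other.gene_id]
            if o_hi <= own_lo:
                left_edge = max(left_edge, o_hi)
            elif o_lo >= own_hi:
                right_edge = min(right_edge, o_lo)
            else:
                # overlapping basal: no extension past our own edge on
                # the side(s) the other basal covers
                if o_lo < own_lo:
                    left_edge = own_lo
                if o_hi > own_hi:
                    right_edge = own_hi
        dom_lo = max(own_lo - max_extension, left_edge, 0)
        dom_hi = min(own_hi + max_extension, right_edge, genome[g.chrom])
        dom_lo = min(dom_lo, own_lo)
        dom_hi = max(dom_hi, own_hi)
        out.append(
            RegulatoryDomain(
                gene_id=g.gene_id,
                chrom=g.chrom,
                basal=(own_lo, own_hi),
                domain=(dom_lo, dom_hi),
            )
        )
    return out


def associate_regions(
    regions: RegionSet, domains: Sequence[RegulatoryDomain]
) -> Tuple[Dict[str, List[int]], List[int]]:
    """Assign each region to every gene whose domain contains its summit
    (midpoint when the summit is absent).

    Returns (gene_id -> region indices, indices of unassociated regions).
    """
    by_chrom: Dict[str, List[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    assoc: Dict[str, List[int]] = {}
    unassociated: List[int] = []
    for i, iv in enumerate(regions):
        pos = iv.summit if iv.summit is not None else iv.midpoint
        hit = False
        for d in by_chrom.get(iv.chrom, []):
            if d.domain[0] <= pos < d.domain[1]:
                assoc.setdefault(d.gene_id, []).append(i)
                hit = True
        if not hit:
            unassociated.append(i)
    return assoc, unassociated


def regions_near_genes(
    regions: RegionSet,
    genes: Sequence[GeneModel],
    radius: int = 500_000,
) -> RegionSet:
    """Regions whose midpoint lies within +/- ``radius`` bp of any listed
    gene's TSS (inclusive bound)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not genes:
        warnings.warn("empty gene group")
        return RegionSet([], name=regions.name, genome=regions.genome)
    tss_by_chrom: Dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)  # type: ignore[union-attr]
    tss_by_chrom = {
        c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tss_by_chrom.items()
    }
    kept = []
    for iv in regions:
        arr = tss_by_chrom.get(iv.chrom)
        if arr is None:
            continue
        mid = iv.midpoint
        j = int(np.searchsorted(arr, mid))
        near = False
        for k in (j - 1, j):
            if 0 <= k < len(arr) and abs(mid - int(arr[k])) <= radius:
                near = True
        if near:
            kept.append(iv)
    return RegionSet(kept, name=regions.name, genome=regions.genome)
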