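"""Synthetic input generators with known ground truth.

Every generator is a pure function of its config and seed: counts are
negative-binomial per replicate, a configured minority of open-chromatin
sites receives an amplitude shift at one uniformly chosen time point,
motif instances are planted inside and outside open regions with a
logistic binding model on the motif quality score, and the expression
design is 2x2 (vehicle/treatment x control-siRNA/knockdown) with planted
dependent and independent treatment effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    RegionCountMatrix,
    RegionSet,
    SampleInfo,
)
from .expression import CONTROL_SIRNA, KNOCKDOWN_SIRNA, TREATED, VEHICLE, ExpressionMatrix
from .motif import BASES, PWM, MotifHit, score_site

__all__ = [
    "SimulationConfig",
    "FaireTruth",
    "ChipTruth",
    "ExpressionTruth",
    "default_pwm",
    "simulate_genome",
    "simulate_faire_counts",
    "simulate_chip",
    "simulate_expression",
]


@dataclass
class SimulationConfig:
    seed: int
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chrS": 10_000_000}
    )
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # open chromatin / counts
    n_faire_sites: int = 2000
    faire_width: int = 300
    fraction_differential: float = 0.17
    n_time_points: int = 4
    n_replicates: int = 3
    nb_mean: float = 100.0
    nb_dispersion: float = 20.0  # NB size parameter; larger = closer to Poisson
    effect_multiplier: float = 3.0
    library_size: int = 5_000_000
    library_size_jitter: float = 0.1
    # genes
    n_genes: int = 100
    gene_length: int = 20_000
    n_exons: int = 4
    # motifs / binding
    n_motif_instances: int = 5000
    fraction_instances_in_open: float = 0.5
    logistic_slope: float = 0.25
    logistic_intercept: float = -2.0
    closed_chromatin_factor: float = 0.1
    subpeak_width: int = 200
    # expression
    n_expr_genes: int = 1000
    n_dependent: int = 200
    n_independent: int = 200
    expression_effect: float = 1.5
    expression_sd: float = 0.2
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.0
    expression_times: Tuple[str, ...] = ("4", "24")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for rate in (
            self.fraction_differential,
            self.fraction_instances_in_open,
            self.closed_chromatin_factor,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {rate} outside [0, 1]")
        for count in (
            self.n_faire_sites,
            self.n_time_points,
            self.n_replicates,
            self.library_size,
            self.n_expr_genes,
        ):
            if count <= 0:
                raise ValueError("counts must be > 0")
        if self.n_dependent + self.n_independent > self.n_expr_genes:
            raise ValueError("planted genes exceed gene total")


@dataclass
class FaireTruth:
    differential: np.ndarray  # bool per site
    affected_time_point: np.ndarray  # time-point index, -1 for static sites


@dataclass
class ChipTruth:
    hits: List[MotifHit]  # planted instances with true bound/open flags
    bound_probability: np.ndarray  # per instance


@dataclass
class ExpressionTruth:
    status: pd.Series  # gene_id -> dependent | independent | null
    effect: pd.Series  # planted treatment effect per gene


def default_pwm(width: int = 12, seed: int = 7) -> PWM:
    """A generic informative motif with heterogeneous per-position
    sharpness, so sampled match scores have near-continuous support."""
    rng = np.random.default_rng(seed)
    dominant = rng.integers(0, 4, size=width)
    sharp = rng.uniform(0.6, 0.95, size=width)
    rest = rng.dirichlet(np.ones(3) * 2.0, size=width) * (1.0 - sharp)[:, None]
    freq = np.empty((width, 4))
    for i in range(width):
        others = [b for b in range(4) if b != dominant[i]]
        freq[i, dominant[i]] = sharp[i]
        freq[i, others] = rest[i]
    return PWM("synthetic_motif", freq)


def simulate_genome(
    cfg: SimulationConfig,
) -> Tuple[ChromSizes, Dict[str, str], List[GeneModel]]:
    """Random background sequence plus genes placed so that their basal
    promoter windows do not overlap."""
    rng = np.random.default_rng(cfg.seed)
    genome = ChromSizes(cfg.chrom_lengths)
    sequences: Dict[str, str] = {}
    for chrom, length in cfg.chrom_lengths.items():
        codes = rng.choice(4, size=length, p=np.asarray(cfg.base_composition))
        ascii_bases = np.frombuffer(BASES.encode(), dtype=np.uint8)
        sequences[chrom] = ascii_bases[codes].tobytes().decode("ascii")

    genes: List[GeneModel] = []
    if cfg.n_genes > 0:
        chroms = list(cfg.chrom_lengths)
        per_chrom = {c: 0 for c in chroms}
        for i in range(cfg.n_genes):
            per_chrom[chroms[i % len(chroms)]] += 1
        gid = 0
        for chrom, n in per_chrom.items():
            length = cfg.chrom_lengths[chrom]
            # deterministic spacing with jitter keeps basal windows disjoint
            slot = length // max(n, 1)
            if slot < cfg.gene_length + 12_000:
                raise ValueError("genes cannot be placed at requested density")
            for k in range(n):
                jitter = int(rng.integers(0, max(slot - cfg.gene_length - 12_000, 1)))
                start = k * slot + 6_000 + jitter
                strand = "+" if rng.random() < 0.5 else "-"
                lo, hi = start, start + cfg.gene_length
                exon_len = cfg.gene_length // (2 * cfg.n_exons)
                exons = [
                    (
                        lo + j * (cfg.gene_length // cfg.n_exons),
                        lo + j * (cfg.gene_length // cfg.n_exons) + exon_len,
                    )
                    for j in range(cfg.n_exons)
                ]
                tss, tts = (lo, hi) if strand == "+" else (hi, lo)
                genes.append(
                    GeneModel(f"gene_{gid:05d}", chrom, strand, tss, tts, exons)
                )
                gid += 1
    return genome, sequences, genes


def _place_sites(
    rng: np.random.Generator,
    genome: ChromSizes,
    n_sites: int,
    width: int,
) -> RegionSet:
    intervals: List[GenomicInterval] = []
    chroms = list(genome)
    weights = np.array([genome[c] for c in chroms], dtype=np.float64)
    weights /= weights.sum()
    per_chrom = rng.multinomial(n_sites, weights)
    idx = 0
    for chrom, n in zip(chroms, per_chrom):
        length = genome[chrom]
        slot = length // max(n, 1)
        if slot <= width:
            raise ValueError("too many sites for chromosome length")
        for k in range(n):
            start = k * slot + int(rng.integers(0, slot - width))
            intervals.append(
                GenomicInterval(
                    chrom, start, start + width, name=f"site_{idx:06d}"
                )
            )
            idx += 1
    return RegionSet(intervals, name="open_chromatin", genome=genome)


def simulate_faire_counts(
    cfg: SimulationConfig, genome: ChromSizes
) -> Tuple[RegionCountMatrix, FaireTruth]:
    """Negative-binomial replicate counts over open-chromatin sites with
    a planted amplitude shift in a configured fraction of sites.

    The number of planted sites is round(fraction * n); each planted
    site's mean is multiplied by ``effect_multiplier`` at one uniformly
    chosen time point in every replicate.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    regions = _place_sites(rng, genome, cfg.n_faire_sites, cfg.faire_width)
    n = len(regions)
    n_diff = int(round(cfg.fraction_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    differential = np.zeros(n, dtype=bool)
    differential[diff_idx] = True
    affected = np.full(n, -1, dtype=np.int64)
    affected[diff_idx] = rng.integers(0, cfg.n_time_points, size=n_diff)

    samples: List[SampleInfo] = []
    lib_sizes: List[int] = []
    for t in range(cfg.n_time_points):
        for r in range(cfg.n_replicates):
            jitter = 1.0 + cfg.library_size_jitter * (2 * rng.random() - 1.0)
            lib = int(cfg.library_size * jitter)
            lib_sizes.append(lib)
            samples.append(
                SampleInfo(
                    sample_id=f"t{t}_r{r + 1}",
                    assay="FAIRE",
                    time_point=f"t{t}",
                    replicate=r + 1,
                    library_size=lib,
                )
            )
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    size = cfg.nb_dispersion
    for j, s in enumerate(samples):
        t = int(s.time_point[1:])
        lib_factor = lib_sizes[j] / cfg.library_size
        mu = np.full(n, cfg.nb_mean * lib_factor)
        boosted = differential & (affected == t)
        mu[boosted] *= cfg.effect_multiplier
        p = size / (size + mu)
        counts[:, j] = rng.negative_binomial(size, p)
    matrix = RegionCountMatrix(regions, samples, counts)
    return matrix, FaireTruth(differential=differential, affected_time_point=affected)


def _sample_wmer(rng: np.random.Generator, pwm: PWM) -> str:
    return "".join(
        BASES[rng.choice(4, p=pwm.freq[i])] for i in range(pwm.width)
    )


def simulate_chip(
    cfg: SimulationConfig,
    genome: ChromSizes,
    faire: RegionSet,
    pwm: PWM,
) -> Tuple[RegionSet, RegionSet, pd.DataFrame, ChipTruth]:
    """Plant motif instances inside/outside open chromatin and emit
    bound-instance subpeaks with per-region treated/control counts.

    P(bound) = logistic(slope * score + intercept), multiplied by
    ``closed_chromatin_factor`` outside open chromatin.  Bound instances
    produce a treated subpeak centered on the instance with elevated
    treated counts; control counts stay at baseline.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_motif_instances
    n_open = int(round(cfg.fraction_instances_in_open * n))
    open_sites = list(faire)
    if n_open > 0 and not open_sites:
        raise ValueError("no open regions to place instances in")

    hits: List[MotifHit] = []
    probs = np.empty(n)
    treated_peaks: List[GenomicInterval] = []
    control_peaks: List[GenomicInterval] = []
    count_rows = []
    chroms = list(genome)
    half = cfg.subpeak_width // 2
    for i in range(n):
        in_open = i < n_open
        if in_open:
            site = open_sites[int(rng.integers(0, len(open_sites)))]
            chrom = site.chrom
            pos = int(
                rng.integers(site.start, max(site.end - pwm.width, site.start + 1))
            )
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(half + 1, genome[chrom] - pwm.width - half - 1))
            while faire.any_overlap(
                GenomicInterval(chrom, max(0, pos - half), pos + pwm.width + half)
            ):
                pos = int(
                    rng.integers(half + 1, genome[chrom] - pwm.width - half - 1)
                )
        wmer = _sample_wmer(rng, pwm)
        score = score_site(pwm, wmer)
        p_bound = 1.0 / (1.0 + np.exp(-(cfg.logistic_slope * score + cfg.logistic_intercept)))
        if not in_open:
            p_bound *= cfg.closed_chromatin_factor
        probs[i] = p_bound
        bound = bool(rng.random() < p_bound)
        hit = MotifHit(
            interval=GenomicInterval(chrom, pos, pos + pwm.width, strand="+"),
            score=score,
            p_value=float("nan"),
            in_open_chromatin=in_open,
            bound=bound,
        )
        hits.append(hit)
        if bound:
            center = pos + pwm.width // 2
            start = max(0, center - half)
            end = min(genome[chrom], center + half)
            treated_count = int(rng.poisson(200))
            control_count = int(rng.poisson(40))
            name = f"subpeak_{len(treated_peaks):06d}"
            treated_peaks.append(
                GenomicInterval(
                    chrom, start, end,
                    score=float(9 + rng.random() * 20), summit=center, name=name,
                )
            )
            count_rows.append(
                {
                    "region_id": name,
                    "count_treated": treated_count,
                    "count_control": control_count,
                }
            )
    treated = RegionSet(treated_peaks, name="treated_subpeaks", genome=genome)
    control = RegionSet(control_peaks, name="control_subpeaks", genome=genome)
    counts = pd.DataFrame(count_rows)
    return treated, control, counts, ChipTruth(hits=hits, bound_probability=probs)


def simulate_expression(
    cfg: SimulationConfig,
) -> Tuple[ExpressionMatrix, ExpressionTruth]:
    """2x2 expression design with planted dependent / independent genes.

    Dependent genes carry the treatment effect only under the control
    siRNA; independent genes carry it under both; remaining genes are
    null.  Values are baseline + effect + Normal(0, sd) noise.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    gene_ids = [f"egene_{i:05d}" for i in range(cfg.n_expr_genes)]
    status = np.array(
        ["dependent"] * cfg.n_dependent
        + ["independent"] * cfg.n_independent
        + ["null"] * (cfg.n_expr_genes - cfg.n_dependent - cfg.n_independent)
    )
    rng.shuffle(status)
    # up/down split of planted effects
    sign = np.where(rng.random(cfg.n_expr_genes) < 0.5, 1.0, -1.0)
    effect = np.where(status == "null", 0.0, cfg.expression_effect * sign)
    baseline = rng.normal(
        cfg.expression_baseline_mean, cfg.expression_baseline_sd, cfg.n_expr_genes
    )

    design_rows = []
    columns: Dict[str, np.ndarray] = {}
    for time in cfg.expression_times:
        for treatment in (VEHICLE, TREATED):
            for sirna in (CONTROL_SIRNA, KNOCKDOWN_SIRNA):
                for rep in range(1, 4):
                    sid = f"{treatment}_{sirna}_{time}h_r{rep}"
                    design_rows.append(
                        {
                            "sample_id": sid,
                            "treatment": treatment,
                            "sirna": sirna,
                            "time": str(time),
                            "replicate": rep,
                        }
                    )
                    mean = baseline.copy()
                    if treatment == TREATED:
                        if sirna == CONTROL_SIRNA:
                            mean = mean + effect
                        else:
                            mean = mean + np.where(
                                status == "independent", effect, 0.0
                            )
                    columns[sid] = mean + rng.normal(
                        0.0, cfg.expression_sd, cfg.n_expr_genes
                    )
    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(design_rows)
    truth = ExpressionTruth(
        status=pd.Series(status, index=gene_ids),
        effect=pd.Series(effect, index=gene_ids),
    )
    return ExpressionMatrix(values, design), truth
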